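"""Trainable pixel classification: multiscale filter bank + random forest.

The segmentation stage is a fixed, documented multiscale feature bank (the
features are never trained) feeding a random forest; only the forest is
fitted, on sparsely annotated pixels.  Probability maps can optionally be
Gaussian-smoothed before the argmax as a lightweight structured-prediction
stand-in (off by default).  3D stacks are classified slice-wise with 2D
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals, structure_tensor, structure_tensor_eigenvalues
from sklearn.ensemble import RandomForestClassifier

from .imstore import LabelMask, VoxelGrid

FEATURE_CHANNELS = {
    "gaussian": 1,
    "gradient-magnitude": 1,
    "laplacian": 1,
    "hessian-eigenvalues": 2,
    "structure-tensor-eigenvalues": 2,
    "difference-of-gaussians": 1,
}

DEFAULT_FEATURES = (
    "gaussian",
    "gradient-magnitude",
    "laplacian",
    "hessian-eigenvalues",
    "structure-tensor-eigenvalues",
)


@dataclass
class FeatureBankConfig:
    """Multiscale 2D filter-bank definition (fixed per model)."""

    scales: tuple[float, ...] = (1.0, 2.0, 4.0)
    feature_set: tuple[str, ...] = DEFAULT_FEATURES

    def __post_init__(self) -> None:
        self.scales = tuple(float(s) for s in self.scales)
        self.feature_set = tuple(self.feature_set)
        if not self.scales:
            raise ValueError("need at least one scale")
        unknown = set(self.feature_set) - set(FEATURE_CHANNELS)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        """Per-pixel feature count for a single input channel."""
        per_scale = sum(FEATURE_CHANNELS[f] for f in self.feature_set)
        return per_scale * len(self.scales)

    def to_dict(self) -> dict:
        return {"scales": list(self.scales), "feature_set": list(self.feature_set)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureBankConfig":
        return cls(scales=tuple(d["scales"]), feature_set=tuple(d["feature_set"]))


def _plane_features(plane: np.ndarray, cfg: FeatureBankConfig) -> np.ndarray:
    """Feature stack for one 2D plane, shape (H, W, n_features)."""
    img = plane.astype(np.float32)
    if max(cfg.scales) >= min(img.shape):
        raise ValueError(
            f"largest scale {max(cfg.scales)} exceeds image size {img.shape}"
        )
    feats = []
    for s in cfg.scales:
        smoothed = ndi.gaussian_filter(img, s)
        for name in cfg.feature_set:
            if name == "gaussian":
                feats.append(smoothed)
            elif name == "gradient-magnitude":
                feats.append(ndi.gaussian_gradient_magnitude(img, s))
            elif name == "laplacian":
                feats.append(ndi.gaussian_laplace(img, s))
            elif name == "hessian-eigenvalues":
                H = hessian_matrix(img, sigma=s, use_gaussian_derivatives=True)
                feats.extend(hessian_matrix_eigvals(H))
            elif name == "structure-tensor-eigenvalues":
                A = structure_tensor(img, sigma=max(s, 0.5))
                feats.extend(structure_tensor_eigenvalues(A))
            elif name == "difference-of-gaussians":
                feats.append(smoothed - ndi.gaussian_filter(img, 1.6 * s))
    out = np.stack(feats, axis=-1).astype(np.float32)
    if not np.all(np.isfinite(out)):
        out = np.nan_to_num(out)
    return out


def build_features(grid: VoxelGrid | np.ndarray, cfg: FeatureBankConfig) -> np.ndarray:
    """Per-pixel feature stack for a 2D image or slice-wise for a 3D stack.

    Returns shape ``(..., n_features)`` matching the spatial shape of *grid*.
    """
    data = grid.data if isinstance(grid, VoxelGrid) else np.asarray(grid)
    if data.ndim == 2:
        return _plane_features(data, cfg)
    if data.ndim == 3:
        return np.stack([_plane_features(pl, cfg) for pl in data], axis=0)
    raise ValueError("expected a 2D or 3D image")


@dataclass
class ClassifierModel:
    """A trained pixel classifier: fixed feature bank + fitted forest."""

    feature_config: FeatureBankConfig
    forest: RandomForestClassifier
    classes: dict[int, str]
    n_channels: int = 1
    oob_accuracy: float | None = None
    forest_params: dict = field(default_factory=dict)


def _as_channels(image) -> list[np.ndarray]:
    """Normalize a VoxelGrid / array / sequence thereof to channel arrays."""
    if isinstance(image, VoxelGrid):
        return [image.data]
    if isinstance(image, np.ndarray):
        return [image]
    return [(ch.data if isinstance(ch, VoxelGrid) else np.asarray(ch)) for ch in image]


def _multichannel_features(image, cfg: FeatureBankConfig) -> np.ndarray:
    chans = _as_channels(image)
    stacks = [build_features(ch, cfg) for ch in chans]
    return np.concatenate(stacks, axis=-1)


def train(
    images: Sequence,
    sparse_labels: Sequence[np.ndarray],
    cfg: FeatureBankConfig | None = None,
    forest_params: dict | None = None,
    seed: int = 0,
    min_labels: int = 5,
    class_names: dict[int, str] | None = None,
) -> ClassifierModel:
    """Fit the forest on sparsely labeled pixels.

    ``sparse_labels[i]`` is an integer image aligned with ``images[i]``;
    0 marks unlabeled pixels, values >= 1 are class ids.  Every class named in
    *class_names* (or, failing that, at least two observed classes) must have
    at least *min_labels* labeled pixels.  Out-of-bag accuracy is stored on
    the returned model.
    """
    cfg = cfg or FeatureBankConfig()
    if len(images) != len(sparse_labels):
        raise ValueError("images and sparse_labels must have equal length")
    params = {"n_estimators": 100, "max_depth": None, "n_jobs": 1}
    params.update(forest_params or {})

    X_parts, y_parts = [], []
    n_channels = None
    for image, labels in zip(images, sparse_labels):
        labels = np.asarray(labels)
        chans = _as_channels(image)
        if n_channels is None:
            n_channels = len(chans)
        elif len(chans) != n_channels:
            raise ValueError("all training images must have the same channel count")
        if labels.shape != chans[0].shape:
            raise ValueError("label image shape must match the image")
        feats = _multichannel_features(image, cfg)
        sel = labels > 0
        X_parts.append(feats[sel])
        y_parts.append(labels[sel])
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts, axis=0)

    counts = {int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
    expected = set(class_names or {}) or set(counts)
    for cls in sorted(expected):
        if counts.get(cls, 0) < min_labels:
            name = (class_names or {}).get(cls, str(cls))
            raise ValueError(
                f"class {name!r} has {counts.get(cls, 0)} labeled pixels "
                f"(minimum {min_labels})"
            )
    if len(counts) < 2:
        raise ValueError(
            f"training needs at least 2 annotated classes, got {sorted(counts)}"
        )

    forest = RandomForestClassifier(
        random_state=seed, oob_score=True, bootstrap=True, **params
    )
    forest.fit(X, y)
    legend = class_names or {int(c): str(int(c)) for c in forest.classes_}
    return ClassifierModel(
        feature_config=cfg,
        forest=forest,
        classes=legend,
        n_channels=n_channels or 1,
        oob_accuracy=float(forest.oob_score_),
        forest_params=params,
    )


def predict(
    model: ClassifierModel,
    image,
    smooth_sigma: float = 0.0,
) -> tuple[np.ndarray, LabelMask]:
    """Classify every pixel of *image*.

    Returns ``(probabilities, mask)`` where probabilities has one trailing
    channel per class (summing to 1 per pixel) and the mask holds the argmax
    class id.  ``smooth_sigma > 0`` Gaussian-smooths the probability maps
    spatially before the argmax (structured-prediction stand-in).
    """
    chans = _as_channels(image)
    if len(chans) != model.n_channels:
        raise ValueError(
            f"model was trained on {model.n_channels} channel(s), got {len(chans)}"
        )
    spatial_shape = chans[0].shape
    feats = _multichannel_features(image, model.feature_config)
    if feats.shape[-1] != model.forest.n_features_in_:
        raise ValueError("feature bank does not match the trained forest")
    flat = feats.reshape(-1, feats.shape[-1])
    probs = model.forest.predict_proba(flat).reshape(*spatial_shape, -1)
    if smooth_sigma > 0:
        sigmas = (smooth_sigma,) * len(spatial_shape) + (0.0,)
        probs = ndi.gaussian_filter(probs, sigmas)
        total = probs.sum(axis=-1, keepdims=True)
        total[total == 0] = 1.0
        probs = probs / total
    class_ids = np.asarray(model.forest.classes_)
    mask_data = class_ids[np.argmax(probs, axis=-1)].astype(np.int32)
    spacing = (
        image.spacing
        if isinstance(image, VoxelGrid)
        else (chans[0].shape and (1.0,) * chans[0].ndim)
    )
    if not isinstance(image, VoxelGrid):
        first = image[0] if not isinstance(image, np.ndarray) else None
        if isinstance(first, VoxelGrid):
            spacing = first.spacing
    mask = LabelMask(mask_data, spacing, dict(model.classes))
    return probs, mask


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    """Persist a model as a single joblib archive (feature config + forest)."""
    path = Path(path)
    payload = {
        "feature_config": model.feature_config.to_dict(),
        "forest": model.forest,
        "classes": {int(k): v for k, v in model.classes.items()},
        "n_channels": model.n_channels,
        "oob_accuracy": model.oob_accuracy,
        "forest_params": model.forest_params,
    }
    joblib.dump(payload, path, compress=3)
    return path


def load_model(path: str | Path) -> ClassifierModel:
    payload = joblib.load(path)
    return ClassifierModel(
        feature_config=FeatureBankConfig.from_dict(payload["feature_config"]),
        forest=payload["forest"],
        classes={int(k): v for k, v in payload["classes"].items()},
        n_channels=payload["n_channels"],
        oob_accuracy=payload["oob_accuracy"],
        forest_params=payload.get("forest_params", {}),
    )
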