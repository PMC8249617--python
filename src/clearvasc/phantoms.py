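"""Seeded synthetic phantoms with exact ground truth.

Generates the three kinds of inputs the analysis pipelines consume:

* 3D "lectin" vessel volumes — solid thin tubes plus hollow, wall-labeled
  large tubes, with Gaussian/Poisson noise and depth attenuation;
* 3D "dextran" volumes — focal near-vessel extravasation blobs plus bright
  Z-elongated spindle artifacts mimicking axial out-of-focus light;
* 2D two-channel perfusion slides with a 4-class ground-truth map
  (0 background, 1 non-perfused, 2 underperfused, 3 perfused).

Everything is rendered in physical space (µm) and then sampled on the
requested anisotropic voxel lattice, so downstream code is exercised on
realistic calibrations.  One seeded generator per call; identical spec+seed
gives bit-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .imstore import LabelMask, VoxelGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_vessel_phantom",
    "make_spot_phantom",
    "make_perfusion_slide",
    "make_shrinkage_samples",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic sample.

    ``centerlines`` may be supplied explicitly (list of ``(points_um, radius_um)``
    with points of shape ``(k, ndim)``) to bypass the random-walk generator —
    used for analytic fixtures such as straight tubes.
    """

    shape: tuple[int, ...] = (32, 96, 96)
    spacing: tuple[float, ...] = (3.0, 0.69, 0.69)
    n_vessels: int = 4
    radius_range: tuple[float, float] = (3.0, 6.0)
    hollow_above: float = 10.0
    wall_thickness: float = 3.0
    n_spots: int = 0
    spot_radius_range: tuple[float, float] = (12.0, 20.0)
    n_artifacts: int = 0
    artifact_z_extent: float = 30.0
    noise_sd: float = 4.0
    poisson: bool = False
    attenuation_per_um: float = 0.0
    seed: int = 0
    # rendering intensities (8-bit scale)
    vessel_intensity: float = 200.0
    dextran_vessel_intensity: float = 90.0
    spot_intensity: float = 220.0
    artifact_intensity: float = 235.0
    background: float = 12.0
    class_proportions: tuple[float, float, float] = (0.25, 0.25, 0.5)
    centerlines: list[tuple[np.ndarray, float]] | None = None

    def validate(self) -> None:
        if len(self.shape) not in (2, 3) or len(self.spacing) != len(self.shape):
            raise ValueError("shape/spacing must both be 2D or 3D")
        if any(n <= 0 for n in self.shape):
            raise ValueError("shape entries must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")
        for name in ("n_vessels", "n_spots", "n_artifacts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("radius_range", "spot_radius_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        extent = self.extent
        if 2.0 * self.radius_range[1] > min(extent):
            raise ValueError(
                f"volume extent {extent} µm too small for max vessel radius "
                f"{self.radius_range[1]} µm"
            )

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical size of the lattice per axis, µm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def ndim(self) -> int:
        return len(self.shape)


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a phantom."""

    vessel_mask: LabelMask | None = None          # filled tubes
    wall_mask: LabelMask | None = None            # hollow-tube walls only
    centerlines: list[tuple[np.ndarray, float]] = field(default_factory=list)
    spot_records: list[dict] = field(default_factory=list)
    artifact_records: list[dict] = field(default_factory=list)
    class_map: LabelMask | None = None            # 2D slides only

    def summary(self) -> dict:
        return {
            "n_vessels": len(self.centerlines),
            "n_spots": len(self.spot_records),
            "n_artifacts": len(self.artifact_records),
            "spot_records": self.spot_records,
            "artifact_records": self.artifact_records,
        }


# ---------------------------------------------------------------------------
# geometry helpers


def _voxel_coords(shape: tuple[int, ...], spacing: tuple[float, ...]) -> np.ndarray:
    """Physical coordinates of every voxel, shape (N, ndim)."""
    grids = np.indices(shape, dtype=np.float64)
    for ax, s in enumerate(spacing):
        grids[ax] *= s
    return grids.reshape(len(shape), -1).T


def _random_centerline(
    rng: np.random.Generator,
    extent: Sequence[float],
    radius: float,
    step: float = 8.0,
    bend: float = 0.35,
) -> np.ndarray:
    """Cubic-smoothed bounded-curvature random walk within the volume, µm."""
    ndim = len(extent)
    margin = np.minimum(radius, np.asarray(extent) / 4)
    lo, hi = margin, np.asarray(extent) - margin
    pos = rng.uniform(lo, hi)
    d = rng.normal(size=ndim)
    d /= np.linalg.norm(d)
    pts = [pos.copy()]
    max_steps = int(2 * max(extent) / step) + 4
    for _ in range(max_steps):
        d = d + bend * rng.normal(size=ndim)
        d /= np.linalg.norm(d)
        pos = pos + step * d
        if np.any(pos < lo) or np.any(pos > hi):
            break
        pts.append(pos.copy())
    pts = np.asarray(pts)
    if len(pts) < 4:  # too short a walk: fall back to a straight chord
        end = rng.uniform(lo, hi)
        pts = np.linspace(pts[0], end, 6)
    t = np.arange(len(pts), dtype=float)
    return CubicSpline(t, pts, axis=0)(np.linspace(0, len(pts) - 1, 4 * len(pts)))


def _densify(points: np.ndarray, ds: float) -> np.ndarray:
    """Resample a polyline at arc-length intervals of roughly *ds* µm."""
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if total <= 0:
        return points[:1]
    n = max(int(np.ceil(total / ds)) + 1, 2)
    si = np.linspace(0.0, total, n)
    out = np.empty((n, points.shape[1]))
    for ax in range(points.shape[1]):
        out[:, ax] = np.interp(si, s, points[:, ax])
    return out


def _render_tubes(
    spec: PhantomSpec,
    centerlines: list[tuple[np.ndarray, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelize tubes.  Returns (filled_mask, wall_mask, lit_mask).

    ``lit_mask`` marks voxels that carry label intensity: whole tube for solid
    vessels, the wall shell only for hollow ones.
    """
    shape, spacing = spec.shape, spec.spacing
    filled = np.zeros(shape, dtype=bool)
    wall = np.zeros(shape, dtype=bool)
    lit = np.zeros(shape, dtype=bool)
    if not centerlines:
        return filled, wall, lit

    ds = 0.5 * min(spacing)
    samples, radii, hollow_flags = [], [], []
    for pts, radius in centerlines:
        dense = _densify(np.asarray(pts, dtype=float), ds)
        samples.append(dense)
        radii.append(np.full(len(dense), radius))
        hollow_flags.append(np.full(len(dense), radius > spec.hollow_above))
    samples = np.vstack(samples)
    radii = np.concatenate(radii)
    hollow_flags = np.concatenate(hollow_flags)

    coords = _voxel_coords(shape, spacing)
    tree = cKDTree(samples)
    dist, idx = tree.query(coords, k=1, workers=-1)
    r = radii[idx]
    inside = dist <= r
    filled = inside.reshape(shape)
    is_wall = inside & hollow_flags[idx] & (dist > r - spec.wall_thickness)
    wall = is_wall.reshape(shape)
    lit = (inside & (~hollow_flags[idx] | is_wall)).reshape(shape)
    return filled, wall, lit


def _finish_channel(
    spec: PhantomSpec, img: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Apply depth attenuation, noise and 8-bit quantization."""
    out = img.astype(np.float64)
    if spec.ndim == 3 and spec.attenuation_per_um > 0:
        depth = np.arange(spec.shape[0], dtype=float) * spec.spacing[0]
        out *= np.exp(-spec.attenuation_per_um * depth)[:, None, None]
    if spec.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if spec.noise_sd > 0:
        out += rng.normal(0.0, spec.noise_sd, size=out.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# public generators


def make_vessel_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Render the vessel ("lectin") channel and its exact ground truth.

    Tubes follow smooth random polylines (or ``spec.centerlines`` when given).
    Tubes with radius above ``spec.hollow_above`` are lit only in a wall shell
    of ``spec.wall_thickness``; the ground-truth ``vessel_mask`` is always the
    filled tube.
    """
    spec.validate()
    if spec.ndim != 3:
        raise ValueError("make_vessel_phantom needs a 3D shape")
    rng = np.random.default_rng((spec.seed, 1))

    if spec.centerlines is not None:
        centerlines = [(np.asarray(p, dtype=float), float(r)) for p, r in spec.centerlines]
    else:
        centerlines = []
        for _ in range(spec.n_vessels):
            radius = rng.uniform(*spec.radius_range)
            pts = _random_centerline(rng, spec.extent, radius)
            centerlines.append((pts, radius))

    filled, wall, lit = _render_tubes(spec, centerlines)
    img = np.full(spec.shape, spec.background, dtype=np.float64)
    img[lit] = spec.vessel_intensity
    channel = VoxelGrid(_finish_channel(spec, img, rng), spec.spacing, "lectin")
    truth = PhantomTruth(
        vessel_mask=LabelMask(filled.astype(np.uint8), spec.spacing, {1: "vessel"}),
        wall_mask=LabelMask(wall.astype(np.uint8), spec.spacing, {1: "wall"}),
        centerlines=centerlines,
    )
    return channel, truth


def _render_ellipsoid(
    canvas: np.ndarray,
    spacing: tuple[float, ...],
    center: np.ndarray,
    semi_axes: np.ndarray,
    value: float,
) -> int:
    """Paint an axis-aligned ellipsoid; returns the voxel count painted."""
    shape = canvas.shape
    lo = np.maximum(np.floor((center - semi_axes) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + semi_axes) / spacing).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return 0
    slices = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.indices(tuple(b - a for a, b in zip(lo, hi)), dtype=np.float64)
    for ax in range(len(shape)):
        grids[ax] = (grids[ax] + lo[ax]) * spacing[ax]
    q = np.zeros(grids.shape[1:])
    for ax in range(len(shape)):
        q += ((grids[ax] - center[ax]) / semi_axes[ax]) ** 2
    inside = q <= 1.0
    region = canvas[slices]
    region[inside] = np.maximum(region[inside], value)
    canvas[slices] = region
    return int(inside.sum())


def make_spot_phantom(
    spec: PhantomSpec, truth: PhantomTruth
) -> tuple[VoxelGrid, PhantomTruth]:
    """Render the tracer ("dextran") channel: vessels dim, spots and artifacts bright.

    Spherical extravasation spots are placed adjacent to vessel centerlines;
    bright Z-elongated spindles (axial out-of-focus artifacts) sit on vessel
    voxels and are kept below 10,000 µm³ true volume.  If free space runs out
    fewer objects are placed; the truth records reflect the actual counts.
    """
    spec.validate()
    if truth.vessel_mask is None or not truth.centerlines:
        if spec.n_spots > 0 or spec.n_artifacts > 0:
            raise ValueError("spot phantom requires vessel truth with centerlines")
    rng = np.random.default_rng((spec.seed, 2))
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = np.asarray(spec.extent)

    img = np.full(spec.shape, spec.background, dtype=np.float64)
    if truth.vessel_mask is not None:
        # dim baseline: residual tracer in the vasculature
        lit = truth.vessel_mask.binary()
        img[lit] = spec.dextran_vessel_intensity

    truth2 = copy.copy(truth)
    truth2.spot_records = []
    truth2.artifact_records = []

    dense_lines = [
        (_densify(np.asarray(p, dtype=float), 2.0), r) for p, r in truth.centerlines
    ]
    placed_spots: list[tuple[np.ndarray, float]] = []
    placed_artifacts: list[tuple[np.ndarray, float]] = []

    def far_enough(c: np.ndarray, r: float, placed, gap: float) -> bool:
        return all(np.linalg.norm(c - pc) >= r + pr + gap for pc, pr in placed)

    # --- spots -------------------------------------------------------------
    # generous separation: the postprocessing dilation + 3D smoothing grows
    # objects by several µm (most along z, where the Gaussian tails of two
    # neighbours add up), and merged spots would corrupt the ground truth
    for _ in range(spec.n_spots):
        for _attempt in range(500):
            pts, vr = dense_lines[rng.integers(len(dense_lines))]
            anchor = pts[rng.integers(len(pts))]
            r = rng.uniform(*spec.spot_radius_range)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            center = anchor + u * (vr + 0.7 * r)
            margin = np.array([r + 6.0, 0.6 * r, 0.6 * r])
            if np.any(center < margin) or np.any(center > extent - margin):
                continue
            if not far_enough(center, r, placed_spots, 32.0):
                continue
            count = _render_ellipsoid(
                img, spec.spacing, center, np.full(3, r), spec.spot_intensity
            )
            if count == 0:
                continue
            placed_spots.append((center, r))
            truth2.spot_records.append(
                {
                    "centroid_um": center.tolist(),
                    "radius_um": float(r),
                    "volume_um3": count * float(np.prod(spacing)),
                }
            )
            break

    # --- PSF-like spindle artifacts ---------------------------------------
    vessel_idx = (
        np.argwhere(truth.vessel_mask.binary()) if truth.vessel_mask is not None else None
    )
    for _ in range(spec.n_artifacts):
        if vessel_idx is None or len(vessel_idx) == 0:
            break
        for _attempt in range(1000):
            vox = vessel_idx[rng.integers(len(vessel_idx))]
            center = vox * spacing
            c = spec.artifact_z_extent / 2.0
            # thin spindle: true volume well below the 10,000 µm³ exclusion
            # bound so it stays below it even after dilation-based postprocessing
            target_vol = rng.uniform(600.0, 2000.0)
            a = np.sqrt(3.0 * target_vol / (4.0 * np.pi * c))
            if np.any(center < (c, a, a)) or np.any(center > extent - (c, a, a)):
                continue
            # artifact-artifact merges would leak a >bound component, so keep
            # them far apart; a merge into a much larger spot is harmless
            if not far_enough(center, max(a, c), placed_artifacts, 30.0):
                continue
            if not far_enough(center, max(a, c), placed_spots, 20.0):
                continue
            count = _render_ellipsoid(
                img, spec.spacing, center, np.array([c, a, a]), spec.artifact_intensity
            )
            if count == 0:
                continue
            placed_artifacts.append((center, max(a, c)))
            truth2.artifact_records.append(
                {
                    "centroid_um": center.tolist(),
                    "semi_axes_um": [float(c), float(a), float(a)],
                    "volume_um3": count * float(np.prod(spacing)),
                }
            )
            break

    channel = VoxelGrid(_finish_channel(spec, img, rng), spec.spacing, "dextran")
    return channel, truth2


def make_perfusion_slide(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, VoxelGrid, PhantomTruth]:
    """Render a 2D two-channel perfusion slide with an exact 4-class map.

    Vessel curves are assigned classes by ``spec.class_proportions`` over
    {1 non-perfused, 2 underperfused, 3 perfused}.  Class 1 is bright only in
    the dextran channel, class 3 only in the lectin channel, class 2 in both
    with a dextran intensity drawn below the class-1 mean.
    """
    spec.validate()
    if spec.ndim != 2:
        raise ValueError("make_perfusion_slide needs a 2D shape")
    props = np.asarray(spec.class_proportions, dtype=float)
    if np.any(props < 0) or props.sum() <= 0:
        raise ValueError("class_proportions must be non-negative and sum > 0")
    props = props / props.sum()
    rng = np.random.default_rng((spec.seed, 3))

    radius = float(np.mean(spec.radius_range))
    dextran = np.full(spec.shape, spec.background, dtype=np.float64)
    lectin = np.full(spec.shape, spec.background, dtype=np.float64)
    class_map = np.zeros(spec.shape, dtype=np.uint8)

    coords = _voxel_coords(spec.shape, spec.spacing)
    for _ in range(spec.n_vessels):
        cls = int(rng.choice((1, 2, 3), p=props))
        pts = _densify(
            _random_centerline(rng, spec.extent, radius, step=12.0),
            0.5 * min(spec.spacing),
        )
        dist, _ = cKDTree(pts).query(coords, k=1, workers=-1)
        inside = (dist <= radius).reshape(spec.shape)
        class_map[inside] = cls
        # overwrite BOTH channels so crossings keep consistent intensities
        if cls == 1:
            dextran[inside] = rng.normal(200.0, 5.0)
            lectin[inside] = spec.background
        elif cls == 2:
            dextran[inside] = rng.normal(120.0, 5.0)
            lectin[inside] = rng.normal(185.0, 5.0)
        else:
            dextran[inside] = spec.background
            lectin[inside] = rng.normal(200.0, 5.0)

    dex = VoxelGrid(_finish_channel(spec, dextran, rng), spec.spacing, "dextran")
    lec = VoxelGrid(_finish_channel(spec, lectin, rng), spec.spacing, "lectin")
    legend = {0: "background", 1: "non-perfused", 2: "underperfused", 3: "perfused"}
    truth = PhantomTruth(class_map=LabelMask(class_map, spec.spacing, legend))
    return dex, lec, truth


def make_shrinkage_samples(
    n: int,
    ocs_change: float = -71.0,
    cps_change: float = -12.0,
    sd: float = 2.0,
    seed: int = 0,
) -> tuple[list[float], list[float]]:
    """Draw per-sample volume-change percentages for the two preparation groups.

    Returns (optically-cleared, conventionally-prepared) lists of length *n*,
    normally distributed around the stated mean changes.
    """
    if n < 1:
        raise ValueError("need at least one sample per group")
    rng = np.random.default_rng((seed, 4))
    ocs = rng.normal(ocs_change, sd, size=n)
    cps = rng.normal(cps_change, sd, size=n)
    return ocs.tolist(), cps.tolist()
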