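"""Transcardial-perfusion-degree quantification on 2D class maps.

Per-section class-area accounting over the 4-class segmentation
(0 background, 1 non-perfused, 2 underperfused, 3 perfused), tumor-level
weighted averages, per-class intensity statistics, the arcsine transform for
downstream proportion statistics, and the tissue volume-change correction
between optically cleared (OCS) and conventionally prepared (CPS) samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imstore import LabelMask, VoxelGrid

VASCULAR_CLASSES = (1, 2, 3)
CLASS_NAMES = {1: "non_perfused", 2: "underperfused", 3: "perfused"}


@dataclass
class SectionQuant:
    """Per-section vascular class areas and percentages."""

    section_id: str
    areas_um2: dict[int, float]           # class -> area
    total_vascular_area_um2: float
    percentages: dict[int, float]         # class -> % of total vascular area
    empty: bool = False                   # no vascular pixels in the ROI


def quantify_section(
    class_mask: LabelMask,
    roi_mask: LabelMask | np.ndarray | None = None,
    section_id: str = "",
) -> SectionQuant:
    """Class areas (µm²) and percentages of total vascular area within a ROI.

    Background (class 0) is excluded from the vascular total.  An empty ROI or
    an all-background mask yields a zero-area record flagged ``empty`` with
    all percentages reported as 0.
    """
    data = class_mask.data
    bad = np.setdiff1d(np.unique(data), (0,) + VASCULAR_CLASSES)
    if bad.size:
        raise ValueError(f"class mask contains unexpected values {bad.tolist()}")
    if roi_mask is not None:
        roi = roi_mask.binary() if isinstance(roi_mask, LabelMask) else np.asarray(roi_mask, bool)
        if roi.shape != data.shape:
            raise ValueError("ROI shape does not match the class mask")
        if not roi.any():
            warnings.warn("empty ROI: zero-area section record", stacklevel=2)
        data = np.where(roi, data, 0)
    px_area = class_mask.voxel_volume  # 2D -> pixel area
    counts = np.bincount(data.ravel(), minlength=4)
    areas = {c: float(counts[c]) * px_area for c in VASCULAR_CLASSES}
    total = float(sum(areas.values()))
    if total > 0:
        pct = {c: 100.0 * areas[c] / total for c in VASCULAR_CLASSES}
        empty = False
    else:
        pct = {c: 0.0 for c in VASCULAR_CLASSES}
        empty = True
    return SectionQuant(section_id or "section", areas, total, pct, empty)


def tumor_weighted_summary(sections: list[SectionQuant]) -> dict[int, float]:
    """Tumor-level percentages: sections weighted by their vascular area.

    Sections with zero vascular area are skipped.  Raises if every section is
    empty.
    """
    if not sections:
        raise ValueError("need at least one section")
    weighted = [s for s in sections if s.total_vascular_area_um2 > 0]
    if not weighted:
        raise ValueError("all sections have zero vascular area")
    total_weight = sum(s.total_vascular_area_um2 for s in weighted)
    return {
        c: sum(s.percentages[c] * s.total_vascular_area_um2 for s in weighted) / total_weight
        for c in VASCULAR_CLASSES
    }


def class_intensity_stats(
    intensity: VoxelGrid, class_mask: LabelMask
) -> dict[int, float]:
    """Mean pixel intensity per vascular class; absent classes are omitted."""
    if intensity.shape != class_mask.shape:
        raise ValueError(
            f"intensity {intensity.shape} and class mask {class_mask.shape} differ"
        )
    out = {}
    for c in VASCULAR_CLASSES:
        sel = class_mask.data == c
        if sel.any():
            out[c] = float(intensity.data[sel].mean())
    return out


def arcsine_transform(p):
    """Variance-stabilizing transform for proportions: ``asin(sqrt(p))``."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass
class ShrinkageCorrection:
    """Tissue volume-change correction between preparation methods.

    ``CF = med(OCS) - med(CPS)`` where each median is over per-sample volume
    change percentages.  ``apply`` rescales an optically-cleared sample volume
    to its sectioned-preparation equivalent via
    ``(100 + med_cps) / (100 + med_ocs)``.
    """

    med_ocs: float
    med_cps: float
    CF: float = field(init=False)

    def __post_init__(self) -> None:
        self.CF = self.med_ocs - self.med_cps

    def apply(self, volume: float) -> float:
        if self.med_ocs == -100.0:
            raise ZeroDivisionError("med(OCS) = -100% leaves zero residual volume")
        return volume * (100.0 + self.med_cps) / (100.0 + self.med_ocs)


def shrinkage_correction(
    ocs_changes: list[float], cps_changes: list[float]
) -> ShrinkageCorrection:
    """Medians of per-sample volume-change percentages and their difference."""
    if not len(ocs_changes) or not len(cps_changes):
        raise ValueError("each group needs at least one sample")
    return ShrinkageCorrection(
        med_ocs=float(np.median(ocs_changes)),
        med_cps=float(np.median(cps_changes)),
    )
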