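"""Calibrated image containers, TIFF I/O and result serialization.

All images are carried as :class:`VoxelGrid` (one channel, physical voxel
spacing in micrometres) or :class:`LabelMask` (integer class map aligned to a
grid).  Axis order is fixed as ``(z, y, x)`` for 3D and ``(y, x)`` for 2D,
indices are 0-based, and the physical coordinate of a voxel is
``index * spacing`` (voxel-corner origin).  All physical quantities are in
µm / µm² / µm³ unless stated otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class CalibrationError(ValueError):
    """Raised when physical voxel spacing is required but unavailable."""


class FormatError(ValueError):
    """Raised for unsupported on-disk image layouts or output formats."""


@dataclass
class VoxelGrid:
    """A single-channel 2D or 3D intensity image with physical calibration.

    Parameters
    ----------
    data:
        2D ``(y, x)`` or 3D ``(z, y, x)`` array.
    spacing:
        µm per axis, same order and length as ``data.ndim``.
    channel_name:
        Free-text channel label (e.g. ``"lectin"``, ``"dextran"``).
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise FormatError(f"expected a 2D or 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for a {self.data.ndim}D image"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume (3D, µm³) or area (2D, µm²) of one voxel."""
        return float(np.prod(self.spacing))

    @property
    def dtype_bits(self) -> int:
        return self.data.dtype.itemsize * 8


@dataclass
class LabelMask:
    """Integer class map aligned to a :class:`VoxelGrid` lattice."""

    data: np.ndarray
    spacing: tuple[float, ...]
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer) and self.data.dtype != bool:
            raise FormatError("LabelMask data must be integer or boolean")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match mask dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def binary(self) -> np.ndarray:
        """Boolean view: any nonzero label is foreground."""
        return self.data.astype(bool)


def as_binary(mask: LabelMask | np.ndarray, *, op: str = "operation") -> np.ndarray:
    """Validate that *mask* holds only values {0, 1} and return a bool array."""
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{op} requires a binary mask; found values {vals[:10]}")
    return data.astype(bool)


# ---------------------------------------------------------------------------
# TIFF stack I/O


def write_stack(grid: VoxelGrid | LabelMask, path: str | Path) -> Path:
    """Write a grid as a single-channel (OME-ish ImageJ) TIFF with spacing tags.

    XY spacing is stored in the TIFF resolution tags (pixels per µm), Z spacing
    in the ImageJ ``spacing`` metadata field.  A JSON sidecar is not needed for
    round-trips through :func:`read_stack`.
    """
    path = Path(path)
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        data = data.astype(np.float32)
    if data.ndim == 3:
        dz, dy, dx = grid.spacing
        meta = {"spacing": dz, "unit": "um"}
    else:
        dy, dx = grid.spacing
        meta = {"unit": "um"}
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata=meta,
    )
    return path


def _spacing_from_tiff(tif: tifffile.TiffFile, ndim: int) -> tuple[float, ...] | None:
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    if dx <= 0 or dy <= 0:
        return None
    if ndim == 2:
        return (dy, dx)
    meta = tif.imagej_metadata or {}
    dz = meta.get("spacing")
    if dz is None or dz <= 0:
        return None
    return (float(dz), dy, dx)


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, ...] | None = None,
    channel_name: str = "",
) -> VoxelGrid:
    """Read a single-channel TIFF/OME-TIFF stack into a :class:`VoxelGrid`.

    Spacing is taken from file metadata when present, otherwise from
    ``spacing_override``; if neither is available a :class:`CalibrationError`
    is raised.  RGB / multi-sample files are rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise FormatError(
                f"{path.name}: expected one sample per pixel, "
                f"got {page.samplesperpixel} (RGB/multi-channel not supported)"
            )
        data = tif.asarray()
        if data.ndim not in (2, 3):
            raise FormatError(f"{path.name}: expected a 2D/3D stack, got shape {data.shape}")
        spacing = _spacing_from_tiff(tif, data.ndim)
    if spacing is None:
        if spacing_override is None:
            raise CalibrationError(
                f"{path.name}: no voxel spacing in metadata and no override given"
            )
        spacing = tuple(spacing_override)
    return VoxelGrid(data=data, spacing=spacing, channel_name=channel_name)


# ---------------------------------------------------------------------------
# Intensity normalization


def to_8bit(grid: VoxelGrid, low_pct: float = 0.0, high_pct: float = 100.0) -> VoxelGrid:
    """Rescale the ``[p_low, p_high]`` percentile window linearly to [0, 255].

    Values outside the window are clipped.  8-bit input with the full (0, 100)
    window is passed through unchanged.  A constant image maps to all zeros
    (with a warning) because the window is degenerate.
    """
    if high_pct <= low_pct:
        raise ValueError(f"high_pct must exceed low_pct, got ({low_pct}, {high_pct})")
    if grid.data.dtype == np.uint8 and low_pct == 0.0 and high_pct == 100.0:
        return grid
    lo, hi = np.percentile(grid.data, (low_pct, high_pct))
    if hi <= lo:
        warnings.warn("constant intensity window; output is all zeros", stacklevel=2)
        out = np.zeros(grid.shape, dtype=np.uint8)
    else:
        scaled = (grid.data.astype(np.float64) - lo) / (hi - lo)
        out = np.clip(np.round(scaled * 255.0), 0, 255).astype(np.uint8)
    return VoxelGrid(out, grid.spacing, grid.channel_name)


# ---------------------------------------------------------------------------
# Tabular / graph serialization


def write_table(table: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write a records table (e.g. per-spot morphometry) to disk."""
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "json":
        table.to_json(path, orient="records", indent=2)
    else:
        raise FormatError(f"unknown table format {fmt!r}")
    return path


def write_graph(graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Serialize a vessel graph as GraphML (lossless) or SWC-like text.

    GraphML stores node positions/degrees and full per-segment attributes,
    with polylines/radii JSON-encoded so the file round-trips through
    :func:`read_graph`.  The SWC writer emits one point per polyline sample
    (``id type x y z radius parent``); branching graphs share junction points.
    """
    import networkx as nx

    path = Path(path)
    if fmt == "graphml":
        g = nx.MultiGraph()
        g.graph["mask_volume_um3"] = float(getattr(graph, "mask_volume_um3", 0.0))
        for nid, node in graph.nodes.items():
            pos = np.asarray(node.position, dtype=float)
            g.add_node(nid, degree=int(node.degree), position=json.dumps(pos.tolist()))
        for seg in graph.segments:
            g.add_edge(
                seg.u,
                seg.v,
                key=seg.id,
                seg_id=int(seg.id),
                length_um=float(seg.length),
                chord_um=float(seg.chord),
                tortuosity=float(seg.tortuosity),
                mean_diameter_um=float(seg.mean_diameter),
                points=json.dumps(np.asarray(seg.points, dtype=float).tolist()),
                radii=json.dumps(np.asarray(seg.radii, dtype=float).tolist()),
            )
        nx.write_graphml(g, path)
    elif fmt == "swc":
        lines = ["# id type x y z radius parent  (positions in um, z/y/x from axis order)"]
        counter = 1
        node_swc_id: dict[int, int] = {}
        for seg in graph.segments:
            pts = np.asarray(seg.points, dtype=float)
            radii = np.asarray(seg.radii, dtype=float)
            parent = node_swc_id.get(seg.u, -1)
            for i, (p, r) in enumerate(zip(pts, radii)):
                z, y, x = (p if len(p) == 3 else (0.0, *p))
                lines.append(
                    f"{counter} 0 {x:.3f} {y:.3f} {z:.3f} {r:.3f} {parent}"
                )
                if i == 0 and seg.u not in node_swc_id:
                    node_swc_id[seg.u] = counter
                parent = counter
                counter += 1
            # last emitted point stands for the closing node of the segment
            node_swc_id.setdefault(seg.v, counter - 1)
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise FormatError(f"unknown graph format {fmt!r}")
    return path


def read_graph(path: str | Path):
    """Read a GraphML file written by :func:`write_graph` back into a graph."""
    import networkx as nx

    from .vasculature import GraphNode, Segment, VesselGraph

    g = nx.read_graphml(path, force_multigraph=True)
    nodes = {}
    for nid, attrs in g.nodes(data=True):
        nodes[int(nid)] = GraphNode(
            id=int(nid),
            position=np.asarray(json.loads(attrs["position"]), dtype=float),
            degree=int(attrs["degree"]),
        )
    segments = []
    for u, v, attrs in g.edges(data=True):
        segments.append(
            Segment(
                id=int(attrs["seg_id"]),
                u=int(u),
                v=int(v),
                points=np.asarray(json.loads(attrs["points"]), dtype=float),
                radii=np.asarray(json.loads(attrs["radii"]), dtype=float),
            )
        )
    segments.sort(key=lambda s: s.id)
    return VesselGraph(
        nodes=nodes,
        segments=segments,
        mask_volume_um3=float(g.graph.get("mask_volume_um3", 0.0)),
    )
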