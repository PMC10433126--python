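"""Volumes, (BED-)dose-volume histograms, plan-quality metrics, iso-surfaces.

All operations accept either a :class:`~bed3d.dose.DoseGrid`, a
:class:`~bed3d.bed.BEDGrid`, or a bare ndarray with a :class:`GridSpec`.
Volumes are voxel counts times the voxel volume (point-in/point-out at
voxel centers; no partial-volume weighting).  Cumulative histograms use the
at-or-above (>=) planning convention.

Conformity and gradient indices follow the standard stereotactic
definitions: Paddick CI = TV_PIV^2 / (TV * PIV) and GI = V_{p/2} / V_p,
applied identically to dose and BED fields (the prescription level is then
in Gy or Gy_{alpha/beta} respectively).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .bed import BEDGrid
from .dose import DoseGrid, GridSpec
from .errors import EmptyMeshError, ShapeMismatchError, UndefinedMetricError, ValidationError

__all__ = [
    "StructureMask",
    "Histogram",
    "IsoSurfaceMesh",
    "mask_volume",
    "dvh",
    "isolevel_volume",
    "paddick_ci",
    "gradient_index",
    "percent_volume_at",
    "extract_isosurface",
]

DEFAULT_BIN_WIDTH = 0.5  # Gy (or Gy_{alpha/beta})


@dataclass
class StructureMask:
    """Binary voxel mask of a target or organ-at-risk on a grid."""

    spec: GridSpec
    voxels: np.ndarray
    label: str = "structure"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.shape != self.spec.shape:
            raise ShapeMismatchError(
                f"mask shape {self.voxels.shape} != grid shape {self.spec.shape}"
            )


@dataclass
class Histogram:
    """Differential and cumulative volume histogram of a scalar field.

    ``differential_volume[k]`` is the structure volume (mm^3) with values in
    the half-open bin [edges[k], edges[k+1]); ``cumulative_volume[k]`` is
    the volume with value >= edges[k] (so entry 0 is the full structure
    volume and the last entry is 0).
    """

    bin_edges: np.ndarray
    differential_volume: np.ndarray
    cumulative_volume: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "edge": self.bin_edges,
                "differential_mm3": np.append(self.differential_volume, 0.0),
                "cumulative_mm3": self.cumulative_volume,
            }
        )


@dataclass
class IsoSurfaceMesh:
    """Triangulated iso-surface in Leksell mm."""

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    iso_level: float
    quantity: str  # "dose" | "bed" | "scalar"

    def enclosed_volume(self) -> float:
        """Volume by the divergence theorem (sum of signed tetrahedra)."""
        v = self.vertices[self.faces]
        signed = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0
        return float(abs(signed.sum()))


def _values_spec(grid, spec: GridSpec | None = None):
    if isinstance(grid, (DoseGrid, BEDGrid)):
        return grid.values, grid.spec
    arr = np.asarray(grid, float)
    if spec is None:
        raise ValidationError("a GridSpec is required with a bare array")
    return arr, spec


def _quantity(grid) -> str:
    if isinstance(grid, DoseGrid):
        return "dose"
    if isinstance(grid, BEDGrid):
        return "bed"
    return "scalar"


def mask_volume(mask: StructureMask) -> float:
    """Structure volume (mm^3): set-voxel count times voxel volume."""
    n = int(mask.voxels.sum())
    if n == 0:
        warnings.warn(f"mask {mask.label!r} is empty", stacklevel=2)
    return n * mask.spec.voxel_volume


def dvh(grid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH) -> Histogram:
    """(BED-)dose-volume histogram of ``grid`` inside ``mask``."""
    values, spec = _values_spec(grid, getattr(mask, "spec", None))
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    if values.shape != mask.voxels.shape:
        raise ShapeMismatchError(
            f"grid shape {values.shape} != mask shape {mask.voxels.shape}"
        )
    sel = values[mask.voxels]
    vmax = float(sel.max()) if sel.size else 0.0
    # half-open bins [lo, hi); one trailing bin keeps the maximum interior
    n_bins = int(np.floor(vmax / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(sel, bins=edges)
    diff = counts * spec.voxel_volume
    cum = np.append(np.cumsum(diff[::-1])[::-1], 0.0)
    return Histogram(bin_edges=edges, differential_volume=diff,
                     cumulative_volume=cum)


def isolevel_volume(grid, level: float, spec: GridSpec | None = None) -> float:
    """Volume (mm^3) of the whole-grid region with value >= level."""
    if level <= 0:
        raise ValidationError("iso level must be > 0")
    values, spec = _values_spec(grid, spec)
    return int((values >= level).sum()) * spec.voxel_volume


def paddick_ci(grid, mask: StructureMask, prescription_level: float) -> float:
    """Paddick conformity index CI = TV_PIV^2 / (TV * PIV)."""
    values, spec = _values_spec(grid, mask.spec)
    if values.shape != mask.voxels.shape:
        raise ShapeMismatchError("grid and mask shapes differ")
    tv = int(mask.voxels.sum())
    if tv == 0:
        raise UndefinedMetricError("conformity index is undefined for an empty mask")
    piv_vox = values >= prescription_level
    piv = int(piv_vox.sum())
    if piv == 0:
        raise UndefinedMetricError(
            f"prescription iso-level {prescription_level} encloses no volume"
        )
    tv_piv = int((piv_vox & mask.voxels).sum())
    return tv_piv**2 / (tv * piv)


def gradient_index(grid, prescription_level: float,
                   spec: GridSpec | None = None) -> float:
    """Gradient index GI = V(level/2) / V(level), >= 1 by construction."""
    v_p = isolevel_volume(grid, prescription_level, spec)
    if v_p == 0:
        raise UndefinedMetricError(
            f"prescription iso-level {prescription_level} encloses no volume"
        )
    return isolevel_volume(grid, prescription_level / 2.0, spec) / v_p


def percent_volume_at(grid, mask: StructureMask, level: float) -> float:
    """Percent of the structure volume receiving at least ``level``."""
    values, _ = _values_spec(grid, mask.spec)
    if values.shape != mask.voxels.shape:
        raise ShapeMismatchError("grid and mask shapes differ")
    tv = int(mask.voxels.sum())
    if tv == 0:
        raise UndefinedMetricError("percent volume is undefined for an empty mask")
    return 100.0 * int((values[mask.voxels] >= level).sum()) / tv


def extract_isosurface(grid, level: float, spec: GridSpec | None = None) -> IsoSurfaceMesh:
    """Marching-cubes triangulation of the iso-level surface, in Leksell mm.

    The level must lie strictly between the field's minimum and maximum.
    The mesh is watertight whenever the level set stays off the grid
    boundary.
    """
    values, spec = _values_spec(grid, spec)
    vmin, vmax = float(values.min()), float(values.max())
    if not vmin < level < vmax:
        raise EmptyMeshError(
            f"iso level {level} outside the field's value range ({vmin}, {vmax})"
        )
    s = spec.spacing
    verts, faces, _, _ = measure.marching_cubes(values, level=level,
                                                spacing=(s, s, s))
    # marching_cubes places voxel index i at coordinate i*s; voxel centers
    # live at (i+1)*s in the Leksell convention
    verts = verts + s
    return IsoSurfaceMesh(vertices=verts, faces=faces, iso_level=float(level),
                          quantity=_quantity(grid))
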