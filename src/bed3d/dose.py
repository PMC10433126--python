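"""Physical-dose computation on the Leksell calculation matrix.

Each shot i deposits dose

    d_i(x, y, z) = dose_rate_i * duration_i * F_L(L(x, y, z)),

where L is the ellipsoid-expansion coefficient

    L = (FWHM_x * FWHM_y * FWHM_z)^(1/3)
        * sqrt(((x-x_i)/FWHM_x)^2 + ((y-y_i)/FWHM_y)^2 + ((z-z_i)/FWHM_z)^2)

mapping a 3D offset from the isocenter to an equivalent radial position on
the collimator's falloff curve F_L.  L equals the Euclidean offset when the
three FWHMs are equal, and the half-maximum iso-dose surface is the
ellipsoid with semiaxes FWHM/2.

Grid convention: voxel (i, j, k) (zero-based) has its CENTER at Leksell
coordinate ((i+1)*spacing, (j+1)*spacing, (k+1)*spacing) mm, so with the
default 200 voxels at 1 mm the frame center (100, 100, 100) coincides with
the center of voxel (99, 99, 99) and the sampled peak equals the true peak.
Dose is point-sampled at voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .profiles import COLLIMATOR_LABELS, CollimatorModel, evaluate_profile

__all__ = [
    "Shot",
    "Plan",
    "GridSpec",
    "DoseGrid",
    "SparseField",
    "ellipsoid_coefficient",
    "shot_contour",
    "shot_dose_field",
    "accumulate_dose",
]


@dataclass(frozen=True)
class Shot:
    """One focal irradiation: collimator, isocenter, dose rate, timing.

    ``dose_rate`` is the rate at the profile maximum (Gy/min); ``duration``
    is the beam-on time (min); ``gap_after`` is the pause before the next
    shot (min).
    """

    index: int
    collimator_label: int
    isocenter: tuple[float, float, float]
    dose_rate: float
    duration: float
    gap_after: float = 0.0

    def validate(self) -> None:
        if self.collimator_label not in COLLIMATOR_LABELS:
            raise ValidationError(
                f"shot {self.index}: unknown collimator {self.collimator_label!r}"
            )
        if self.duration <= 0:
            raise ValidationError(
                f"shot {self.index}: duration must be > 0 min (the protraction "
                "factor divides by the beam-on time); model an acute shot with "
                "a small positive duration"
            )
        if self.dose_rate <= 0:
            raise ValidationError(f"shot {self.index}: dose_rate must be > 0")
        if self.gap_after < 0:
            raise ValidationError(f"shot {self.index}: gap_after must be >= 0")
        if len(self.isocenter) != 3:
            raise ValidationError(f"shot {self.index}: isocenter must be 3D")
        if not all(0.0 <= c <= 200.0 for c in self.isocenter):
            raise ValidationError(
                f"shot {self.index}: isocenter {self.isocenter} outside the "
                "[0, 200] mm Leksell range"
            )

    @property
    def peak_dose(self) -> float:
        """Dose at the isocenter, dose_rate * duration (Gy)."""
        return self.dose_rate * self.duration


@dataclass(frozen=True)
class Plan:
    """An ordered exposure sequence; list order is delivery order."""

    shots: tuple
    name: str = "plan"

    def __post_init__(self):
        object.__setattr__(self, "shots", tuple(self.shots))

    def validate(self) -> None:
        if len(self.shots) < 1:
            raise ValidationError("plan must contain at least one shot")
        for s in self.shots:
            s.validate()

    def __len__(self) -> int:
        return len(self.shots)


@dataclass(frozen=True)
class GridSpec:
    """Cubic calculation matrix: ``n_per_axis`` voxels, ``spacing`` mm."""

    n_per_axis: int = 200
    spacing: float = 1.0

    def __post_init__(self):
        if self.n_per_axis < 2:
            raise ValidationError("n_per_axis must be >= 2")
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_per_axis,) * 3

    def coords(self) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        return (np.arange(self.n_per_axis) + 1.0) * self.spacing

    def index_to_mm(self, idx) -> np.ndarray:
        return (np.asarray(idx, float) + 1.0) * self.spacing

    def mm_to_index(self, mm) -> np.ndarray:
        return np.asarray(mm, float) / self.spacing - 1.0

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3


@dataclass
class SparseField:
    """A per-shot dose field stored on its bounding box only.

    ``origin`` is the zero-based index of the box corner in the full grid;
    reconstruction to the full grid is exact.
    """

    origin: tuple[int, int, int]
    values: np.ndarray

    def to_dense(self, spec: GridSpec) -> np.ndarray:
        full = np.zeros(spec.shape)
        i, j, k = self.origin
        ni, nj, nk = self.values.shape
        full[i : i + ni, j : j + nj, k : k + nk] = self.values
        return full

    def slices(self) -> tuple[slice, slice, slice]:
        i, j, k = self.origin
        ni, nj, nk = self.values.shape
        return (slice(i, i + ni), slice(j, j + nj), slice(k, k + nk))


@dataclass
class DoseGrid:
    """Total physical dose (Gy) on the calculation matrix.

    When built with ``keep_per_shot``, the per-shot fields are retained
    (sparsely) so the BED engine can evaluate the shot-interaction terms.
    """

    spec: GridSpec
    values: np.ndarray
    per_shot: list | None = None  # list[SparseField], delivery order

    def per_shot_dense(self, i: int) -> np.ndarray:
        if self.per_shot is None:
            raise ValidationError("per-shot fields were not retained")
        return self.per_shot[i].to_dense(self.spec)


def ellipsoid_coefficient(point, isocenter, fwhm) -> np.ndarray:
    """Ellipsoid-expansion coefficient L (mm) for point(s) about an isocenter.

    Vectorised over ``point`` (last axis = xyz).  Reduces to the Euclidean
    distance when the three FWHMs are equal.
    """
    fwhm = np.asarray(fwhm, float)
    if np.any(fwhm <= 0):
        raise ValidationError("all FWHM values must be positive")
    delta = np.asarray(point, float) - np.asarray(isocenter, float)
    gm = float(np.cbrt(fwhm[0] * fwhm[1] * fwhm[2]))
    return gm * np.sqrt(np.sum((delta / fwhm) ** 2, axis=-1))


def shot_contour(shot: Shot, model: CollimatorModel):
    """Half-maximum contour of a shot: ellipsoid (center, semiaxes FWHM/2)."""
    if model.collimator_label != shot.collimator_label:
        raise ConfigurationError(
            f"shot {shot.index} uses the {shot.collimator_label} mm collimator "
            f"but the model is for {model.collimator_label} mm"
        )
    semiaxes = (model.fwhm_x / 2.0, model.fwhm_y / 2.0, model.fwhm_z / 2.0)
    return shot.isocenter, semiaxes


def _bounding_indices(shot: Shot, model: CollimatorModel, spec: GridSpec):
    """Index ranges of the axis-aligned box containing the l_max ellipsoid."""
    fwhm = np.asarray(model.fwhm)
    gm = np.cbrt(np.prod(fwhm))
    half_extent = model.l_max * fwhm / gm  # mm along each axis
    iso = np.asarray(shot.isocenter, float)
    lo = np.ceil(spec.mm_to_index(iso - half_extent)).astype(int)
    hi = np.floor(spec.mm_to_index(iso + half_extent)).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, spec.n_per_axis - 1)
    return lo, hi


def _shot_dose_sparse(shot: Shot, model: CollimatorModel, spec: GridSpec) -> SparseField:
    shot.validate()
    if model.collimator_label != shot.collimator_label:
        raise ConfigurationError(
            f"shot {shot.index}: model is for collimator "
            f"{model.collimator_label} mm, shot uses {shot.collimator_label} mm"
        )
    lo, hi = _bounding_indices(shot, model, spec)
    if np.any(hi < lo):
        warnings.warn(
            f"shot {shot.index} at {shot.isocenter} deposits no dose inside "
            "the calculation matrix",
            stacklevel=2,
        )
        return SparseField(origin=(0, 0, 0), values=np.zeros((0, 0, 0)))
    coords = spec.coords()
    axes = [coords[lo[a] : hi[a] + 1] - shot.isocenter[a] for a in range(3)]
    fwhm = np.asarray(model.fwhm)
    gm = np.cbrt(np.prod(fwhm))
    dx2 = (axes[0] / fwhm[0]) ** 2
    dy2 = (axes[1] / fwhm[1]) ** 2
    dz2 = (axes[2] / fwhm[2]) ** 2
    L = gm * np.sqrt(dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :])
    vals = shot.peak_dose * evaluate_profile(model, L)
    return SparseField(origin=tuple(int(x) for x in lo), values=vals)


def shot_dose_field(
    shot: Shot,
    model: CollimatorModel,
    spec: GridSpec,
    use_bounding_box: bool = True,
) -> np.ndarray:
    """Per-shot dose array d_i (Gy) on the full grid.

    With ``use_bounding_box`` the evaluation is restricted to the box
    containing the l_max ellipsoid; values are identical to the full-grid
    evaluation (voxels outside are exactly zero by the truncation contract).
    """
    if use_bounding_box:
        return _shot_dose_sparse(shot, model, spec).to_dense(spec)
    shot.validate()
    coords = spec.coords()
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    L = ellipsoid_coefficient(pts, shot.isocenter, model.fwhm)
    return shot.peak_dose * evaluate_profile(model, L)


def accumulate_dose(
    plan: Plan,
    models: dict,
    spec: GridSpec | None = None,
    keep_per_shot: bool = False,
) -> DoseGrid:
    """Total physical dose D_T = sum_i d_i over all shots of a plan.

    ``models`` maps collimator labels to fitted :class:`CollimatorModel`s.
    With ``keep_per_shot`` the individual fields are retained (sparse,
    exactly reconstructible) for the BED computation.
    """
    plan.validate()
    spec = spec or GridSpec()
    missing = sorted({s.collimator_label for s in plan.shots} - set(models))
    if missing:
        raise ConfigurationError(
            f"no collimator model for label(s) {missing}; "
            f"available: {sorted(models)}"
        )
    total = np.zeros(spec.shape)
    fields = []
    for s in plan.shots:
        f = _shot_dose_sparse(s, models[s.collimator_label], spec)
        if f.values.size:
            total[f.slices()] += f.values
        if keep_per_shot:
            fields.append(f)
    return DoseGrid(spec=spec, values=total, per_shot=fields if keep_per_shot else None)
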