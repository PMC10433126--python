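"""Single-shot dose-falloff profile models for Model B/C collimators.

A Gamma Knife B/C shot delivered through one of the 4 / 8 / 14 / 18 mm
collimators produces, in the absence of channel blocking, a dose falloff
along each frame axis that is close to a normal curve.  This module fits
the measured per-axis falloff tables with sums of Gaussian terms

    F(t) = sum_i  u_i * exp(-((t - v_i) / w_i)**2),

derives the full width at half maximum (FWHM) per axis, and collapses the
three axis curves into a single radial falloff law F_L over the ellipsoid
expansion coefficient L (the geometric mean of the per-axis half-widths at
each iso-dose level).  F_L is what the dose engine evaluates at every voxel.

Relative dose is a fraction in [0, 1] everywhere inside the package; percent
appears only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    FitFailureError,
    InsufficientDataError,
    LevelGridError,
    ProfileShapeError,
    ValidationError,
)

__all__ = [
    "DoseProfileTable",
    "GaussianSumModel",
    "CollimatorModel",
    "fit_axis_profile",
    "compute_fwhm",
    "build_radial_profile",
    "evaluate_profile",
    "COLLIMATOR_LABELS",
]

COLLIMATOR_LABELS = (4, 8, 14, 18)
AXES = ("x", "y", "z")

#: iso-dose levels (fractions) used to build the pooled signed-L point cloud
LEVEL_GRID = np.round(np.arange(0.95, 0.049, -0.05), 2)

#: relative dose below which the radial model is truncated to exactly zero
TRUNCATION_LEVEL = 1e-3


@dataclass(frozen=True)
class DoseProfileTable:
    """One measured falloff curve: relative dose vs. signed offset (mm).

    ``rel_dose`` is a fraction of the central maximum (1.0 = peak); a small
    measurement overshoot up to 1.05 is tolerated.  Offsets are signed
    distances from the profile centre, covering both sides of the peak.
    """

    collimator_label: int
    axis: str
    offsets_mm: np.ndarray
    rel_dose: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "offsets_mm", np.asarray(self.offsets_mm, float))
        object.__setattr__(self, "rel_dose", np.asarray(self.rel_dose, float))

    def validate(self) -> None:
        t, y = self.offsets_mm, self.rel_dose
        if self.collimator_label not in COLLIMATOR_LABELS:
            raise ValidationError(
                f"unknown collimator label {self.collimator_label!r}; "
                f"expected one of {COLLIMATOR_LABELS}"
            )
        if self.axis not in AXES and self.axis != "L":
            raise ValidationError(f"unknown axis {self.axis!r}")
        if t.ndim != 1 or t.shape != y.shape:
            raise ValidationError("offsets and rel_dose must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("offsets must be strictly increasing")
        if y.min() < 0 or y.max() > 1.05:
            raise ValidationError("rel_dose must lie in [0, 1.05]")
        if not (t.min() < 0 < t.max()):
            raise ValidationError("offsets must cover both sides of the peak")
        near0 = np.abs(t) <= max(2.0, 2 * np.median(np.diff(t)))
        if not np.any(y[near0] >= 0.99):
            raise ValidationError("no sample with rel_dose >= 0.99 near offset 0")


@dataclass(frozen=True)
class GaussianSumModel:
    """Sum of N Gaussian terms u_i * exp(-((t - v_i)/w_i)^2)."""

    u: np.ndarray  # amplitudes (fractions)
    v: np.ndarray  # centres (mm)
    w: np.ndarray  # widths (mm, > 0)

    def __post_init__(self):
        object.__setattr__(self, "u", np.atleast_1d(np.asarray(self.u, float)))
        object.__setattr__(self, "v", np.atleast_1d(np.asarray(self.v, float)))
        object.__setattr__(self, "w", np.atleast_1d(np.asarray(self.w, float)))
        if not (len(self.u) == len(self.v) == len(self.w)) or len(self.u) < 1:
            raise ValidationError("u, v, w must have equal length >= 1")
        if np.any(self.w <= 0):
            raise ValidationError("widths must be positive")

    @property
    def n_terms(self) -> int:
        return len(self.u)

    def __call__(self, t):
        t = np.asarray(t, float)
        z = (t[..., None] - self.v) / self.w
        return np.einsum("...i,i->...", np.exp(-(z**2)), self.u)

    def search_halfspan(self) -> float:
        """Half-width of the interval that certainly contains all structure."""
        return float(np.max(np.abs(self.v)) + 8.0 * np.max(self.w))

    def peak(self) -> tuple[float, float]:
        """Location and value of the global maximum (deterministic search)."""
        span = self.search_halfspan()
        grid = np.linspace(-span, span, 4001)
        vals = self(grid)
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -self(t), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-9},
        )
        return float(res.x), float(-res.fun)

    def to_dict(self) -> dict:
        return {
            "n": self.n_terms,
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "w": self.w.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianSumModel":
        m = cls(np.asarray(d["u"]), np.asarray(d["v"]), np.asarray(d["w"]))
        if m.n_terms != d.get("n", m.n_terms):
            raise ValidationError("inconsistent term count in serialized model")
        return m


@dataclass(frozen=True)
class CollimatorModel:
    """Fitted falloff law for one collimator.

    ``radial_model`` is F_L, the relative dose as a function of the ellipsoid
    expansion coefficient L; ``l_max`` is the truncation radius beyond which
    the relative dose is defined as exactly zero.
    """

    collimator_label: int
    fwhm_x: float
    fwhm_y: float
    fwhm_z: float
    axis_models: dict = field(default_factory=dict)  # axis -> GaussianSumModel
    radial_model: GaussianSumModel = None
    l_max: float = 0.0

    @property
    def fwhm(self) -> tuple[float, float, float]:
        return (self.fwhm_x, self.fwhm_y, self.fwhm_z)

    def to_dict(self) -> dict:
        return {
            "collimator": self.collimator_label,
            "fwhm": {"x": self.fwhm_x, "y": self.fwhm_y, "z": self.fwhm_z},
            "radial": self.radial_model.to_dict(),
            "l_max": self.l_max,
            "axes": {a: m.to_dict() for a, m in self.axis_models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CollimatorModel":
        return cls(
            collimator_label=int(d["collimator"]),
            fwhm_x=float(d["fwhm"]["x"]),
            fwhm_y=float(d["fwhm"]["y"]),
            fwhm_z=float(d["fwhm"]["z"]),
            axis_models={
                a: GaussianSumModel.from_dict(m)
                for a, m in d.get("axes", {}).items()
            },
            radial_model=GaussianSumModel.from_dict(d["radial"]),
            l_max=float(d["l_max"]),
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _gauss_sum(t, params):
    n = len(params) // 3
    u, v, w = params[:n], params[n : 2 * n], params[2 * n :]
    z = (t[:, None] - v) / w
    return np.exp(-(z**2)) @ u


def _fit_points(
    t: np.ndarray,
    y: np.ndarray,
    max_terms: int = 4,
    rmse_tol: float = 0.005,
) -> GaussianSumModel:
    """Fit (t, y) with the smallest-N Gaussian sum meeting ``rmse_tol``.

    Deterministic initialisation: amplitudes split the peak value evenly,
    centres start at 0, widths fan out geometrically around a moment
    estimate of the data width.  No random restarts.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if not 1 <= max_terms <= 8:
        raise ValidationError("max_terms must be between 1 and 8")
    if len(t) < 3 * max_terms:
        raise InsufficientDataError(
            f"{len(t)} samples cannot constrain {max_terms} Gaussian terms "
            f"(need at least {3 * max_terms})"
        )
    peak = float(y.max())
    if peak <= 0.05:
        raise FitFailureError("profile has no peak to fit (all values near zero)")

    # moment width: for a pure Gaussian exp(-(t/w)^2) the y-weighted second
    # moment of t equals w^2/2
    mom = float(np.sqrt(max(2.0 * np.sum(y * t**2) / np.sum(y), 1e-4)))
    span = float(max(abs(t.min()), abs(t.max())))

    best_model, best_rmse = None, np.inf
    for n in range(1, max_terms + 1):
        u0 = np.full(n, peak / n)
        # centres fan out symmetrically; exactly-zero centres would pin the
        # centre gradient at 0 for symmetric data (a stationary saddle)
        v0 = mom * np.linspace(-0.4, 0.4, n) if n > 1 else np.zeros(1)
        w0 = mom * np.geomspace(0.6, 1.6, n) if n > 1 else np.array([mom])
        p0 = np.concatenate([u0, v0, w0])
        lb = np.concatenate([np.full(n, -2.0), np.full(n, -2 * span), np.full(n, 1e-3)])
        ub = np.concatenate([np.full(n, 2.0), np.full(n, 2 * span), np.full(n, 4 * span)])
        try:
            res = optimize.least_squares(
                lambda p: _gauss_sum(t, p) - y,
                p0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        model = GaussianSumModel(res.x[:n], res.x[n : 2 * n], res.x[2 * n :])
        _, pk = model.peak()
        if pk <= 0.05:
            continue
        # normalise so the model's own maximum is 1.0; measure the RMSE on
        # the model actually returned, not on the raw optimiser residuals
        model = GaussianSumModel(model.u / pk, model.v, model.w)
        rmse = float(np.sqrt(np.mean((model(t) - y) ** 2)))
        if rmse < best_rmse:
            best_model, best_rmse = model, rmse
        if rmse <= rmse_tol:
            return model
    if best_model is None:
        raise FitFailureError("Gaussian-sum fit failed at every term count",
                              best_rmse=None)
    return best_model


def fit_axis_profile(
    table: DoseProfileTable,
    max_terms: int = 4,
    rmse_tol: float = 0.005,
) -> GaussianSumModel:
    """Fit one per-axis falloff table with a Gaussian sum.

    Returns the smallest-N model whose RMSE against the table is within
    ``rmse_tol``, otherwise the best fit found at ``max_terms``.  The fitted
    model is normalised so its own maximum evaluates to 1.0.

    Raises
    ------
    InsufficientDataError
        Fewer than ``3 * max_terms`` samples.
    FitFailureError
        Optimiser failure at every term count, or a degenerate profile.
    ValidationError
        Table violates its invariants (e.g. a constant-zero profile).
    """
    table.validate()
    return _fit_points(table.offsets_mm, table.rel_dose, max_terms, rmse_tol)


def compute_fwhm(model: GaussianSumModel) -> float:
    """Full width at half maximum of a fitted (peak ~ 1) profile model.

    Brackets the outermost half-maximum crossings on either side of the peak
    and refines each by bisection to sub-1e-6 mm.
    """
    t_peak, pk = model.peak()
    if not 0.9 <= pk <= 1.1:
        raise ProfileShapeError(f"model peak {pk:.3f} is not ~1; normalise first")
    half = pk / 2.0

    def crossing(direction: int) -> float:
        span = model.search_halfspan()
        # outermost crossing: scan from the far end toward the peak
        grid = t_peak + direction * np.linspace(0.0, span, 20001)
        vals = model(grid) - half
        above = np.nonzero(vals > 0)[0]
        if len(above) == 0:
            raise ProfileShapeError("no half-maximum crossing found")
        i = above[-1]  # last point above half, moving outward
        if i + 1 >= len(grid):
            raise ProfileShapeError("profile never falls below half maximum")
        lo, hi = grid[i], grid[i + 1]
        return float(optimize.bisect(lambda t: model(t) - half, lo, hi, xtol=1e-8))

    right = crossing(+1)
    left = crossing(-1)
    return abs(right - left)


def _half_width_at_level(model: GaussianSumModel, level: float, side: int) -> float:
    """|offset| at which ``model`` falls to ``level`` on the given side."""
    t_peak, pk = model.peak()
    span = model.search_halfspan()
    grid = t_peak + side * np.linspace(0.0, span, 20001)
    vals = model(grid) - level * pk
    above = np.nonzero(vals > 0)[0]
    if len(above) == 0 or above[-1] + 1 >= len(grid):
        raise LevelGridError(
            f"iso-dose level {level:.2f} is not reached on side {side:+d}"
        )
    i = above[-1]
    root = optimize.bisect(
        lambda t: model(t) - level * pk, grid[i], grid[i + 1], xtol=1e-8
    )
    return abs(float(root) - t_peak)


def build_radial_profile(
    tables_xyz: dict | list,
    max_terms: int = 4,
    rmse_tol: float = 0.005,
) -> CollimatorModel:
    """Collapse three per-axis falloff tables into a radial model F_L.

    For each iso-dose level p on each side of the peak, the per-axis
    half-widths a, b, c are read off the fitted axis curves and mapped to
    the signed ellipsoid-expansion coefficient L = sign * (|a||b||c|)^(1/3)
    — the geometric mean of the half-widths.  The pooled signed (L, p)
    points are then fitted with the same Gaussian-sum machinery, giving the
    radial law F_L.  By construction F_L at the geometric mean of the
    half-FWHMs equals the half-maximum level.
    """
    if isinstance(tables_xyz, dict):
        tables = tables_xyz
    else:
        tables = {tb.axis: tb for tb in tables_xyz}
    missing = [a for a in AXES if a not in tables]
    if missing:
        raise ValidationError(f"missing axis tables: {missing}")
    labels = {tb.collimator_label for tb in tables.values()}
    if len(labels) != 1:
        raise ValidationError(f"mixed collimator labels in axis tables: {labels}")
    label = labels.pop()

    axis_models = {a: fit_axis_profile(tables[a], max_terms, rmse_tol) for a in AXES}
    fwhm = {a: compute_fwhm(axis_models[a]) for a in AXES}

    ls, ps = [0.0], [1.0]  # anchor the peak
    for side in (+1, -1):
        for p in LEVEL_GRID:
            hw = [_half_width_at_level(axis_models[a], p, side) for a in AXES]
            ls.append(side * float(np.cbrt(hw[0] * hw[1] * hw[2])))
            ps.append(float(p))
    order = np.argsort(ls)
    lpts = np.asarray(ls)[order]
    ppts = np.asarray(ps)[order]

    radial = _fit_points(lpts, ppts, max_terms, rmse_tol)

    # truncation radius: smallest |L| at which the fitted law drops below
    # TRUNCATION_LEVEL, per side; take the smaller side
    def first_below(sign: int) -> float:
        lattice = sign * np.arange(0.0, 40.0 * max(fwhm.values()), 0.01)
        vals = radial(lattice)
        below = np.nonzero(vals < TRUNCATION_LEVEL)[0]
        if len(below) == 0:
            return float(abs(lattice[-1]))
        return float(abs(lattice[below[0]]))

    l_max = min(first_below(+1), first_below(-1))

    return CollimatorModel(
        collimator_label=label,
        fwhm_x=fwhm["x"],
        fwhm_y=fwhm["y"],
        fwhm_z=fwhm["z"],
        axis_models=axis_models,
        radial_model=radial,
        l_max=l_max,
    )


def evaluate_profile(model: CollimatorModel, L):
    """Relative dose fraction at ellipsoid coefficient L >= 0.

    Clamped to [0, 1]; exactly 0 beyond the truncation radius ``l_max``.
    """
    L = np.asarray(L, float)
    if np.any(L < 0):
        raise ValidationError(
            "L must be non-negative (the spatial mapping from voxel offsets "
            "to the ellipsoid coefficient yields L >= 0)"
        )
    vals = np.clip(model.radial_model(L), 0.0, 1.0)
    vals = np.where(L > model.l_max, 0.0, vals)
    return vals if vals.ndim else float(vals)
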