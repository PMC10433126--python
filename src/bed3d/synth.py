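"""Synthetic measurement and plan generators.

Everything the toolkit consumes can be generated here: per-collimator
falloff tables emulating TMR10-style dosimetry or radiochromic-film
measurements, randomized multi-isocenter plans, and target / organ-at-risk
masks (spheres, ellipsoids, and an elongated fiber-tract tube whose extent
motivates the full 200 mm matrix).

The truth profile is a flat-shouldered Gaussian

    f(t) = exp(-(g(|t|) / w)^2),   g(u) = s * log(cosh(u / s)),

where the shoulder sharpness s (mm) softens the peak: a single Gaussian
term cannot fit it exactly, so the multi-term fitting machinery is
genuinely exercised.  The t-axis is rescaled so the requested FWHM is exact
and is recorded in the spec as ground truth for recovery tests.

All generators are pure functions of (spec, seed), using numpy's PCG64
``default_rng`` stream for cross-platform determinism.  The default FWHM
values are fixture conventions near the nominal collimator sizes (z
narrowest, as in practice); they are not measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .dose import GridSpec, Plan, Shot
from .errors import ValidationError
from .metrics import StructureMask
from .profiles import COLLIMATOR_LABELS, DoseProfileTable

__all__ = [
    "ProfileSpec",
    "PlanSpec",
    "DEFAULT_FWHM",
    "gen_profile_tables",
    "gen_plan",
    "gen_ellipsoid_mask",
    "gen_tract_mask",
    "default_profile_spec",
    "default_tract_polyline",
    "polyline_length",
]

#: fixture-convention FWHM triples (mm) per collimator label
DEFAULT_FWHM = {
    4: (6.0, 6.0, 4.8),
    8: (10.4, 10.4, 8.4),
    14: (16.8, 16.8, 13.2),
    18: (21.6, 21.6, 16.4),
}


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for one collimator's three synthetic falloff tables."""

    collimator_label: int
    fwhm: tuple[float, float, float]  # true FWHM per axis (mm), recorded truth
    shoulder: float = 0.8  # mm; larger = flatter peak
    noise_sd: float = 0.0  # fraction of peak
    sample_spacing: float = 0.25  # mm
    seed: int = 0

    def __post_init__(self):
        if self.collimator_label not in COLLIMATOR_LABELS:
            raise ValidationError(f"unknown collimator {self.collimator_label}")
        if any(f <= 0 for f in self.fwhm):
            raise ValidationError("FWHM values must be positive")
        if not 0.0 <= self.noise_sd <= 0.02:
            raise ValidationError("noise sd must be in [0, 0.02]")
        if self.shoulder <= 0 or self.sample_spacing <= 0:
            raise ValidationError("shoulder and sample spacing must be positive")


def default_profile_spec(label: int, noise_sd: float = 0.0, seed: int = 0) -> ProfileSpec:
    return ProfileSpec(collimator_label=label, fwhm=DEFAULT_FWHM[label],
                       noise_sd=noise_sd, seed=seed)


def _shoulder_arg(u: np.ndarray, s: float) -> np.ndarray:
    # s*log(cosh(u/s)); overflow-safe for large u/s: log cosh x = |x| - log 2 + log1p(e^{-2|x|})
    x = np.abs(u) / s
    return s * (x - np.log(2.0) + np.log1p(np.exp(-2.0 * x)))


def _truth_profile(fwhm: float, shoulder: float):
    """Return f(t) with exact FWHM and its support half-width (dose < 2e-4)."""
    target = np.sqrt(np.log(2.0))
    # width w placing the half-maximum of exp(-(g(t)/w)^2) exactly at fwhm/2
    w = float(_shoulder_arg(np.asarray(fwhm / 2.0), shoulder)) / target

    def f(t):
        return np.exp(-((_shoulder_arg(np.asarray(t, float), shoulder) / w) ** 2))

    ext = float(optimize.brentq(lambda t: f(t) - 2e-4, fwhm / 2.0, 20.0 * fwhm))
    return f, ext


def gen_profile_tables(spec: ProfileSpec) -> dict:
    """Three per-axis falloff tables for one collimator, keyed by axis.

    Each table samples the flat-shouldered truth curve on a symmetric grid
    (the offset-0 sample is kept exactly at 1.0 so the peak invariant holds
    under noise), with seeded Gaussian noise elsewhere, clipped to [0, 1.05].
    """
    rng = np.random.default_rng(spec.seed)
    tables = {}
    for axis, fwhm in zip(("x", "y", "z"), spec.fwhm):
        f, ext = _truth_profile(fwhm, spec.shoulder)
        m = int(np.ceil(ext / spec.sample_spacing))
        offsets = spec.sample_spacing * np.arange(-m, m + 1)
        vals = f(offsets)
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
        vals = np.clip(vals, 0.0, 1.05)
        vals[m] = 1.0  # peak sample
        tables[axis] = DoseProfileTable(
            collimator_label=spec.collimator_label, axis=axis,
            offsets_mm=offsets, rel_dose=vals,
        )
    return tables


@dataclass(frozen=True)
class PlanSpec:
    """Recipe for a randomized multi-isocenter plan."""

    n_shots: int = 5
    target_center: tuple[float, float, float] = (100.0, 100.0, 100.0)
    target_extent: tuple[float, float, float] = (20.0, 20.0, 16.0)  # box (mm)
    collimator_mix: tuple = (4, 8, 14, 18)
    dose_rate_range: tuple[float, float] = (1.5, 3.5)  # Gy/min
    duration_range: tuple[float, float] = (1.0, 10.0)  # min
    gap_range: tuple[float, float] = (1.0, 5.0)  # min
    seed: int = 0

    def __post_init__(self):
        if self.n_shots < 1:
            raise ValidationError("n_shots must be >= 1")
        for lo, hi in (self.dose_rate_range, self.duration_range, self.gap_range):
            if lo < 0 or hi < lo:
                raise ValidationError("ranges must be non-negative and ordered")
        if self.duration_range[0] <= 0 or self.dose_rate_range[0] <= 0:
            raise ValidationError("dose rate and duration must be positive")
        if any(c not in COLLIMATOR_LABELS for c in self.collimator_mix):
            raise ValidationError("collimator mix contains unknown labels")


def gen_plan(spec: PlanSpec, name: str = "synthetic-plan") -> Plan:
    """Randomized plan: isocenters uniform inside the target box, parameters
    uniform in their ranges, delivery order randomized then fixed."""
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.target_center)
    e = np.asarray(spec.target_extent)
    iso = rng.uniform(c - e / 2.0, c + e / 2.0, size=(spec.n_shots, 3))
    labels = rng.choice(spec.collimator_mix, size=spec.n_shots)
    rates = rng.uniform(*spec.dose_rate_range, size=spec.n_shots)
    durs = rng.uniform(*spec.duration_range, size=spec.n_shots)
    gaps = rng.uniform(*spec.gap_range, size=spec.n_shots)
    order = rng.permutation(spec.n_shots)
    shots = []
    for rank, k in enumerate(order):
        shots.append(Shot(
            index=rank + 1,
            collimator_label=int(labels[k]),
            isocenter=tuple(float(x) for x in iso[k]),
            dose_rate=float(rates[k]),
            duration=float(durs[k]),
            gap_after=0.0 if rank == spec.n_shots - 1 else float(gaps[k]),
        ))
    plan = Plan(shots=tuple(shots), name=name)
    plan.validate()
    return plan


def gen_ellipsoid_mask(center, semiaxes, spec: GridSpec,
                       label: str = "target") -> StructureMask:
    """Mask of voxels whose centers lie inside the analytic ellipsoid."""
    center = np.asarray(center, float)
    semiaxes = np.asarray(semiaxes, float)
    if np.any(semiaxes <= 0):
        raise ValidationError("semiaxes must be positive")
    coords = spec.coords()
    dx = (coords - center[0]) / semiaxes[0]
    dy = (coords - center[1]) / semiaxes[1]
    dz = (coords - center[2]) / semiaxes[2]
    inside = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2) <= 1.0
    return StructureMask(spec=spec, voxels=inside, label=label)


def polyline_length(control_points) -> float:
    """Total length (mm) of a piecewise-linear polyline."""
    pts = np.asarray(control_points, float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def default_tract_polyline() -> np.ndarray:
    """Gently curved centerline emulating a pyramidal tract (> 150 mm long)."""
    z = np.linspace(25.0, 175.0, 61)
    x = 100.0 + 18.0 * np.sin(np.pi * (z - 25.0) / 150.0)
    y = 95.0 + 10.0 * np.cos(np.pi * (z - 25.0) / 75.0)
    return np.column_stack([x, y, z])


def gen_tract_mask(control_points, radius: float, spec: GridSpec,
                   label: str = "tract") -> StructureMask:
    """Tube of ``radius`` mm around an interpolated polyline.

    The polyline is resampled at ~0.2 mm arc-length steps; voxels whose
    centers are within ``radius`` of the resampled centerline are set.
    """
    pts = np.asarray(control_points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValidationError("control_points must be an (n, 3) array, n >= 2")
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    coords = spec.coords()
    lo, hi = coords[0], coords[-1]
    if pts.min() < lo - 1e-9 or pts.max() > hi + 1e-9:
        raise ValidationError("polyline exits the calculation grid")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    samples = np.arange(0.0, arc[-1], 0.2)
    dense = np.column_stack([
        np.interp(samples, arc, pts[:, a]) for a in range(3)
    ])
    tree = cKDTree(dense)

    bb_lo = np.maximum(np.floor(spec.mm_to_index(pts.min(axis=0) - radius)).astype(int), 0)
    bb_hi = np.minimum(np.ceil(spec.mm_to_index(pts.max(axis=0) + radius)).astype(int),
                       spec.n_per_axis - 1)
    mask = np.zeros(spec.shape, dtype=bool)
    ax = [coords[bb_lo[a] : bb_hi[a] + 1] for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    box_pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dist, _ = tree.query(box_pts, k=1)
    inside = (dist <= radius).reshape(X.shape)
    mask[bb_lo[0] : bb_hi[0] + 1, bb_lo[1] : bb_hi[1] + 1,
         bb_lo[2] : bb_hi[2] + 1] = inside
    if radius < spec.spacing / 2.0 and not mask.any():
        warnings.warn(
            f"tract radius {radius} mm is below half the voxel spacing; "
            "the mask came out empty", stacklevel=2,
        )
    return StructureMask(spec=spec, voxels=mask, label=label)
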