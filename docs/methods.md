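# Methods

## Scope and assumptions

`bed3d` models single-session Gamma Knife Model B/C deliveries: every shot
is a fixed-geometry exposure through a 4, 8, 14 or 18 mm collimator with
no channel blocking, so the per-axis dose falloff is close to a normal
curve and a Gaussian-sum fit is appropriate. Sector-composite shots
(Perfexion/Icon/Esprit), channel blocking, tissue heterogeneity, skull
attenuation and multi-day fractionation are out of scope. Dose is
point-sampled at voxel centers on a cubic Leksell matrix; partial-volume
weighting is not modelled.

## Profile model

Each measured axis profile (relative dose vs. signed offset, fraction of
the central maximum) is fitted with

    F(t) = sum_i u_i exp(-((t - v_i) / w_i)^2),

selecting the smallest number of terms N whose root-mean-square error is
within `rmse_tol` (default 0.005, N <= 4). Initialisation is
deterministic — amplitudes split the peak evenly, widths fan out
geometrically around a moment estimate, centres fan out over +-0.4 of the
moment width — so refitting identical data is byte-reproducible. Centres
must not all start at zero: for symmetric data that is a stationary point
of the least-squares objective and the optimiser would never move them.
The fitted model is rescaled so its own maximum is exactly 1, and the
acceptance RMSE is measured on that rescaled model.

The three axis fits are collapsed to one radial law F_L: at each iso-dose
level p in {0.95, 0.90, ..., 0.05}, on each side of the peak, the per-axis
half-widths a, b, c are read off the fitted curves and pooled as signed
points (L, p) with L = sign * (|a||b||c|)^(1/3) — the geometric mean, i.e.
the radius of the sphere with the same volume as the level-p ellipsoid.
The pooled cloud (both sides plus the peak anchor) is fitted with the same
machinery. Fitting is two-sided so any left/right asymmetry is averaged;
evaluation is one-sided (L >= 0) because the spatial mapping

    L = (FWHMx FWHMy FWHMz)^(1/3) sqrt(sum_axis (offset/FWHM_axis)^2)

cannot produce negative values. Beyond the truncation radius `l_max` (the
smaller of the two signed radii where the fitted law first drops below
1e-3) the relative dose is defined as exactly 0, and evaluation is clamped
to [0, 1]; Gaussian sums can re-rise or go negative far outside the data
range, and the truncation makes extrapolation safe.

Relative dose is a fraction in [0, 1] everywhere inside the package;
percent appears only at I/O boundaries.

## Dose engine

Voxel (i, j, k), zero-based, has its center at ((i+1)s, (j+1)s, (k+1)s) mm
at spacing s, so the default 200-voxel, 1 mm matrix places the frame
reference (100, 100, 100) exactly on the center of voxel (99, 99, 99) and
the sampled peak of a centered shot equals the true peak. A shot deposits
`dose_rate * duration * F_L(L)`; evaluation is restricted to the bounding
box of the `l_max` ellipsoid, which is exact (outside it the kernel is 0
by the truncation contract) and keeps per-shot fields sparse. Shots whose
ellipsoid misses the grid contribute no dose but keep their place in the
timing sequence — their beam-on time still elapses.

## BED engine

The per-voxel BED under the linear-quadratic model with bi-exponential
sublethal-damage repair is

    BED = D_T + (alpha/beta)^-1 [Phi(mu1) + c Phi(mu2)]/(1 + c) sum_i d_i^2

with the protraction factor

    Phi(mu) = [sum_j d_j^2 A_j + sum_{i<j} d_i d_j B_ij] / sum_k d_k^2
    A_j  = (2/mu) (dt_j - (1/mu)(1 - e^{-mu dt_j})) / dt_j^2
    B_ij = (2/mu^2) e^{-mu(t_j - t_i - dt_i)} (1 - e^{-mu dt_i})(1 - e^{-mu dt_j}) / (dt_i dt_j)

The cross term is algebraically rearranged so every exponent is
non-positive (no overflow for any mu, duration or gap) and `1 - e^{-x}`
is evaluated with `expm1`. A_j and B_ij depend only on the timing, so the
whole grid reduces to two quadratic forms over the per-shot dose fields
(one per repair rate): O(V N^2) multiply-adds with no per-voxel
exponentials. This is the package's answer to the computational load of
voxel-by-voxel BED on a full 200^3 matrix; a two-shot 8M-voxel grid
converts in well under a second.

Initiation times accumulate as t_{k+1} = t_k + dt_k + gap_k with t_1 = 0.
Time is minutes throughout; repair rates can be entered directly (1/min)
or as half-times (mu = ln 2 / T_half). Zero-duration shots are rejected at
validation (the factor divides by the beam-on time); an effectively acute
shot is modelled with a small positive duration, for which Phi -> 1.
Voxels with zero total dose short-circuit to BED = 0 rather than
evaluating the 0/0 normalisation.

Bounds: for a single shot 0 < Phi <= 1, with Phi -> 1 as mu dt -> 0. For
multiple shots the normalisation by sum d^2 means the no-repair limit is
Phi -> (sum d)^2 / sum d^2 >= 1 (all shots fully interact), so the general
invariant is 0 < Phi sum d^2 <= (sum d)^2. In that limit the BED of n
coincident acute shots reduces to the textbook acute value
D + D^2/(alpha/beta) for the total dose D.

**Verification oracle.** `phi_numeric_oracle` evaluates the defining
double integral (2/sum d^2) ∫∫_{t'<t} R(t) R(t') e^{-mu(t-t')} dt' dt for
the piecewise-constant dose-rate function directly, by composite Simpson
quadrature per shot segment (step <= min(dt_min/200, 0.02/mu); the second
cap keeps the quadrature resolving the repair timescale). Cross-segment
rectangles separate into products of 1-D integrals with a constant
inter-segment attenuation factor; exponents are again arranged
non-positive. The closed-form weights and the oracle agree to better than
1e-6 relative over randomized plans — they share no code path.

No default values for alpha/beta, mu1, mu2 or c are asserted as truth;
the examples use literature-style values (alpha/beta 8.2 or 2.47 Gy,
repair half-times ~10 and ~190 min, c ~ 1) purely as fixtures.

## Plan metrics

Volumes are voxel counts times the voxel volume. Histograms use half-open
bins [lo, hi) with a default width of 0.5 Gy; the cumulative curve is
at-or-above (>=), the planning convention, so its first entry is the
structure volume and it is non-increasing. The conformity and gradient
indices are the standard stereotactic definitions — Paddick
CI = TV_PIV^2/(TV * PIV) and GI = V(level/2)/V(level) — applied
identically to dose and BED grids (named but not defined in the source
method; this interpretation is a documented choice). Iso-surfaces come
from scikit-image marching cubes, shifted to the voxel-center coordinate
convention; the mesh's divergence-theorem volume cross-checks the
voxel-counted iso-level volume.

## Synthetic fixtures

The generator emulates TMR10-style or film-measured falloff tables with a
flat-shouldered Gaussian truth curve exp(-(g(|t|)/w)^2),
g(u) = s log cosh(u/s) (shoulder s = 0.8 mm), rescaled so the requested
FWHM is exact and recorded as ground truth. The shoulder keeps the truth
outside the single-Gaussian family so multi-term fitting is genuinely
exercised. Default FWHM triples — 4 mm: (6.0, 6.0, 4.8); 8 mm:
(10.4, 10.4, 8.4); 14 mm: (16.8, 16.8, 13.2); 18 mm: (21.6, 21.6, 16.4) —
are fixture conventions near the nominal collimator sizes with z narrowest
(as in practice); they are not measured values, and all recovery checks
compare against the generator's recorded truth, never the nominal label.
Measurement noise is additive Gaussian (sd up to 0.02 of the peak; the
peak sample itself is pinned at 1.0 so table invariants hold). Plans draw
isocenters uniformly in a target box and delivery parameters uniformly in
their ranges. Masks include analytic ellipsoids and a curved ~161 mm
tract tube whose extent is what motivates the full 200 mm matrix.

What the fixtures do **not** emulate: detector-specific systematic error,
per-axis asymmetry beyond what the two-sided fit averages, output-factor
differences between collimators, and any anatomy. Passing tests therefore
demonstrate the correctness of the mathematics and the pipeline, not
clinical accuracy for a particular instrument — real use requires
measured profile tables for the machine in question.

## Numerical choices and problem sizes

- Axis fits: `scipy.optimize.least_squares` (trust-region reflective),
  bounds |u| <= 2, widths >= 1e-3 mm; no random restarts.
- FWHM and level half-widths: outermost bracketed crossing on each side,
  refined by bisection to < 1e-6 mm.
- Noiseless truth-recovery checks fit with max_terms = 6,
  rmse_tol = 5e-4 (clean data supports the tighter tolerance); noisy and
  routine fits use the defaults (4, 0.005).
- Grid BED vs. voxelwise BED agrees to < 1e-9 Gy; the check runs on a
  20^3 sub-grid, which already exercises every term of the quadratic form.
- Sub-voxel geometry checks (half-max ellipsoid volume, gradient index of
  a Gaussian shot) use 0.25 mm grids, since a ~2.8 mm-radius surface on a
  1 mm lattice digitizes too coarsely for a few-percent comparison.
- Refinement-stability checks use smooth, wide fixtures (FWHM >= 14 mm at
  1 mm spacing): trilinear interpolation error scales with
  (spacing/width)^2, and sharper kernels simply need finer grids.
- Generators use numpy's PCG64 `default_rng` streams; every stochastic
  step takes an explicit seed, and CLI outputs carry the seed and config
  hash in a JSON sidecar.

## Known limitations

- The radial collapse assumes the three axis profiles share the same
  iso-dose level range; profiles with shoulders on one axis only would
  stress the geometric-mean construction.
- `l_max` truncation introduces a hard zero at the 0.1% level; integral
  quantities over very large volumes ignore the true sub-0.1% tail.
- Masks are voxelized at centers; thin structures below half the voxel
  spacing can come out empty (a warning is raised).
- NRRD I/O is intentionally minimal: 3-D cubic isotropic grids, ASCII
  encoding only.
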