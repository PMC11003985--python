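# Methods

## Rate model of cross-modal suppression

The network module implements a Wilson–Cowan-type model of two homogeneous
VISp populations: pyramidal neurons (P) and fast-spiking interneurons (F).
Each population's mean rate relaxes toward a threshold-linear transform of
its summed input,

    τ_P Ȧ_P = −A_P + f_P(J_PP A_P − J_PF A_F + I^cm + I^v_P)
    τ_F Ȧ_F = −A_F + f_F(J_FP A_P − J_FF A_F + I^cm + I^v_F)
    f_i(h) = G_i · max(h − θ_i, 0).

The cross-modal (tactile) drive targets both populations equally but is
clipped to `[0, ρ]` with `ρ = δ·θ_P` before entering the sums. This cap is
the model's expression of the physiological observation that the tactile
projection can make interneurons fire but only depolarizes pyramidal cells
below their threshold (`θ_F < θ_P` and the capped drive never exceeds
`θ_P` for `δ ≤ 1`).

**Assumptions.** Mean-field (no spiking, no heterogeneity, no plasticity);
exactly two populations; strictly positive weights, gains and time
constants; the closed-form fixed point and the suppression formulas assume
both populations are above threshold in both stimulation conditions —
every analytic routine verifies this post hoc and flags `valid=False`
rather than silently returning a formula value on an inactive branch.

**Default parameters** (dimensionless input units unless noted):
τ_P = 60 ms, τ_F = 12 ms, G_P = 1, G_F = 5 Hz/unit, J_PP = 2, J_PF = 4
(I/E ratio α = J_PF/J_PP = 2), J_FF = 0.8, J_FP = 0.4 unit/Hz,
θ_P = 0.5, θ_F = 0.35, I^v_P = 3.6, I^v_F = 0.6, I^cm = 0.6, δ = 1.
These reproduce φ = 3, steady states (3.5, 1.65) Hz under visual drive,
(1.0, 1.15) Hz with the tactile drive added, and suppression
(−2.5, −0.5) Hz.

**Numerics.** Forward Euler at dt = 0.1 ms — the simplest scheme
consistent with the non-stiff, piecewise-linear dynamics; the default
stimulus protocol (visual drive for 10 s, tactile added at 5 s) leaves
both plateaus hundreds of time constants long, so the simulated and
analytic fixed points agree to ~1e-13 Hz. Rates are clamped at zero after
each step (the transfer is already rectified; the clamp only guards
against Euler overshoot). Non-finite rates raise an error naming the first
bad step. Degenerate networks (φ = 0) raise rather than returning
infinities.

**Regime classification.** ISN criteria: (I) w_PP > 1, (II)
w_FF + 1 > k(w_PP − 1) with k = τ_F/τ_P, (III) φ > 0. Suppression of P
(resp. F) additionally needs `1 + G_F(J_FF − J_PF) < 0` (resp.
`1 + G_P(J_FP − J_PP) < 0`) together with φ > 0. Sweeps label grid points
three ways — non-ISN, ISN without suppression, ISN with suppression — and
keep φ = 0 points as NaN rows instead of aborting. Random-parameter
property tests restrict to draws with a *stable* active fixed point
(φ > 0): for φ < 0 the active fixed point is a saddle and the steady-state
formulas describe a state the dynamics never reach.

## Whisker-array geometry

All geometry uses one right-handed head frame: x nose-ward, y toward the
animal's left, z up, horizontal plane parallel to bregma–lambda. Azimuth
and elevation are measured in a left-eye-centered spherical frame (0°
azimuth straight ahead, positive toward left-lateral; elevation positive
up).

Whisking is modeled as rigid rotation of each whisker about its own
basepoint around the normal of its row's whisking plane (least-squares
plane through the row's basepoints and tips; greek whiskers α–δ follow
rows A–D). The plane normal's sign is chosen so positive angles protract.
Planes are fitted from the four arc whiskers of each row; the greek
straddlers reuse their row's plane rather than influencing the fit, which
keeps the plane definition identical whether or not greeks are present.
Scenario composition is incline planes → protract/retract → roll, with
roll (rotation about the base-to-tip chord) using row-specific angles
A = −36.8°, B = −14.0°, C = 23.8°, D = 16.2°, E = 26.7°, scalable by 0.5,
1 or 2; greek whiskers take their row's angle (an assumption — only
row angles are known). All three transforms are exact isometries (checked
to 1e-9 mm).

**Overlap.** Tips are converted to (azimuth, elevation) and tested against
the VISp coverage polygon with shapely; boundary tips count as inside.
Eye movements are emulated by buffering the polygon outward by 20° in the
planar degree space — adequate because the covered field spans well under
a hemisphere; spherical buffering is out of scope.

**Tip uncertainty.** Six perturbed whisker variants (±2° emergence
elevation and azimuth, ±4° twist) are generated by rigidly rotating the
whisker about its basepoint; each source's uncertainty is the mean tip
displacement of its ± pair; the three sources combine in quadrature and a
0.5 mm basepoint uncertainty is added to the radius. The quadrature
combination is justified post hoc by a Monte-Carlo oracle (uniform draws
in the angle boxes): because the three displacement directions are nearly
orthogonal, the quadrature radius tracks the maximal sampled displacement
within 25%. Across-animal summaries add the s.e.m. across arrays linearly
to the propagated radius.

**Synthetic arrays.** Real whiskers are traced; here they are planar
quadratic curves (50-point polylines) whose curvature plane is selected by
the twist angle ζ (0° = ventral). Basepoints sit on a 5-column grid over a
parametric pad (greek column caudal-most); nominal lengths fall from 22 mm
(greek) to 8 mm (arc 4), matching the caudal-longest ordering of real
arrays; emergence azimuths point caudo-laterally at rest so that
protraction sweeps tips toward the nasal visual field. The eye sits
dorso-caudal to the pad at (0, 3, 5) mm — the true eye-center offset is
not known to this model, so overlap fractions are meaningful relative to
this placement (their *ordering* across scenarios, not their absolute
values, is the tested claim). The coverage template spans azimuth 0–90°
and elevation −25° to +60° with a bevelled temporal-dorsal corner.

## Spatial statistics

**PCA and parcellation.** Axes come from scikit-learn's PCA on the pooled
2D-projected points (pooling across animals before PCA is the default;
per-animal analysis can be run by calling the function per subset). Sign
convention: pc1 has non-negative x-component, pc2 completes a
right-handed pair. Section lines take the slope of pc2 and are spaced
exactly `spacing` (default 200 px) apart along pc1, implemented via
y-intercept shifts; vertical lines are encoded as (inf, x-position).
A span of m·spacing yields m interior boundaries and m+1 sections; points
exactly on a line join the lower-pc1 side, so assignment is total. The
number of parcels is a property of the data extent, not a constant.

**Density maps.** `scipy.stats.gaussian_kde` with Scott's bandwidth on a
uniform grid (default step 58 ≈ 200/√12 px) spanning the data limits
padded by 3 kernel bandwidths per side; padding is evaluated then cut off
(the padded field is kept for normalization checks — its Riemann sum is 1
within a few percent). Contour levels use matplotlib's automatic locator.
A singular covariance (collinear points) triggers a deterministic jitter
fallback with a warning.

**Barrel enrichment.** `fr_b = (#Cells_b/#Cells_tot)·(#Area_tot/#Area_b)`
with `#Cells_tot` counted over *all* layers (so layers share a scale) and
areas as pixel counts; `#Area_tot` is the whole depicted field. The null
repositions each layer's cells uniformly over the full rectangular field
including septa (uniform-over-barrels would be a defensible alternative;
the support is the whole field here). Because uniform repositioning
followed by per-barrel counting is distributionally identical to one
multinomial draw with probabilities ∝ barrel areas, shuffles are drawn as
multinomials — an exact equivalence, not an approximation — making 2500
shuffles essentially free. P-values use the add-one estimator
`p = (1 + #{fr^sh ≥ fr^obs})/(1 + n_shuffles)` (never zero, slightly
conservative); the default per-barrel test at the strict α = 0.001 is the
multiplicity control, with an optional max-statistic family-wise mode
(`method="max-stat"`).

**Visual-space assignment.** Parcel polygons are mapped vertex-wise
through the retinotopy (optionally densifying edges first); parcels with
fractions ≥ 5% merge into the modulated-field polygon. Parcels leaving
the retinotopy's declared domain are excluded with a warning.

## Synthetic data and what passing tests show

Generators are pure functions of (config, seed); each block derives an
independent RNG stream by hashing its name into the master seed, so draws
in one generator never shift another's output. Every dataset ships a
sidecar dict with the latent truth (axis angle, variance split, enrichment
factors, eye position, …).

The generators reproduce the *statistical and geometric structure* the
analyses rely on — anisotropy, density gradients, caudal-longest length
ordering, per-barrel enrichment — but not anatomical realism: no traced
whisker shapes, no real retinotopic map, no imaging noise. Passing tests
therefore demonstrate that the algorithms are correct and calibrated
(recover planted parameters, hold their nominal error rates, satisfy the
model's closed forms), not that any particular biological effect size is
reproduced; quantities that depend on real data (absolute overlap
percentages, real variance splits) are only checked for direction and
internal consistency.

## Problem sizes used by tests and the acceptance script

Rate-model simulations run the full 10 s protocol at dt = 0.1 ms.
Regime/sign agreement uses 1000 accepted random parameter sets.
Uncertainty oracles use 10⁴ Monte-Carlo draws per whisker. Permutation
calibration uses 200 runs × 2000 cells × 20 barrels at 400 shuffles
(α = 0.05 needs only ~1/400 p-resolution); the power check uses 100 runs
at the full 2500 shuffles and α = 0.001. PCA recovery uses 10⁴-point
clouds. These sizes give sampling noise well inside the asserted bands.

## Known limitations

- No spiking dynamics, adaptation, or more than two populations; no
  parameter fitting to recordings.
- Torsion is applied only at end-of-protraction poses, not continuously
  through the stroke; no dynamic whisking time series.
- Planar (degree-space) polygon geometry for the visual field; fine for
  the ~90° × 85° domain, wrong near poles.
- The cm-only analytic fixed point assumes the capped drive cannot
  activate P (guaranteed for δ ≤ 1); larger δ with visual drive absent
  falls back to simulation.
- Barrel masks are label rasters; sub-pixel cell positions are binned by
  floor, so boundary cells take the pixel's label.
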