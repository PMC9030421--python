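# Methods

## The measurement model

A specimen is a binary silhouette on a pixel grid, obtained either from a
flatbed scan or from the synthetic generator. All geometry lives in
0-based `(row, col)` coordinates with pixel centres at integer positions;
lengths are in pixels, with an optional conversion to millimetres by
`25.4 / dpi` (areas by its square). Dimensionless descriptors are
unaffected by the unit choice, and classification is invariant to any
per-descriptor affine rescaling, so the px/mm decision cannot change an
attribution.

### Segmentation

The scan is thresholded with the Otsu (bimodal-histogram) criterion —
parameter-free and well matched to high-contrast scanner images. Polarity
follows the recorded background mode, so foreground is always "seed".
Foreground components are 8-connected with 4-connected background (the
standard duality); interior holes are filled before measurement so that
scanner speckle inside a seed cannot masquerade as concavity. Components
below a minimum area are dropped, as (optionally) are components touching
the image border. Touching seeds are *not* separated: they produce one
merged mask and a warning, on the assumption that an operator lays seeds
apart on the glass. Masks are ordered by centroid (top-to-bottom, then
left-to-right) and identifiers assigned in that order, which makes
segmentation fully deterministic.

### Boundary tracing and the perimeter dialect

The outer boundary is traced with Moore-neighbour tracing (Jacob's
stopping criterion) through the centres of boundary pixels — foreground
pixels 4-adjacent to background — yielding a closed counter-clockwise
polygon. The perimeter is the polygon's arc length: steps of 1 between
4-neighbours and sqrt(2) between diagonal neighbours, with **no
corner-smoothing correction**.

This dialect matters. An uncorrected 8-chain overestimates the length of a
smooth continuous outline by the angle-averaged factor
`8(sqrt(2)-1)/pi ≈ 1.0548`. Consequently, on a digitized disk the measured
circularity converges not to 1 but to `pi^2 / (64 (3 - 2 sqrt 2)) ≈ 0.899`,
and convexity (hull perimeter over boundary perimeter) to about `0.95`.
The tests assert monotone convergence to these dialect asymptotes. Users
comparing against software that applies a corner correction should expect
systematically smaller perimeters (and larger circularities) there; within
a single pipeline the bias is common to all specimens and is immaterial to
discriminant classification.

### The 26 descriptors

Primary: `Perim`, `Area` (shoelace area of the boundary polygon),
`Pixels` (foreground count), `MinR`/`MaxR` (min/max distance from the
pixel-mass centroid to boundary-polygon vertices — "the middle of the
seed" is taken to be the centroid, the only parameter-free choice),
`Feret` (maximum caliper diameter, rotating calipers over the convex
hull), `Breadth` (caliper extent perpendicular to the Feret direction, so
`ArBBox = Feret * Breadth` is the Feret-aligned bounding box), `CHull`
(convex-hull perimeter — a length, for dimensional consistency of the
ratios that divide by it), `CArea` (hull area) and `MBCRadius` (minimal
enclosing circle of the hull vertices, Welzl's move-to-front algorithm
with a fixed-seed permutation for determinism and expected-linear running
time on points in convex position).

Derived, exactly as conventionally printed for this descriptor set:
`AspRatio = Feret/Breadth`, `Circ = 4*pi*Area/Perim^2`,
`Roundness = 4*Area/(pi*Feret^2)`, `ArEquivD = sqrt(4/pi * Area)`,
`PerEquivD` (see below), `EquivEllAr = pi*Feret*Breadth/4`,
`Compactness = sqrt(4/pi * Area)/Feret`, `Solidity = Area/CArea`,
`Concavity = CArea - Area`, `Convexity = CHull/Perim`,
`Shape = Perim^2/Area`, `RFactor = CHull/(Feret*pi)`,
`ModRatio = 2*MinR/Feret`, `Sphericity = MinR/MaxR`,
`ArBBox = Feret*Breadth`, `Rectang = Area/ArBBox`.

**PerEquivD.** The source descriptor list defines the perimeter-equivalent
diameter as `Area/pi`, although the conventional definition is
`Perimeter/pi`; the printed form is almost certainly an erratum (it has
area dimension, not length). The package implements the printed formula by
default (`perequivd_convention="as_printed"`, converted as an area under
mm units) and offers `"perimeter_over_pi"` for the conventional reading.
Since LDA is affine-invariant per descriptor, the choice does not affect
classification.

Degenerate specimens (fewer than 3 boundary pixels, zero polygon area,
collinear hulls) are rejected with a warning and listed in the table's
rejects; measurement fails outright only when every specimen is rejected.

## The classifier

### Stepwise Wilks'-lambda selection

With within-group and total SSCP matrices `W` and `T`,
`Lambda(S) = det(W_S)/det(T_S)` over the selected set `S`. At each step,
for `p = |S|`, `n` specimens and `g` classes:

    F_enter(x | S)   = (n - g - p)/(g - 1) * (Lambda_S / Lambda_{S+x} - 1)
    F_remove(x in S) = (n - g - p + 1)/(g - 1) * (Lambda_{S-x} / Lambda_S - 1)

The best excluded candidate enters if `F >= F_to_enter` *and* its
within-group tolerance `1 - R^2` against the included set (computed as a
determinant ratio of `W` submatrices) clears the tolerance threshold; then
any included descriptor with `F < F_to_remove` is removed, worst first.
Iteration stops at a fixed point, on a repeated state, or at `max_steps`.
Defaults — F-to-enter 3.84, F-to-remove 2.71, tolerance 0.001 — are the
long-standing conventions of the classic statistics packages for this
procedure; the thresholds correspond to the 5%/10% points of F(1, inf).
If nothing passes at step one the procedure raises rather than silently
returning an empty model.

### Discriminant, priors, cross-validation, allocation

Classification uses Gaussian linear discriminant scores with the pooled
within-class covariance `W/(n - g)`; posteriors come from a numerically
stable log-sum-exp. Priors default to **equal** across classes: reference
collection sizes reflect sampling convenience, not prevalence. Proportional
priors are available.

Cross-validation defaults to leave-one-out with selection performed
**once on the full labelled table**, each held-out specimen classified by
a discriminant refit without it. This mirrors the workflow of the classic
packages and is optimistic, since the held-out specimen influenced
selection; `reselect_per_fold=True` (CLI `--honest-cv`) re-runs selection
inside each fold. A `features=` override skips selection entirely — needed,
for example, to study null behaviour, where selection correctly refuses to
build a model at all. Stratified k-fold with a seed is available; LOO is
deterministic by construction. Classes reduced to a single specimen are
excluded from CV with a warning. Rows labelled `UNKNOWN` never influence
selection, fitting or CV; ties in the argmax posterior break
lexicographically by class label.

Allocation tables are row-stochastic percentage matrices. The printed
(one-decimal) view uses **largest-remainder rounding** per row, so every
row totals exactly 100.0 — naive per-cell rounding can drift by 0.05 per
column. The raw, unrounded percentages remain available on the object.
`overall_correct` is the count-weighted diagonal percentage.

A caution on interpreting LOO under the null: fold predictions are
correlated, so the null distribution of LOO accuracy is noticeably wider
than binomial (roughly 39–58% across seeds at n = 200 with 26 noise
descriptors) and slightly pessimistic on average. Chance-level results
should be judged with that in mind.

## The synthetic generator

Each class is a distribution over rotated superellipses
`|x/a|^m + |y/b|^m = 1`: semi-major axis `a` ("size_px"), semi-axis ratio
`b/a` ("aspect"), exponent `m` ("squareness": 2 = ellipse, large =
rectangle-like; truncated to [1.2, 100]), plus a low-order radial Fourier
perturbation `r(theta) * (1 + sum_{k=2..5} A_k cos(k theta + phi_k))` whose
total relative amplitude is set by `boundary_noise`. Parameters are drawn
from truncated normals around the class means; rotation is uniform; the
silhouette is rasterised by an inside test at pixel centres. One seeded
generator drives every draw, so a population regenerates bit for bit.

`render_scan` places masks on a grid with guaranteed spacing (no overlap
by construction) on a uniform background — dark seeds (~60) on light
(~245) for white mode, inverted for black — with per-seed intensity jitter
and mild Gaussian pixel noise, emulating a scanner image.

The default three-class bundle is loosely modelled on real seed dimensions
at 400 dpi (0.0635 mm/px): plum-stone-like (a ≈ 170 px ≈ 22 mm long),
watermelon-seed-like (a ≈ 100 px) and grape-pip-like (a ≈ 47 px), with
aspect and squareness chosen to give visibly different outline families.

`analytic_features` gives ground truth for the noise-free family,
independently of the raster pipeline: area from the closed form
`4ab * Gamma(1+1/m)^2 / Gamma(1+2/m)`, Feret/Breadth from a dense
parametric boundary sampling (4001 points; the diameter of a smooth convex
curve is second-order insensitive to sampling density, so this is accurate
to well below 0.1%).

**What the generator does not emulate:** real seed texture and shading
gradients, shadows and dust, waterlogging deformation and shrinkage of
archaeological material, asymmetries beyond low-order radial harmonics,
and seeds touching each other. Passing the recovery experiments therefore
demonstrates that the measurement and classification machinery is correct
and well-calibrated on silhouette-like material — not that any particular
real collection would reach the same accuracies.

## Problem sizes and numerical choices

The randomized invariant sweep uses 1000 masks from 20 heterogeneous
classes (sizes 30–80 px, aspects 0.35–0.95, squareness 1.6–3.5, noise up
to 4%). The end-to-end recovery experiment uses three classes sharing one
size distribution (60 ± 5 px) that differ only in aspect
(0.75/0.60/0.45) and squareness (2.8/2.2/1.8), 100 seeds per class, with
a 70-seed unknown cohort — discrimination there is purely shape-based.
Twenty seeded replicates of the full pipeline run in a few minutes.

Rotating-calipers Feret is exact (identical arithmetic to the brute-force
pairwise maximum, verified to 1e-9 on every sweep mask). The minimal
enclosing circle uses absolute tolerances around 1e-10 for in-circle and
collinearity tests, appropriate for coordinates up to a few thousand
pixels. Wilks' lambdas are computed via `slogdet` for stability; any
subset with a non-positive-definite submatrix is treated as inadmissible.
The pooled covariance must pass a Cholesky check, otherwise fitting raises
a collinearity error.

## Known limitations

- No watershed separation of touching seeds; lay seeds apart or accept
  merged masks (flagged by count mismatches in the pipeline).
- The perimeter dialect is uncorrected chain length (see above); compare
  across software with care.
- Stepwise selection is greedy; it matches exhaustive best-subset search
  on well-separated instances (verified) but carries no global optimality
  guarantee in general.
- Default cross-validation is the optimistic variant (selection on the
  full table); use `--honest-cv` for unbiased accuracy estimates.
- Only silhouette (binary) information is used: no colour, texture or
  3-D measures, and no elliptic Fourier outline descriptors.
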