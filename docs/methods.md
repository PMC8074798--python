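# Methods

This note documents the quantitative models implemented in
`harvestledger`, the choices made where the underlying field protocol
leaves them open, and what the synthetic-data experiments do and do not
demonstrate.

## Reference AGB from a weighed harvest

A harvested tree's green mass is weighed in two pools: the **stem** (bole
from flush with the ground to the first fork, including the stump) and
the **crown** (everything above the fork). Reference dry mass is

    AGB_ref = (m_stem + m_crown) / q_m + S,

where `q_m` is the whole-tree green-to-dry **mass** ratio and `S` the
swarf correction. `q_m` is estimated by the mass-weighted approach:
subsample ratios are averaged per pool and the pool means combined with
green-mass weights. The implied moisture fraction is `1 − 1/q_m`
(≈ 0.38–0.42 for the campaign ratios of 1.617–1.731).

**Swarf.** Each manageable stem section costs one chainsaw kerf, modelled
as a cylinder of the section's representative diameter (mean of its end
diameters) and a cut width of 8.4 mm (caliper-measured field average,
configurable). Lost dry mass is kerf volume × green woody density / `q_m`,
which collapses to kerf volume × basic density. Whether N sections imply
N or N−1 physical cuts is not observable from the tables; the default is
one kerf per section, with a configurable integer offset. The crown is
deliberately left uncorrected, so the correction (0.7–1.8 % of AGB on the
campaign trees) is a lower bound on true losses. The crown mass ratio is
computed on dry mass with swarf assigned to the stem.

**Geometric cross-check.** Converting stem section length/diameter records
to volume with Smalian's formula, `V = L (A₁ + A₂)/2`, and multiplying by
green density gives a geometry-derived stem mass. Smalian's formula
upper-bounds the true conical-frustum volume (arithmetic-vs-full mean of
the end areas; equality only for equal ends), which is one reason
geometry-derived reference data overestimate — the package treats weighed
mass as the reference and reports the geometric error alongside.

## Whole-tree basic woody tissue density

Basic density (dry mass / green volume, kg m⁻³) is computed per subsample
and aggregated three ways:

- **mass_weighted** — unweighted subsample mean per pool, pools combined
  by green mass. Subsamples are deliberately not weighted within a pool:
  the disc protocol (blocks spanning the full major axis) already samples
  the radial profile, and pool green mass is the only mass measurement
  available at that granularity.
- **stem** — mean of the two outer subsamples of the breast-height disc,
  mimicking an increment-borer core. Outer blocks are identified
  positionally (first/last along the major axis).
- **literature** — mean of exact species-level matches (case-folded,
  whitespace-normalised) in a wood-density table. No genus fallback: a
  missing species is an error, not a silent substitution.

Green volumes absent at ingest are imputed as dry volume × the tree-mean
green-to-dry **volume** ratio from subsamples that measured both, falling
back to a caller-supplied campaign mean with a logged warning.

The symmetric percentage difference `100 |a−b| / ((a+b)/2)` is the default
comparison between density approaches (a plain relative form is
available); on the campaign values it gives 3/3/14/21 % between
mass-weighted and literature estimates.

## Non-destructive estimators

**Allometry.** `AGB = a (D² H ρ)^b` with D in cm, H in m, ρ in g cm⁻³,
output kg. Defaults a = 0.0673, b = 0.976 (the pan-tropical
diameter-height-density model fitted on 4004 harvested trees). The
coefficient is often printed rounded to 0.067; the unrounded default
reproduces the campaign's published estimates to < 0.05 % where the
rounded value sits ≈ 0.45 % low, and the rounded model is exposed as a
named constant. The ρ unit is g cm⁻³ (a printed "g cm⁻¹" in some sources
is a typo — the quantity is a density).

**QSM volume × density.** Total cylinder volume `Σ π r² ℓ` of a
TreeQSM-style cylinder table times a basic density. The stem/crown
boundary is branch order 0 vs ≥ 1 (the first fork), mirroring the harvest
stem definition. Leaf volume is assumed absent from the QSM (leaf returns
are removed upstream) and no leaf-mass term is added. Order-0 volume is
reported as-is, including any below-fork stump region the QSM covers.

## Error framework

With `ε = AGB_est − AGB_ref` and `RE = |ε| / AGB_ref`, the package
reports MRE (mean RE), ME (trueness), STDEV of ε (precision) and RMSE
(accuracy), all in population (1/n) form, so `RMSE² = ME² + STDEV²` holds
exactly; the published campaign's lidar RMSE of 191.1 kg violates that
identity for its own ME/STDEV pair and is treated as a misprint of the
implied 198.1 kg. Summed RE compares cumulative estimated and reference
AGB. `error_size_slope` regresses |ε| (or RE) on AGB_ref by OLS and flags
size dependence when the 95 % CI excludes zero — additive error shows no
trend in |ε|, multiplicative error no trend in RE.

## Crown metrics

Crown base is the height of the first fork (lowest order-1 cylinder
start); from point clouds it must be supplied, since a cloud alone does
not define the fork. The crown "major axis" is the maximum pairwise
horizontal distance between crown points (endpoint radii added for QSMs),
computed via the 2-D convex hull; an ellipse or area-equivalent definition
would give smaller values for irregular crowns. Aspect ratio is major
axis / crown height.

## The synthetic generator

`synthetic_data` emulates the campaign's measurement process on trees
with known ground truth:

- **Architecture** — a vertical stem of stacked conical frusta with power
  taper (exponent 1.5, top/base radius 0.55), calibrated so the diameter
  at 1.3 m equals the drawn D ∈ [0.6, 1.2] m; height `40 D^0.4` m
  (≈ 33–43 m); a fork at 0.44–0.60 of height; 3–5 first-order branches
  with recursive order-2/3 children. Branch radii are rescaled so the
  crown holds a drawn 0.42–0.62 of dry mass — the crown mass fraction is
  a study condition, not an emergent property.
- **Density field** — `ρ(h, r) = ρ₀ (1 + a h/H + b r/R)`, ρ₀ ∈ [560, 770]
  kg m⁻³, per-tree gradients a, b ∈ [−0.1, 0.1] spanning both signs
  (observed intra-tree trends are unsystematic between trees). Segment
  dry mass integrates the field exactly (volume-weighted mean height,
  radial mean 2/3).
- **Harvest protocol** — stem sections of 0.15–0.54 m (stump 1 m), crown
  sacks capped at 400 kg (crane capacity), green masses rounded to the
  0.1 kg scale division; discs at 1.3 m and 25/50/75 % of stem length plus
  branch-order midpoints; 150 × 50 × 50 mm subsamples spanning each disc
  diameter, outer blocks first/last. Subsample noise: density σ = 15
  kg m⁻³, g2d mass ratio σ = 0.02.
- **Swarf** — kerf volumes are priced at the tree's mass-weighted density
  (solved as a fixed point of the pipeline's own estimator), not the local
  density at each cut. This is the one place the generator is written to
  the analysis convention: it makes the bookkeeping exactly
  self-consistent, so with all noise off the pipeline's AGB_ref equals
  true dry mass to machine precision — the end-to-end identity the test
  suite asserts at 10⁻⁹.
- **QSM error** — cylinders are volume-preserving equivalents of the true
  frusta, radii scaled by a single per-tree lognormal factor
  (σ_V = 0.04 on volume) so total-volume error is multiplicative and
  size-independent; branches thinner than 5 mm are omitted (a small
  negative bias). With these defaults the QSM estimator's tree-scale MRE
  is ≈ 3–4 %.
- **Allometric error** — the allometric formula applied to the synthetic
  tree's D, H and estimated density, times a lognormal residual
  (σ = 0.3). Both the residual and the model-form mismatch are
  multiplicative, so absolute error grows with tree size — the contrast
  with the QSM-like estimator that the cohort experiments quantify.

What the generator does **not** emulate: occlusion or any optics of laser
scanning (QSM error is statistical, not ray-traced), internal rot and
cavities, bark/wood tissue partitioning, leaf mass, buttresses, and
within-disc density structure beyond the linear radial gradient. Passing
synthetic tests therefore demonstrates the correctness of the
bookkeeping, the estimators and the error framework under the stated
error models — not the field performance of lidar scanning itself.

## Numerical choices

- Masses kg, lengths m, densities kg m⁻³ internally; subsamples keep
  laboratory g/cm³; the allometric boundary converts D→cm, ρ→g cm⁻³.
- Whole-tree densities are sanity-checked against (50, 1500) kg m⁻³;
  green-to-dry ratios must be ≥ 1 (a dry mass above green mass warns but
  does not abort, since it can arise from instrument noise on small
  blocks).
- CSV readers parse floats in round-trip precision mode so a write/read
  cycle preserves every numeric field bit-exactly; reports are written at
  fixed precision (default 1 decimal) for byte-identical reruns.
- Randomness: one integer seed; each synthetic tree uses the
  `SeedSequence([seed, index])` substream, so cohorts are reproducible
  under reordering and single trees can be regenerated in isolation.
- Cohort sizes in the shipped experiments (100 trees for the error-size
  contrast, 200 replicates for density recovery, 3 trees for the
  noiseless identity) are chosen so every experiment runs in seconds at
  desk scale while leaving the statistical conclusions unambiguous.

## Known limitations

- Only tree-level aggregates of the published campaign are available, so
  campaign-derived checks are fixture-consistency checks; per-section and
  per-subsample behaviour is validated on synthetic data only.
- The stem density approach's bias under radial gradients depends on disc
  geometry (outer blocks over-represent the periphery); the generator
  reproduces the mechanism but its magnitude is protocol-specific.
- The literature approach requires exact species matches; campaigns with
  unresolved taxonomy need their own fallback policy before ingest.
- The error-size regression on n = 4 trees has very low power; it is
  reported for completeness but only the synthetic cohorts give it
  statistical meaning.
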