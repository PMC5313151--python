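# Methods

## Scope and model structure

`compsd` implements a two-stage definition of a tree species' potential
distribution. Stage one is purely abiotic: per-cell responses to normalized
photosynthetically active radiation (nPAR, 0–1), soil water content (SWC,
scaled so 0 is the permanent wilting point and 1 field capacity) and growing
degree days (GDD, °C·day over a 5 °C base) are multiplied into an original
PSD index in [0, 1]. Stage two corrects that index for interspecific
competition, which abiotic suitability cannot see: an individual-based gap
model is run per landscape class ("forestland type"), the resulting
replicate-mean species biomass is converted to relative competitive ratings
(P100), and the original PSD is multiplied by the rating of the cell's type.
Because P100 ∈ [0, 1], revision is a pure shrinkage operator on the map.

## Response kernels

- Light response `c1·(1 − exp[−c2(nPAR − cp)])` is negative below the
  compensation point `cp` and can exceed 1 for `c1 > 1`; output is clamped to
  [0, 1] so that the PSD product remains a 0–1 index. Values outside that
  range have no interpretation in the suitability algebra.
- The soil-water curve is normalized so that its value at the optimum ψ is
  exactly 1: with χ the normalized optimum position, α = χ/(1−χ) and
  κ = 1/(χ^α (1−χ)^{1/α}), the response κ·ξ^α(1−ξ)^{1/α} peaks at ξ = χ.
  Outside (SWC_min, SWC_max) the power expressions are undefined and the
  response is defined as 0, consistent with tolerance-limit semantics.
- The degree-day parabola is symmetric about the window midpoint and clamped
  at 0 outside the window.
- All kernels vectorize over rasters and propagate NaN (nodata) untouched;
  no silent filling anywhere in the pipeline.

## Gap model

The simulator follows the classic JABOWA-family forms; all constants are
exposed on `GapConfig`:

- Height allometry `H = 137 + b2·D − b3·D²` with `b2 = 2(H_max−137)/D_max`,
  `b3 = (H_max−137)/D_max²`, so `H(D_max) = H_max` with zero slope.
- Optimal increment
  `dD = G·D·(1 − D·H/(D_max·H_max)) / (274 + 3 b2 D − 4 b3 D²)`, floored at
  0 and capped so DBH never exceeds `D_max`.
- Shading: trees are ranked by height; available light under the leaf area
  of strictly taller trees is `AL = exp(−k·LAI_above)` with extinction
  coefficient k = 0.4 per unit LAI. A tree contributes
  `0.08·D²/plot_area` to the patch LAI; on the default 100 m² patch this
  makes roughly eight 28-cm canopy trees a closed canopy (LAI ≈ 5). With
  the coefficient set much higher a single large tree casts essentially
  total darkness, which extinguishes the tolerant understorey and turns the
  model into a pure gap-cycling system; 0.08 keeps a persistent shade-
  tolerant bank, the mechanism that produces late-successional dominance.
- The light multiplier runs `AL` through a tolerance-class light-curve
  archetype: class 1 (least tolerant) uses the steep high-compensation-point
  curve (c1 = 2.24, c2 = 1.136, cp = 0.08), class 5 (most tolerant) the
  early-saturating low-compensation-point curve (1.0, 4.64, 0.05);
  intermediate classes interpolate linearly.
- Realized growth = optimal × light × R_GDD × R_SWC × nutrient index. Soil
  nutrients are collapsed to a single 0–1 multiplicative index because the
  landscape surfaces carry no nutrient information.
- Mortality: intrinsic `p = 4/age_max` per year (≈ e⁻⁴ of a cohort reaches
  its maximum age) plus stress mortality 0.368 after two consecutive years
  with increment < 0.01 cm (suppressed trees die within about a decade).
- Establishment: a species recruits Poisson(recruit_rate) saplings
  (0.5–2.5 cm DBH) per year when site GDD and SWC fall strictly inside its
  tolerance windows and forest-floor light exceeds its compensation point.
- Annual order is fixed: growth → mortality → establishment. No exogenous
  disturbance is modeled beyond gap formation by canopy death and
  self-thinning.
- Replicates use derived streams seed+r, making replicate means bit-for-bit
  reproducible.

## Competitive ratings

Within each forestland type, species shares of total replicate-mean biomass
are divided by the row-maximum share, so every type has exactly one (or, on
ties, several) species at 1.0 and eliminated species at 0. This row-wise
reading is the only one consistent with a ratings table whose every row
contains a 1. An alternative definition — biomass as a proportion of the
species' own monoculture optimum before rescaling — is provided as
`p100_matrix(..., mode="monoculture")` for users who can supply per-species
optimum runs; the two definitions are not equivalent and the share-based one
is the default.

## Forestland classification

The landscape is partitioned by seeded k-means (scikit-learn, k-means++
initialization, 10 restarts) over per-cell species-PSD vectors, a
deliberately simple stand-in for hybrid unsupervised–supervised
classification schemes used operationally. Cluster ids are renumbered by
decreasing size so the partition is stable under species reordering, and
types are auto-labelled by their up-to-three species with centroid
suitability ≥ 0.2 ("rS-wP-eH" style). The default of 12 types matches common
practice for a mixed Acadian-forest landscape and is a flag, not a constant.

## Accuracy assessment

Predicted presence is strict: PSD > 0.25. Per species, a 2×2 table of
predicted × observed presence gives overall agreement 100·(n_pp+n_aa)/N and
Cohen's kappa (P_o − P_e)/(1 − P_e) with marginal-product expected agreement;
kappa of a degenerate table (P_e = 1) is 1 if agreement is perfect, else 0
with a warning. N is always the sum of the four cells. Across-species means
are unweighted arithmetic means. Verbal classes follow the Monserud–Leemans
bins (<0.20 poor, 0.20–0.40 fair, 0.40–0.50 moderate, 0.50–0.70 good,
0.70–0.80 very good, ≥0.80 excellent), half-open on the upper bound.
Printed-report rounding uses decimal half-up (81.25 → 81.3), matching the
convention of published assessment tables. Plots on nodata or unclassified
cells are excluded and counted in the log.

The bundled `assessment_original.csv`/`assessment_revised.csv` tables
transcribe a published 16-species validation; the header of that source is
ambiguous about which middle column is the false positive, so the columns
are stored in printed order as (n_pa, n_ap) — agreement and kappa are
invariant to the choice. A few printed rows are internally inconsistent
with their own counts by one unit in the last digit; the package recomputes
from counts and does not attempt to reproduce those rows.

## Synthetic landscapes

The generator emulates the *shape* of real inputs, not any particular
region: Gaussian-smoothed seeded white noise rescaled affinely to each
variable's range gives spatially autocorrelated surfaces with a controllable
correlation length (default 10 cells on a 200×200 grid of 70 m cells;
default GDD range 900–2500 °C·day). Species parameters are drawn to honor
every validation invariant, with tolerance classes cycling 1–5 and a
longevity-for-growth-rate trade-off across classes; at least every other
species receives a degree-day window centred inside the landscape's range so
a mixed community always exists. Plot observations flip the generating truth
independently with probability ε, so a perfect model scores exactly
100·(1−ε) in expectation — the basis of the end-to-end recovery checks
(ε = 0 → 100% and κ = 1; ε = 0.1, 2000 plots → 90% within binomial error).

What passing these tests does *not* show: real abiotic surfaces have
cross-correlations, anisotropy and process-driven structure that smoothed
noise lacks; real observation error is spatially and taxonomically
structured, not independent Bernoulli noise; and the bundled 16-species
parameter table is synthetic (the authoritative per-species values are not
machine-readable from any source available here), so absolute simulated
biomass levels are illustrative only.

## Problem sizes and numerical choices

Default test and acceptance runs use an 80×80 grid, 8 species, 4 forestland
types, 100-year simulations with 8 replicates per type (the one-patch
demography checks use the full 50-replicate protocol); these sizes keep a
full pipeline run under a minute while leaving every statistical check
comfortably powered. Ties in the shading rank (exactly equal heights) share
the same overhead leaf area rather than shading each other. Cell membership
of plot coordinates is half-open on the right/bottom edge. The PSD product,
rating rescaling and kappa are exact floating-point expressions with no
iterative numerics; k-means is the only iterative algorithm and is fully
seeded.

## Known limitations

- Raster I/O supports the ESRI ASCII grid format only (single band, explicit
  nodata); projection metadata is carried as an opaque label.
- The gap model is a compact member of its family: no explicit crown
  geometry, no soil depth/nitrogen submodels, no disturbance regimes.
- Forestland classification from PSD vectors alone cannot reproduce
  operationally derived type maps that used additional covariates.
- P100 ratings depend on the initial stands and parameter tables used for
  the per-type simulations; the package ships no claim that its synthetic
  defaults reproduce any published rating table.
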