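# Methods

`fcspat` implements the spatial point-pattern workflow used to ask whether
two sets of mapped objects in the same plot — bare-soil fairy circles (FCs)
and Euphorbia shrubs — could share a generating process. The workflow
combines nearest-neighbor statistics, second-order (scale-dependent)
statistics with Monte-Carlo null-model envelopes, a periodicity classifier,
and two small non-spatial comparisons (object diameters, water-infiltration
times).

## Data model

A pattern is a finite set of planar points (meters) in an axis-aligned
rectangular window of area `A`. All formulas are Euclidean; geographic
coordinates must be projected before use and the reader refuses input that
looks like lon/lat degrees. Exact duplicate coordinates are rejected rather
than jittered: fairy circles and shrubs are physical, non-overlapping
objects, so duplicates indicate digitization faults. Window presets exist
for the seven survey plots (five of 500 m × 500 m, plus 800 m × 330 m and
800 m × 400 m). When reading deposited coordinates whose origin is
unspecified, the declared window is by default re-anchored at
`(floor(min x), floor(min y))` of the data; a strict mode keeps the window
exactly as declared. A bounding box exceeding the declared window by more
than 5% is an error, not a guess.

## Nearest-neighbor statistics

With `λ = n/A`, the Clark-Evans index is `R = r̄_A / r̄_E`, where `r̄_A` is
the observed mean nearest-neighbor distance and `r̄_E = 1/(2√λ)` its CSR
(homogeneous Poisson) expectation. `R = 1` is random, `R < 1` clustered,
`R > 1` regular; a unit-spacing square lattice filling its window gives
`R = 2` exactly. Both terms are used **without edge correction** — the
convention under which the index has historically been reported for these
surveys — so the estimator carries a small positive edge bias (CSR draws
average `R` slightly above 1). For that reason significance never relies on
the classical normal approximation but on a conditional Monte-Carlo test:
`M` CSR patterns with the observed `n` are simulated in the observed
window, `R` is computed for each, and the two-sided rank p-value is

    p = min(1, 2 · (min(k_low, k_high) + 1) / (M + 1)),

with `k_low`/`k_high` the counts of simulated `R` ≤/≥ the observed value
(ties count toward the extreme tail, which is conservative). The test is
exact: its attainable p-values form a uniform grid with floor `2/(M+1)` —
0.002 at the default `M = 999`. The pattern label is Regular (p < α and
R > 1), Clustered (p < α and R < 1) or Random, with α = 0.05 by default.
The coefficient of variation of NN distances, `100 · sd/mean` with the
sample (n−1) standard deviation, accompanies `R`: near 0 for lattices,
about 52.3 for interior points of a large CSR pattern (the Rayleigh closed
form `100·√(4/π − 1)`), and large for clustered patterns.

## Second-order statistics

Ripley's K is estimated as

    K̂(r) = (A / (n(n−1))) · Σ_{i≠j} e_ij · 1[d_ij ≤ r],

with `e_ij` an edge-correction weight. The default is the translation
correction `e_ij = A / ((W−|dx|)(H−|dy|))`, exact and deterministic for
rectangles; Ripley's isotropic correction (exact circle-arc formula for
rectangles) and no correction are selectable. The L-transform
`L(r) = √(K(r)/π) − r` is computed from K̂ (0 under CSR; < 0 regular, > 0
aggregated) and is the preferred cumulative statistic at large scales
(defaults: r ≤ 250 m in 1 m steps, capped at half the shorter window side).

The pair-correlation function g(r) — the expected density of points at
distance r from a typical point divided by λ, equal to 1 under CSR — is
estimated with an Epanechnikov kernel of half-width `h`:

    ĝ(r) = A · Σ_{i≠j} e_ij · κ_h(r − d_ij) / (2π r n (n−1)).

`h` defaults to Stoyan's rule `0.15/√λ`; the bandwidth used is recorded in
the result and values at `r < h` are flagged unreliable (the kernel mass
there leaks past r = 0). The default grid is r ∈ (0, 50] m in 0.5 m steps;
r = 0 is excluded from all grids so the 1/r factor is well defined.
Validation includes a dual-route check against the closed-form Matérn
cluster g (`g(r) = 1 + A_ov(r)/(κ(πR²)²)` with `A_ov` the two-disc overlap
area), which the estimator matches within 8% at high intensity.

Simulation envelopes are pointwise: the statistic is evaluated on the same
grid for `M` CSR simulations conditional on `n`, and the rank-`k` smallest/
largest simulated values form the lower/upper envelopes, a two-sided
pointwise level of `2k/(M+1)` (defaults k = 5, M = 199: ≈ 95%). Since an
observed CSR curve is exchangeable with the simulated ones, the expected
fraction of grid points outside the envelopes is exactly the nominal level;
the calibration tests verify ≈ 5%. Excursions — maximal runs of grid points
strictly outside the envelopes — are recorded as intervals with sign.

## Periodicity classification

The published criterion for a spatially periodic pattern is verbal: the
g-function "strongly fluctuates" below and above the CSR envelopes at small
scales, reflecting approximately equal spacing to about six nearest
neighbors. The package operationalizes it as a trough-then-peak rule: a
below-envelope excursion at small r followed by an above-envelope excursion
whose peak lies within `[0.5, 1.5] × r̄_A`, in a pattern the Clark-Evans
test already labels Regular. Excursions shorter than 2 grid points are
treated as envelope noise (a single grid point strays outside 5% of the
time by construction). Patterns with significant excursions of both signs
but no trough-then-peak ordering are labeled "mixed"; otherwise the
Clark-Evans label is returned. The thresholds (peak window, minimum run)
are arguments, so sensitivity is auditable. Calibration: CSR inputs
classify "random" in ≥ 90% of draws; the periodic and clustered reference
regimes below classify correctly in 100/100 seeded draws.

## Synthetic regimes

The generators reproduce the study's pattern regimes so the full pipeline
is testable without the field coordinates:

- **Periodic FC regime** — hexagonal lattice, spacing 12 m, isotropic
  Gaussian jitter sd 1.5 m, 500 m window (≈ 2005 points, R ≈ 1.7). The
  jittered lattice is the simplest process with the six-equidistant-
  neighbor signature; a Gibbs/Strauss sampler would add complexity without
  changing what the tests can show.
- **Regular (non-periodic) FC regime** — simple sequential inhibition,
  n = 284, hard core 12 m: regularity without periodicity.
- **Random FC regime** — CSR with n = 113 in the 800 × 330 m window.
- **Clustered shrub regimes** — Matérn cluster processes (Poisson parents,
  Poisson offspring uniform in a disc; parents drawn in a window expanded
  by the cluster radius to avoid edge deficit). Matérn rather than Thomas
  because the uniform-disc offspring has a closed-form g for oracle
  testing. The main preset (65 parents/25 ha, radius 30 m, mean 2
  offspring) matches the mixed-plot shrub regime (E[n] = 130, R ≈ 0.83,
  CV ≈ 70); the tight Garub preset (35 parents/26.4 ha, radius 20 m, mean
  2.6) reproduces the very high CV (≈ 95–100) of that plot. A stationary
  Matérn process cannot reproduce that plot's printed R (0.80) and CV
  (95.3) simultaneously — clustering strong enough for the CV drives R
  lower — and the preset prioritizes the CV signature.
- **Diameters** — truncated normals on the printed [min, max] ranges at the
  printed means; the surveys report no spread, so sd is fixed at a quarter
  of the printed range.
- **Infiltration times** — lognormals with matched mean/sd, nine draws per
  side, means at the printed region values (equal 28 s/28 s on deep sand;
  109/85 s and 89/112 s elsewhere); the sd (7 s, 25 s, 25 s) is a free
  spread parameter of roughly a quarter of the means.

What the generators do **not** emulate: habitat heterogeneity (drainage
lines, rocky patches) that locally thins real patterns, measurement error
in digitized centers, and any interaction between the FC and shrub
patterns. Passing regime-recovery tests therefore shows the statistics
separate the idealized regimes, not that every field plot is classified
identically.

## Size and infiltration comparisons

Diameter groups are summarized by exact order statistics and the mean, and
compared with one-sided two-sample t-tests — Welch's unequal-variance form
with Welch-Satterthwaite df by default, since mega-circle and shrub
variances plainly differ; the pooled form is available for sensitivity.
The two Giribes shrub samples (10 + 30) are pooled into one 40-shrub group,
matching how the published comparison is phrased. Infiltration times get
means and medians per region × position only; attaching a hypothesis test
would overstate what the nine-per-side design supports.

## Numerical choices and problem sizes

- Pair enumeration uses a k-d tree restricted to `r ≤ r_max (+ h)`;
  kernel sums are chunked to bound memory.
- Envelope statistics for classification are evaluated on r ∈ (0, 25] m in
  0.5 m steps (the periodic signature lives below ~2 lattice spacings).
- Calibration runs use 1000 replicates at M = 199 for the type-I error,
  100 draws per regime for recovery, 100 replicates for envelope
  exceedance, and 1000 draws for size-test power; the acceptance script
  uses smaller replicate counts (400/20/50/500) chosen to keep a single
  CPU run within a few minutes while leaving Monte-Carlo error well inside
  the asserted bands.
- All simulation streams are `numpy` PCG64 generators seeded per call;
  results record the seed when given as an integer.

## Known limitations

- The deposited coordinate workbook is required to reproduce the published
  per-plot table; without it the reproduction test reports failure rather
  than silently skipping.
- The exact bandwidth, grid, and edge correction behind the published
  g-function figures are unstated; curve shapes can be matched
  qualitatively, printed NN/R values quantitatively.
- The isotropic correction assumes a rectangular window, as does the
  translation correction; irregular windows are out of scope.
- p-values from rank tests are floor-limited (0.002 at M = 999); printed
  values at the floor are reproduced categorically, not as continuous
  quantities.
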