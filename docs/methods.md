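# Methods

This note documents the statistical models and procedures implemented in
`cytoboot`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data tests do and do not establish about
real data.

## Data model and preprocessing

The atom is the `CellTable`: a cells × channels matrix of marker
intensities with per-cell donor/group metadata and an explicit scale
state. Raw ion-count intensities are nonnegative and heavily
right-skewed; all analysis runs on the arcsinh scale,
`y = asinh(raw / c)` with cofactor `c = 5`, the common convention for
mass cytometry. The cofactor is configurable; nothing downstream depends
on its exact value beyond the usual variance-stabilisation trade-off.
Raw data live on disk (FCS 3.0/3.1 or delimited text, written by the
package's own minimal FCS codec); the arcsinh state exists only in
memory, which prevents double transforms by contract.

Donor and group labels are never stored inside FCS files: one file per
donor-sample, linked to a design table by filename, matching how public
cytometry depositions are organised.

## Donor-bootstrap logistic GLM

For a contrast (reference, comparison), each cell contributes one
Bernoulli observation whose outcome is its donor's condition and whose
predictors are the standardized arcsinh expressions of the selected
markers. Coefficients are log-odds per 1 SD, so effects are comparable
across markers on one forest plot. Fitting is Newton–Raphson with
step-halving (gradient tolerance 1e-8, max 100 iterations).

Cell-level likelihoods ignore within-donor correlation, so standard
errors must come from resampling the independent units. The cluster
bootstrap resamples donors with replacement within each group stratum,
preserving group sizes; for paired contrasts, pregnant↔post-partum pairs
are resampled as single units. Each resample reuses the scaling fitted
once on the full assembled contrast (so all resampled coefficients share
one scale) and the percentile interval at level 0.95 is read off the
bootstrap coefficient distribution. Significance is exactly "the CI
excludes zero"; no multiplicity correction is applied beyond that
per-marker rule, which is a documented limitation.

Design choices worth knowing:

- **Balancing subsample.** By default every donor is downsampled (without
  replacement, seeded) to the minimum donor cell count, so high-count
  donors cannot dominate the cell-level likelihood. Configurable off.
- **Canonical orientation.** The fit is always performed with the outcome
  indicator set to the alphabetically later group label and signs flipped
  afterwards if the requested comparison is the other group; bootstrap
  draws visit strata in sorted-label order. Reversing a contrast therefore
  negates every point estimate bitwise and mirrors every CI, rather than
  agreeing only to optimizer tolerance.
- **Separation.** Complete or quasi-complete separation has no finite
  maximum-likelihood estimate. A fit is flagged `separated` when the
  coefficient norm diverges (max |β| > 30 during iteration) or when, at
  convergence, every cell sits on the correct side of the boundary
  (all classification margins ≥ 0) with max |β| > 10. A separated
  bootstrap resample is refit with a tiny ridge (1e-6 on slopes, never
  the intercept), kept in the percentile distribution if finite, and
  counted in `n_failed_resamples`; more than 20% failures aborts the
  analysis with advice to reduce the marker panel or increase cells.
- **Seeding.** One model seed expands deterministically into a
  subsampling stream and a bootstrap stream, so results are reproducible
  and independent of donor-file or cell order (the latter to float
  rounding).

With ~10 donors per group, percentile cluster-bootstrap intervals are
known to be slightly anti-conservative; the calibration benchmark
(below) quantifies this at roughly double the nominal 5% rate, which is
the expected small-cluster behaviour, not a defect of the resampling.

## Fisher LDA on donor medians

The LDA observation is the donor-sample — the median arcsinh expression
profile of the donor's gated population — never the cell: donors are
the independent units, and cell-level LDA would pseudo-replicate.
Axes are the leading eigenvectors of `(S_W + λI)⁻¹ S_B` (within- and
between-class scatter), normalized to unit Euclidean norm, at most
(groups − 1) of them. `λ` defaults to 0 when there are more donors than
markers and to `1e-3 · trace(S_W)/m` otherwise, since a ~40-marker panel
with ~50 donor-samples sits near singularity; a singular `S_W` at λ = 0
raises an error advising shrinkage. Marker contributions are axis
coefficients scaled by the pooled within-class SD; rankings sort by
absolute contribution with alphabetical tie-breaks, and each axis's sign
is fixed so its largest-magnitude contribution is positive. The fit is
fully deterministic.

## Gating

Manual gating is replaced by declarative per-study thresholds on the
arcsinh scale: a root conjunction (live by viability channel, then
CD3⁻CD19⁻CD20⁻CD14⁻) and terminal populations on top. Polarity `above`
keeps strictly greater values, `below` keeps less-or-equal, which fixes
every tie-break. The CD56dim/CD56bright split uses two CD56 thresholds
with a CD16 conjunction — bright: CD56 > hi and CD16 ≤ t; dim:
lo < CD56 ≤ hi and CD16 > t — disjoint by construction. Thresholds are
configuration tuned to the synthetic generator's bimodal CD56/CD16
structure; they make no claim about any particular instrument or panel.
Per-donor positive/co-expression frequencies count cells above all
listed thresholds; a donor with an empty denominator keeps an explicit
flagged row instead of silently disappearing.

## Nonparametric group comparisons

Unpaired contrasts use the Mann-Whitney U (0.5 credit per tie); paired
pregnant↔post-partum contrasts use the Wilcoxon signed-rank on
comparison-minus-reference differences over complete pairs, discarding
zero differences (the classical, deterministic convention rather than
Pratt's). Both tests are exact by full enumeration — all C(n1+n2, n1)
labelings when n1+n2 ≤ 12 (or ≤ 20 tie-free), all 2ⁿ sign patterns when
n ≤ 15 — because cohort group sizes of 10–30 make enumeration cheap and
the p values then carry no approximation at all. Beyond the crossover,
the normal approximation with tie-corrected variance and a 0.5
continuity correction takes over; the two branches agree within 0.02
absolute p at the crossover on tie-free data. Two-sided p doubles the
smaller tail, capped at 1. Stars follow * p < 0.05, ** p < 0.01,
*** p < 0.001.

## Synthetic study generator

The generator emulates the structure such analyses assume, with full
ground truth for recovery testing. Per cell and marker on the arcsinh
scale: population mixture draw, donor random effect `u ~ N(0, τ²)`
shared across the donor's cells (and reused in the paired post-partum
sample), condition shift `δ` added in the affected group (optionally
restricted to populations, e.g. NKp46 on CD56dim only), cell noise
`N(0, σ²)`; then `raw = c·sinh(max(y, 0))` followed by structural zeros
with probability π. The floor at 0 before inversion guarantees
nonnegative raw values and makes the transform exactly invertible; it is
a deliberate truncation, rare when μ is a few σ above zero. A
cisplatin-like viability channel separates dead from live cells by 8
pooled SDs so threshold gating is near-perfect by design.

Defaults are study-shaped: 21 donors per group in control / pregnant /
post-partum with pregnant↔post-partum pairing, a ~20-marker NK panel
with zero inflation on several functional receptors, a PBMC mixture
(44% T, 28% monocyte, 10% B, 10% CD56dim NK, 3% CD56bright NK, 5% dead)
with bimodal CD56/CD16 offsets, and a pregnancy signature of +0.5 on
CD38 (both NK subsets) and NKp46 (CD56dim only). Randomness flows from
a single seed through a study → latent-donor → sample hierarchy, so
regeneration is byte-identical.

What the generator does *not* emulate: spillover, acquisition drift,
doublets, batch effects between cohorts, or any non-Gaussian shape of
real arcsinh intensities beyond zero inflation and the floor. Passing
recovery tests therefore shows the estimators do what they claim under
the stated model, not that real cytometry data satisfy that model.

## Benchmarks and problem sizes

The reference benchmarks (in `cytoboot.benchmarks`, run by both the test
suite and `scripts/acceptance.py`) use a two-group pure-NK geometry of
10 donors per group × 1000 cells × 10 markers with τ = 0.3 and 200
bootstrap resamples, 50 replicate studies for calibration (no effects)
and power (δ = 0.5 on CD38 and NKp46), and an end-to-end pipeline study
of 10 donors per group × 3000 cells with the full PBMC mixture and
δ = 0.6 (20 replicates). These sizes keep a full benchmark run in a few
minutes while leaving Monte-Carlo error well below the margins being
tested.

## Known limitations

- Percentile CIs with ~10 clusters per stratum are mildly
  anti-conservative; BCa or studentized intervals are out of scope.
- No mixed-effects (GLMM) estimation, covariate adjustment, or
  multiplicity correction.
- Gate thresholds are static configuration; no density-based automatic
  gating.
- The Normal-on-arcsinh-scale generative model is an assumption; real
  raw-intensity distributions are not modelled beyond it.
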