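# Methods

## Data model

Observations are methylated counts `m_kij` out of coverage `c_kij` for
group `k`, subject `i`, CpG site `j`, assumed binomial given the
subject- and site-specific methylation rate. Sites carry 1-based
base-pair positions (matching bismark coverage files); BED export
converts to 0-based half-open. When assembling a dataset from multiple
coverage files, the default merge keeps the intersection of sites —
both tests need every sample observed at every tested site — with an
opt-in union mode that zero-fills missing sites. Sites where any group
has zero total coverage are excluded from testing (the group rate is
undefined there) and logged.

## Covariate adjustment

A single binomial logistic regression is fitted to all samples jointly,

    logit p = β₀ + β₁′x_i,

with trials equal to coverage and the sample-level covariates `x_i`
(never the group label — the group effect is the hypothesis). Because
the linear predictor depends only on the sample, the fit is computed on
per-sample totals (identical likelihood). The *adjusted methylation
count* is the residual `r_kij = m_kij − p̂_kij c_kij`; with an intercept
the residuals sum to zero over all cells (logistic score equation), and
with no covariates the whole stage reduces to subtracting the pooled
rate Σm/Σc.

For the scan test the adjustment can instead use a marginal
estimating-equation fit with an exchangeable (compound-symmetry)
within-subject working correlation and robust sandwich covariance, which
keeps the coefficients consistent when sites within a subject are
correlated even if the working structure is wrong. With no covariates
the marginal mean model is a single rate and the fit coincides exactly
with the pooled proportion, so the package short-circuits to the simple
adjustment in that case (this also makes permutation loops cheap: the
adjustment excludes the group label, so it is computed once and reused
across permutations). Estimation failure falls back to the independence
fit with a logged warning.

## Kernel distance test

Per site, group sums `r_kj = Σ_i r_kij` and `C_kj = Σ_i c_kij` give
group effects `β̂_kj = r_kj/C_kj` and the difference `δ_j = β̂_Aj −
β̂_Uj`. The statistic is the quadratic form `Q(τ) = δ′A(τ)δ` with the
tri-weight kernel `A_jl = (1 − (d_jl/τ)²)³` on distances up to the
bandwidth τ, zero beyond. Because the DMR length is unknown, Q is
maximised over a bandwidth grid; the default grid is 10 values linearly
spaced from the smallest adjacent inter-site spacing to half the region
span (a single fixed τ is supported and is what the calibration study
uses, τ = 6 in site-index units). Ties in the argmax resolve to the
smallest bandwidth. Distances can be in bp (real data) or site-index
units (equally spaced simulated sites).

Inference is by permutation only: subject group labels are shuffled B
times, δ and the τ-maximised Q recomputed (vectorised over all
permutations), and `p = (1 + #{Q_perm ≥ Q*})/(B + 1)` with ties counted
as exceedances, which keeps p in (0, 1]. A scaled-chi-square
approximation would only be valid for a single fixed bandwidth and is
not implemented. Per-site contributions `U_j(τ*)/Q(τ*)` (summing to 1
when Q ≠ 0) provide localisation; a single DMR call is derived as the
contiguous run of sites, containing the top contributor, whose
contribution exceeds a configurable quantile (default 95th) of the
per-site contributions. The quadratic form is label-symmetric (δ → −δ),
so the test is invariant to which group is called "case".

## Binomial scan test

The scan works on group-level counts per site, corrected in three steps:

1. **Recentring.** Zero-mean residuals cannot feed a binomial
   likelihood, so the grand-mean fitted count is added back per cell:
   `R = m − (p̂ − p̄)c` with p̄ the coverage-weighted mean fitted rate,
   clamped to [0, C] after group summation. With no covariates this
   returns the raw methylated counts exactly, so the calibration study
   is unaffected by the choice.
2. **Design effect.** Reads within a sample-site cell are correlated;
   treating each sample's reads at a site as a cluster, the intra-site
   intraclass correlation ρ̂_j is estimated by the one-way ANOVA moment
   estimator across samples (clipped to [0, 1)), and group counts are
   deflated by `deff_kj = max(1 + (c̄_kj − 1)ρ̂_j, floor)` with `c̄_kj`
   the group's mean coverage — the classical variance-inflation
   correction for clustered binary data, a no-op when ρ̂ = 0 or c̄ = 1.
3. **Pseudo-counts.** One methylated and one unmethylated read per
   group and site (`r̃ → r̃+1`, `C̃ → C̃+2`) keep every window proportion
   strictly inside (0, 1).

For every window (all start offsets × the configured size grid; default
sizes 5–30 sites, step 1; the calibration study uses the single size 6),
the statistic is the binomial log likelihood ratio of separate group
rates versus a common rate, evaluated on the real-valued deflated
counts; it is ≥ 0, zero iff the proportions coincide, equals half the G²
deviance of the corresponding 2×2 table, and scales linearly with
coverage at fixed proportions. An algebraically equivalent form written
in the coverage-share/methylated-share parameters is kept in the test
suite as an independent oracle. The global statistic is the maximum over
all windows; for G ≥ 2 nominal groups the statistic generalises to the
multinomial form with per-group MLEs (ordered group labels are not
supported — the order-constrained MLE is intractable).

Permutations shuffle subject labels *before* group aggregation — the
ICC ρ̂ is label-free, while group coverage sums and design effects are
rebuilt per permutation — and record the permuted global maximum. The
global p-value compares the observed maximum to that null; per-window
p-values compare each window's LR to the *same* max-statistic null,
which controls family-wise error across windows. Multiple DMRs are
called greedily: among windows with p ≤ α, repeatedly take the largest
LR whose site span does not overlap an already-selected window, then
report calls in genomic order.

## Synthetic data generator

The generator emulates the study design used to validate the tests:

- Independent draws `X_kij ~ Beta(α_U, β_U)` everywhere, except
  `Beta(α_A, β_A)` for cases inside a run of `r` consecutive sites
  centred in the region (centering ties resolve to the lower index).
  Defaults: α_U = 0.1, β_U = β_A = 0.9, 24 sites, 6-site DMR, 24 + 24
  subjects. The effect size is the Beta-mean difference
  `d = α_A/(α_A+β_A) − α_U/(α_U+β_U)`.
- Spatial dependence through a Gaussian copula: each subject's site
  vector is transformed as `p = 1 − Φ(C Φ⁻¹(1 − X))` with `C` the
  Cholesky factor of `Σ_ij = ρ/|i−j|` (unit diagonal). The transform is
  applied in exactly this form; note that because `Φ⁻¹(1 − X)` is not
  standard normal for non-uniform Beta draws, the transform shifts the
  marginals whenever ρ > 0 — deliberately retained, as the calibration
  targets are defined under this generator. An optional `proper_copula`
  mode maps draws through their Beta CDF first (preserving marginals
  exactly) and is off by default. `Φ⁻¹(1−X)` is evaluated as the
  upper-tail quantile `isf(X)` to avoid catastrophic cancellation for
  the tiny Beta(0.1, ·) draws. The matrix Σ is positive definite for
  ρ ∈ {0.5, 0.7} at 24–30 sites but not for ρ ≳ 0.86; the Cholesky
  failure is surfaced as an error advising a smaller ρ rather than
  silently repaired.
- Coverage `round(Normal(30, 13))` clamped at a minimum of 5 — the 13
  is read as a standard deviation — and counts
  `m ~ Binomial(c, p)`. Everything is drawn from a single seeded
  generator, so a dataset is bit-reproducible given its seed.
- Sites are equally spaced with spacing 1 bp by default, so bp and
  site-index distances coincide on simulated data.

What the generator does **not** emulate: covariate effects (covariate
adjustment is exercised by unit tests on constructed datasets instead),
read-level errors, chromosome-scale site density variation, and
realistic CpG spacing. Passing calibration on this generator therefore
shows correct type-I error under Beta-binomial counts with
distance-decaying cross-site correlation — not robustness to every
property of real bisulfite data.

## Benchmarks and problem sizes

`benchmark_type1` refuses configurations with d ≠ 0, simulates
independent null datasets and reports the rejection fraction at each
nominal level with its binomial Monte-Carlo standard error;
`benchmark_power` does the same across case-α values with d > 0.
Per-replicate random streams are spawned from one `SeedSequence`, so
results are reproducible and chunkable. Both tests on one 48 × 24
dataset with a few hundred permutations take single-digit milliseconds
because the permutation engines are fully vectorised (group sums as one
matrix product per permutation batch; windows via cumulative sums).

The package's own calibration runs use 4,000 replicates with 500
permutations per dataset (`scripts/acceptance.py`) and 2,000 replicates
with 200 permutations in the test suite, against the reference study's
10,000; at these scales the Monte-Carlo standard error of a 5% rate is
about 0.3–0.5 percentage points, which is the resolution at which
agreement is asserted. Power checks use 500 replicates per cell and are
asserted directionally (monotone in d and n, scan ≥ kernel) with
3-standard-error slack, not against numeric power values.

## Numerical and design choices

- Permutation p-values use the add-one estimator with ties counted as
  exceedances: valid (never anti-conservative) and never zero.
- With B permutations the p-value lattice is `{k/(B+1)}`, so the
  achievable rejection rate at nominal α is `⌊α(B+1)⌋/(B+1)` — B = 200
  gives 0.0498 at α = 0.05 and 0.00995 at α = 0.01, which is why the
  calibration checks use B ≥ 200 (and B ≥ 500 at the 1% level in the
  acceptance script).
- The scan's likelihood ratio is evaluated with `log1p` on the
  complement and is exactly 0 for equal proportions up to rounding;
  degenerate proportions are impossible after pseudo-counts.
- Sites excluded (zero group coverage) are dropped before both tests;
  under permutation a group sum can still be zero at a site, in which
  case its δ contribution is set to 0 — the same convention the
  observed statistic would face.
- ICC clipping to [0, 1) and the deff floor of 1 mean the design effect
  never inflates counts; undefined ICC (fewer than two covered samples)
  yields deff = 1 with a warning.
- `DmrCall` intervals are 1-based inclusive internally; only BED output
  converts coordinates.

## Known limitations

- The kernel test is two-group only; the scan handles G ≥ 2 nominal
  groups but not ordered responses.
- KDM reports a single localised region per fitted result (contribution
  threshold rule); multi-region localisation from one contribution
  profile is not attempted.
- No FDR control across independent regions is provided; per-window
  inference within a region is FWE-controlled by the max-statistic
  null.
- No beta-binomial dispersion modelling or rate smoothing; the design
  effect is the only overdispersion correction.
- Genome-wide analysis should be run per chromosome or per candidate
  region; no automatic chunking heuristics are included.
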