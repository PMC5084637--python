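# Methods

`ivmr` implements two-sample Mendelian randomization (MR) on GWAS summary
statistics. This note documents the statistical model, the estimators and
their assumptions, the synthetic-data generator used for validation, and the
numerical and design choices the implementation makes.

## The model

Each genetic instrument *i* is an independent SNP with a per-allele effect
`βx_i` on the exposure (here: HDL cholesterol, standard-deviation units) and
`βy_i` on the outcome (log-transformed estimated glomerular filtration rate,
eGFR), with reported standard errors `σx_i`, `σy_i`. Under the instrumental
variable assumptions — the SNP affects the exposure, shares no confounder
with the outcome, and affects the outcome only through the exposure — each
SNP carries an estimate of the same causal effect `β` via its Wald ratio

    β̂_i = βy_i / βx_i,     se(β̂_i) ≈ σy_i / |βx_i|   (first order).

The first-order delta-method SE ignores the error in `βx_i`; this is the
standard choice when instruments are genome-wide significant (per-SNP
F = (βx/σx)² > 29 at p < 5×10⁻⁸), and a second-order SE including the
exposure-error term is available by flag (`wald_ratios(..., se_order="second")`;
it is never smaller).

## Estimators

**IVW.** The inverse-variance-weighted estimate pools the Wald ratios with
weights `w_i = (βx_i/σy_i)²`:

    β̂ = Σ w_i β̂_i / Σ w_i = Σ βx_i βy_i σy_i⁻² / Σ βx_i² σy_i⁻²,

identical to a zero-intercept weighted regression of `βy` on `βx` (the suite
verifies agreement to 1e-12 relative error). Heterogeneity of the ratios is
measured by Cochran's `Q = Σ w_i (β̂_i − β̂)²` on `n − 1` degrees of freedom.
Three variance models:

* `fixed`: se = (Σ w_i βx_i²... ) i.e. `sqrt(1/Σ βx_i² σy_i⁻²)`;
* `random_multiplicative` (default): the fixed SE inflated by
  `sqrt(max(1, Q/(n−1)))` — the point estimate is unchanged, matching the
  convention of reporting one `β` per SNP set;
* `random_additive`: DerSimonian–Laird meta-analysis of the Wald ratios
  (moment estimator of the between-SNP variance τ²), which can shift the
  point estimate; provided for sensitivity.

**MR-Egger.** The same weighted regression with a free intercept, after
orienting every SNP to its exposure-increasing allele (both betas flipped
when `βx_i < 0`; all estimators are invariant to effect-allele relabelling,
and the suite checks this). The intercept estimates the average *directional*
pleiotropic effect; the slope remains consistent for `β` under the InSIDE
assumption (direct effects independent of instrument strength). SEs come
from the weighted-least-squares covariance scaled by `max(1, residual mean
square)`, so they never drop below the fixed-effects level.

**Weighted median.** Ratios are sorted; with normalized weights `w'_i` the
cumulative midpoint grid is `s_i = Σ_{j≤i} w'_j − w'_i/2` and the estimate
linearly interpolates to `s = 0.5`. It is consistent while valid instruments
hold a majority of the weight. The point estimate is deterministic; its SE
uses a seeded parametric bootstrap (default 10,000 replicates; fewer than 100
is rejected as unstable). Note that consistency is asymptotic in the summary
SEs: with one-sided contamination the median sits at the
`0.5 / (valid-weight fraction)` quantile of the valid ratios, an offset
proportional to the per-ratio noise. The validation suite therefore checks
recovery in a high-precision regime and checks that the residual offset is an
order of magnitude below the IVW bias, rather than asserting exact
unbiasedness at the study's sample sizes.

**Sample-overlap correction.** With a fraction `c` of participants shared
between the exposure and outcome GWAS (≈43% in the motivating analysis), a
two-sample estimate inherits a weak-instrument bias pulled toward the
observational association rather than toward zero. `correct_for_overlap`
subtracts the first-order expected bias `c · β_obs / F̄`, where `β_obs` is the
observational exposure–outcome estimate and `F̄` the mean instrument F
statistic, leaving the SE unchanged. This interpolates between the pure
two-sample case (`c = 0`, no change) and the one-sample worst case, and
vanishes as instruments become strong. It is an approximation, not an exact
likelihood correction; it is exposed with explicit parameters so users can
probe sensitivity.

**Heterogeneity (goodness-of-fit) filter.** Per-SNP contributions
`q_i = w_i (β̂_i − β̂)²` to Q identify instruments whose outcome effects are
not mediated by the exposure. The default `iterative` mode removes the
largest-`q_i` SNP, refits, and repeats until no `q_i` exceeds the upper-5%
χ²(1) quantile or the overall heterogeneity p-value exceeds 0.05 — chosen
because a filter that reports both a flagged count and a just-homogeneous
residual p implies removal until homogeneity. `single_pass` flags all
over-threshold SNPs at once and is the mode whose false-positive rate is
calibrated (≈ `alpha_snp` under the null, verified by simulation). Ties in
`q_i` are broken by the larger absolute standardized residual, then the
lexicographically smaller rsid, making the filter deterministic. The filter
never reduces the set below 3 instruments; it stops with a warning instead.

**Multivariable MR.** Outcome betas are regressed jointly on the exposure
betas and the covariate-trait betas (here LDL cholesterol and triglycerides)
with no intercept and weights `σy⁻²`; the exposure coefficient is its direct
effect conditional on the covariates. Covariate measurement error is ignored
(the first-order summarized-data convention) and an unweighted variant is
available by flag. With zero covariates the point estimate reduces exactly
to fixed-effects IVW. Designs with condition number above 1e10 (after
per-column norm scaling) are rejected as collinear; an all-zero covariate
column is tolerated and its coefficient pinned to zero.

**Enrichment lookup.** Before any MR pooling, the outcome p-values of the
instrument panel are compared against uniformity: the number below α = 0.05
is tested with the exact one-sided binomial tail P(X ≥ k), X ~ Bin(n, α)
(strict inequality "p < α", matching the over-representation wording);
per-SNP significance uses the Bonferroni threshold α/n; and a direction-
consistency count reports SNPs whose exposure-increasing allele moves the
outcome against the expected direction.

## Harmonization

Exposure and outcome tables are merged on rsid; where the outcome file
reports the other allele (directly or after A↔T/C↔G strand complementation)
the outcome beta is negated. Palindromic (A/T, C/G) SNPs are *kept* by
default — the operation assumes both consortia used compatible reference
panels, as when a pre-merged supplementary table is re-analyzed — with
`drop` available by flag. Irreconcilable allele pairs are excluded with a
log message rather than raising. Harmonization is idempotent and only ever
changes the sign of `beta_outcome`. LD independence (pairwise r² < 0.1) is
accepted as a property of the input and recorded as a flag, not computed:
LD estimation needs genotype reference panels, which are out of scope.

## Synthetic-data generator

`simulate_instruments` draws, per SNP: a true exposure effect
`b_i ~ |N(0, s)|` (folded normal, default scale `s = 0.05` SD — with
exposure SE `1/√188,000` this puts roughly 80–90% of draws past genome-wide
significance, emulating a panel of lead SNPs whose effects range widely); a
direct outcome effect `a_i` for a configurable fraction of SNPs
(`a_i ~ N(μ_α, σ_α)`, default σ_α = 0.015 ≈ 5.5 outcome SEs — the strong-
heterogeneity regime; μ_α = 0 is balanced, μ_α ≠ 0 directional;
`inside_violated` makes `a_i` proportional to `b_i`); and observed betas
`b_i + ε_x`, `β·b_i + a_i + ε_y` with `(ε_x, ε_y)` bivariate normal, SDs
`1/√n_exposure` and `1/√n_outcome` (defaults 188,000 and 133,413 — the
exposure and outcome treated as unit-variance traits) and correlation
`overlap_correlation` (0 = disjoint samples; ≈0.43 mimics substantial
participant overlap). Genome-wide selection (p < 5×10⁻⁸) is applied to the
*observed* exposure statistics, so winner's curse is present by construction
and no correction is applied — matching how real panels are assembled.

Determinism: each SNP draws from its own `SeedSequence` substream, so the
same seed gives byte-identical tables and growing `n_snps` never reshuffles
earlier SNPs. If selection leaves fewer than 3 SNPs the panel is redrawn
(fresh substream) up to 10 times, then errors.

What the generator does **not** emulate: LD between instruments (the model
assumes an r²-pruned panel), allele-frequency-dependent SE heterogeneity
(all SNPs share one SE per trait), population stratification, and any
nonlinearity of the exposure–outcome relationship. Passing tests therefore
validate the estimators under the stated sampling model, not the
correctness of any particular real-data analysis.

`power_curve` wraps the generator: for each candidate causal effect it
simulates panels, applies the random-effects IVW test, and reports the
rejection fraction — at `β = 0` this is the empirical type-I error
(≈ 0.04–0.05 with the multiplicative model, slightly conservative because
the SE is never deflated below the fixed-effects level).

## Validation problem sizes

The shipped validation suite uses: 1000 random sets for the IVW algebra
check; 1000 replicates of 68-SNP panels for bias and CI coverage; 200–300
replicates for Egger-intercept recovery and weighted-median robustness
(the latter at 100× the default sample sizes, where the median's asymptotic
regime applies); 100 seeds for outlier-filter recovery and null calibration;
and 400–500 replicates for the type-I-error check. These sizes put Monte-
Carlo error comfortably below the effect sizes being checked while keeping
a full run to a few minutes on one core.

## Known limitations

* The overlap correction is first-order and parameter-driven; it does not
  model the full covariance structure of shared samples.
* The explained-variance estimate from `beta_se_n` (`r²_i = z²/(z² + n − 2)`)
  differs slightly from allele-frequency-based formulas; both are provided
  because published tables do not always include frequencies.
* Second-order Wald SEs, additive random effects, and the unweighted
  multivariable fit are provided as sensitivity flags, not defaults.
* No mode-based estimators, MR-PRESSO, nonlinear MR, LD-aware anything, or
  live annotation lookups; annotation-based pruning consumes a static label
  column.
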