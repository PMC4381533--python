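# Methods

This note records the statistical models behind `mascsig`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter for reproducing a
result.

## Differential expression (SAM-style)

For a two-group comparison the per-gene statistic is the moderated
relative difference

    d_g = (x̄2_g − x̄1_g) / (s_g + s0),

where `s_g` is the pooled standard-error term
`sqrt[(1/n1 + 1/n2)/(n1 + n2 − 2) · Σ(x − x̄)²]` and `s0` is a fudge
factor that stabilises `d` for low-variance genes. `s0` is selected on a
percentile grid (0, 5, …, 100) of the `s_g` distribution by minimising
the coefficient of variation of the median absolute deviation of `d`
across equal-occupancy windows of `s` — the classical tuning recipe for
this statistic. The multiclass statistic replaces the numerator with the
ANOVA-like between-group contrast
`sqrt[(Σ_k 1/n_k) · Σ_k n_k (x̄_k − x̄)²]` over the pooled within-class
`s_g + s0`; for k = 2 it reduces to |d| of the two-class form, which the
tests exploit as a cross-check.

Significance comes from a column-relabelling permutation null. When the
number of distinct relabellings is at most 10,000 the null is enumerated
exhaustively (a 3v3 design has exactly 20); otherwise `n_perm`
relabellings are sampled under the run seed. Two estimates are reported:

* **global q** — at each |d| threshold, the expected number of null
  exceedances over the observed count, suffix-minimised so q is monotone
  in |d|;
* **local FDR** — the ratio of null to observed counts inside a
  symmetric window of half-width 5% of the statistic's range centred on
  each gene's d, clamped to [0, 1].

Two robustness choices deserve emphasis. First, null counts use the
*median* across permutations, not the mean: in small unbalanced designs
(7 vs 3) a handful of relabellings nearly reproduce the true grouping
and would otherwise carry genuine signal into the null. Second, the
local-FDR window is symmetric in d, not in rank: a rank-centred window
straddles the boundary between the null bulk and a dense cluster of
truly changed genes and inflates the apparent null density exactly where
the decision is made. Both choices were validated against an independent
t-test oracle on planted designs.

The null proportion π0 is estimated as the fraction of observed d values
inside the permuted interquartile range, divided by 0.5, capped at 1.

## Signature derivation

The stem-cell signature is the intersection of up-calls from three
two-class comparisons (stem cells versus the myoepithelial population
and versus each luminal population) at local FDR < 0.05 and linear fold
change ≥ 1.5. Fold thresholds are applied on the linear scale while all
expression is held in log2. The top refinement keeps signature genes at
fold change ≥ 2.5 against the myoepithelial arm and against the *pooled*
luminal samples (one combined group, recomputed by a dedicated SAM run).
The fold gate is inclusive: the packaged 69-gene reference table
contains rows printed at exactly 2.50, and an inclusive gate retains
them, which is the behaviour the reference table documents.

Probeset filtering removes rows that map to no gene or to more than one
gene; when several surviving probesets represent one gene, the one with
the highest mean expression wins (an explicit convention — only the
removal rules are externally given).

## Activation scoring

Two per-tumour scores are provided:

* **average** — median-centre every gene across the cohort, then average
  the centred expression of the signature genes. Median centring makes
  the score invariant to per-gene additive shifts, so cross-platform
  location differences cancel.
* **relevance network** — a denoising variant: build the signature-gene
  correlation graph over the cohort, keep edges with Pearson r > 0.3
  (positive sign required, since every signature gene is an up-gene) and
  Bonferroni-corrected p < 0.05, retain the largest connected component,
  drop genes anti-correlated with the component's mean profile, and
  average the z-scored expression of what remains. With fewer than three
  surviving genes the method falls back to the average score with a
  warning. This is a documented stand-in for relevance-network pathway
  scoring in general; it does not claim to reproduce any specific
  published implementation's scores.

Dichotomisation: *top tertile* puts samples at or above the nearest-rank
66.67th percentile in "high" (ties join "high"); *median* puts strictly
greater-than-median samples in "high" (ties to "low"). Both conventions
are stated because neither is standardised in the literature.

## Survival analysis

Kaplan-Meier curves and Cox fits delegate to `lifelines` (Breslow ties,
Wald 95% CI; monotone likelihood — all events in one group — is flagged
and returns an unbounded CI). The two-group log-rank chi-square is
computed directly from the risk-set table in vectorised form because the
matched null evaluates it tens of thousands of times; the test suite
verifies exact agreement with `lifelines.statistics.logrank_test`. All
tests are two-sided.

The **matched random-signature null** asks whether the observed
stratification could be achieved by any gene list of the same size with
a similar expression profile. Genes are binned into deciles of
cohort-mean expression; each of `n_lists` (default 1000) random lists
draws, per signature gene, a non-signature gene from the same decile
(widening to neighbouring deciles only if a bin is exhausted, with a
log note). Every list runs the full score → dichotomise → log-rank
pipeline. The comparison statistic is the log-rank chi-square — monotone
in the p-value but immune to p underflow — and the empirical p uses the
add-one rule `(1 + #{null ≥ observed}) / (n_lists + 1)`, so it is never
zero.

## Subtypes, overlap, single cells

Nearest-centroid classification assigns each tumour the subtype whose
centroid it correlates with most strongly (Pearson default, Spearman
optional); correlations to every centroid are returned, ties break by
subtype name order, and assignments below a configurable `r_min` are
flagged low-confidence rather than suppressed. Enrichment of
high-scoring tumours per subtype uses the hypergeometric upper tail with
Benjamini-Hochberg correction across subtypes; subtypes with fewer than
three tumours are summarised but not tested. The boxplot-style summary
has no canonical test in the source material, so the hypergeometric
choice is stated here explicitly.

Gene-list overlap uses the hypergeometric upper tail
P(X ≥ overlap | universe, |A|, |B|); the universe is a *required*
argument because an unstated universe is the standard way such p-values
get overstated. The upper tail is the conventional one-sided form for
overlap questions and is documented as such.

Single-cell RT-qPCR: spike transcripts at known copies (defaults 8400,
900, 90 molecules) calibrate amplification linearity by regressing Ct on
log10 copies; −log2(10) ≈ −3.3219 cycles/decade corresponds to 100%
efficiency. Relative quantification uses 2^(−ΔΔCt) against a stated
reference and comparator. Heterogeneity analysis works on the 1/Ct
scale, with undetected wells mapped to 0 (non-amplification read as
absence; a Ct-ceiling detection rule is available as an option). The
per-gene coefficient of variation uses the population SD (n
denominator). Contingency percentages are reported to one decimal.

## Synthetic data: what it emulates, what it does not

`simulate_populations` reproduces the purified-population design — 7
stem-cell, 3 myoepithelial, 3 + 3 luminal replicate arrays — with four
planted gene classes: stem-cell-specific (up only in stem cells),
basal-shared (up in stem cells *and* myoepithelium — present precisely
to prove the intersection excludes them), luminal-specific, and null.
Noise is additive Gaussian on the log2 scale with per-gene SDs drawn
from a scaled inverse-chi-square (df = 6) around `noise_sd = 0.3`, the
replicate-level variability typical of RMA-summarised arrays; baselines
are N(7, 2). The default planted effect is 2 log2 units (4-fold).

`simulate_cohort` draws a latent activation A ~ N(0,1) per tumour;
signature genes load on it linearly (default loading 1, noise SD 0.5)
and event times follow an exponential baseline (0.02 events/month,
Weibull shape available) with hazard multiplied by exp(β·A);
censoring is independent exponential (0.005/month). Times are months.

`simulate_single_cells` draws per-gene Gaussian Cts clipped to [10, 40]
with per-gene dropout, and spike Cts from the linear dilution model.

None of the generators emulate probe-level effects, batch structure,
normalisation artefacts, platform-specific probe behaviour, or
clinico-pathological covariates. Passing tests therefore demonstrate
that the statistical machinery is correct and calibrated under the
stated model — not that any particular biological cohort will reproduce
a given hazard ratio.

## Problem sizes used in the checks

The packaged checks run at desk scale: planted designs of 900–1000 genes
across 16 arrays; null calibration over 20 (signature) and 200
(log-rank) seeds; hazard-recovery coverage over 100 cohorts of 1000
tumours against a 60,000-tumour probability-limit run; matched-null
power over 50 cohorts of 500 tumours at 1000 lists each. These sizes
give binomial standard errors small enough for the pass criteria while
keeping a full run in minutes.

## Known limitations

* The local-FDR estimator is a windowed density ratio; very small gene
  universes (< ~100 genes) make it coarse. The global q-value is
  reported alongside so users can gate on either.
* The relevance-network score's component rule can discard weakly
  coupled true genes in small cohorts; the fallback to the average score
  is logged, never silent.
* Cox fits assume proportional hazards between score groups; the
  dichotomised-score group HR is a derived, rule-dependent quantity, not
  the latent per-unit effect β.
* Identifier mapping is the caller's responsibility (a two-column table);
  no orthology database is bundled.
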