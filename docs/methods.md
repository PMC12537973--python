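# Methods

## The screening model

The screen treats the dependency matrix as given — Chronos-style gene
effects are consumed, never re-estimated from sgRNA counts — and asks, per
gene, whether the target entity's cell lines are systematically more
dependent than the pan-cancer background. Two summaries are computed from
the same per-gene data: the **median difference** (robust effect size on the
score scale, the volcano x-axis) and a **two-sample t-test p-value**
(ranking statistic, the volcano y-axis). The Welch (unequal-variance) form
is the default because the two groups are wildly unbalanced (tens of target
lines against hundreds to a thousand background lines) and there is no
reason to assume equal variances; the pooled Student form is available via
`equal_var=True`. Medians use the mean-of-central-order-statistics
convention for even group sizes.

Missing scores are dropped per gene and group, never imputed — imputation
would fabricate dependencies. Genes with fewer than `min_group_size`
(default 3) usable scores in either group are reported with missing
statistics and excluded downstream. A gene with zero variance and equal
means in both groups is uninformative and reported as t = 0, p = 1 rather
than an error; when variances are zero but means differ, p underflows and is
floored at the smallest positive normal float (~2.2e−308), the same floor
applied before every −log10 transform so volcano outputs stay finite.

Selection proceeds in fixed stages. The top-K step ranks by raw p only — no
multiple-testing cutoff is applied, because the workflow treats the K most
significant negative-difference genes as a candidate pool, not as
discoveries. Ties in p are broken by more-negative median difference, then
lexicographic gene symbol, making output identical across platforms. The
final filter applies both essentiality inequalities strictly: target median
< −0.5 *and* background median > −0.5; a gene sitting exactly on the
threshold in either group is excluded. −0.5 is the field's conventional
boundary for complete essentiality on the gene-effect scale.

## Over-representation analysis

ORA uses the exact hypergeometric upper tail, evaluated through scipy's
log-space survival function, with Benjamini–Hochberg correction across all
sets actually tested. The universe defaults to the genes the screen actually
tested (the sampling frame from which the top-K list was drawn); using the
GMT's own gene universe is available via `universe="gmt"`. Sets smaller
than 3 members or larger than half the universe after intersection are
excluded by default — tiny sets make unstable calls and near-universal sets
are uninformative; both bounds are configurable. The g:SCS-style correction
used by some web services is unspecified and proprietary-ish; BH is the
documented substitution, which makes pathway counts on real data
version-dependent and slightly more permissive.

One consequence worth knowing: the top-K list should be a small fraction of
the universe. When the query approaches half the universe the hypergeometric
null already expects large overlaps and planted enrichment becomes
undetectable; with the default K = 200 a universe of ~2000+ genes is the
intended regime (the real screens test ~18k genes).

## Differential expression and ΔΔCt

The DEG statistic is deliberately the simple construction used alongside
such screens, not a count GLM: per gene, counts are transformed as
log2(count + 1) (pseudocount configurable; nothing in the statistic's
definition fixes it), the effect size is the difference of group medians on
that scale (knockdown − control, so silenced targets come out negative), and
significance is a two-sided Welch t-test at raw p < 0.05. No library-size
normalization is applied by default (a CPM flag exists); a BH-adjusted
column is emitted alongside for users who want it. This statistic is noisier
and less calibrated than a negative-binomial GLM at typical n = 3 designs —
that is a property of the method being implemented, not a target for
improvement here.

2^(−ΔΔCt) is the standard relative-quantification identity:
ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_control,
fold change = 2^(−ΔΔCt). It assumes perfect doubling efficiency per cycle.

## Survival analysis

Cohorts are split at the median of the covariate (mean of central order
statistics); ties at the median go to the **low** stratum by default
(configurable via `tie_policy="high"`) — public portals do not document
their convention, and the choice only matters when expression values repeat.
The Kaplan–Meier estimator uses the events-before-censoring convention:
subjects censored at an event time count as at risk for that time. The
log-rank test is the two-group Mantel–Cox form: chi² = (O_A − E_A)²/V on
1 df with the hypergeometric variance term summed over distinct event times;
zero variance (no comparative information) degenerates to chi² = 0, p = 1
with a warning. The stratifier is agnostic to what the covariate is — raw
expression, z-scores, anything ordered — and time units pass through
unchanged.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical shape* the analyses assume, with
truth tables for closed-loop testing:

- **Dependency scores** are Normal(class mean, σ): 0 for non-essential, −1
  for common-essential, and −δ in target lines only for planted selective
  genes. Defaults — 26 target lines, 300 background lines (scaled down from
  1124 so end-to-end tests run in seconds; the full size is one parameter
  away), δ = 0.8, σ = 0.15 — put planted genes at the same separation scale
  as a strong real selective dependency. Real Chronos scores have heavier
  tails, copy-number artifacts and correlated screens; none of that is
  modeled, so passing recovery tests demonstrates the pipeline's logic, not
  robustness to those artifacts.
- **Gene sets**: one planted pathway holding a chosen fraction of the
  planted genes plus random fillers, among uniform random sets.
- **Counts** are negative binomial with var = μ + αμ² (default μ = 500,
  α = 0.1), with ±log2-effect shifts (alternating sign) in the knockdown
  group for planted genes. No gene-length, GC or library-size structure.
- **Survival** draws a standard-normal covariate z, exponential event times
  with rate h₀·exp(βz) (default h₀ = 0.02 per time unit, median ~35 units
  at β = 0), and independent exponential censoring whose rate is tuned to
  the requested censored fraction exactly at β = 0 and approximately
  otherwise. Real cohorts have non-exponential baselines and informative
  censoring.

Every generator is a pure function of its configuration including the seed;
per-gene streams are spawned from the master seed, so one gene's draws do
not change when others are added.

## Numerical and design choices

- Per-gene t statistics are computed vectorized from means and ddof-1
  variances with the Welch–Satterthwaite df; tests verify exact agreement
  with scipy's `ttest_ind` and with the closed form.
- The log-rank implementation is cross-checked in tests against lifelines
  (which is never used as the implementation), and KM against lifelines'
  product-limit fit, to 1e−9.
- Simulation sizes in the validation suite (2000 genes or replicates for
  null calibration; 100 seeds for power) give 3-binomial-SE bands of about
  ±1.5 percentage points around the nominal 5% level.
- The DEG null-calibration check runs at 8 replicates per group: the Welch
  test itself is conservative at n ≤ 5 even on exactly normal data
  (rejection ≈ 3.3% at n = 3), so calibration of the *implementation* is
  assessed in the regime where the test's nominal level holds. The planted
  detection check keeps the typical n = 3 design (~91% power at |log2
  effect| = 2 across seeds).

## Known limitations

- ORA p-values are exact but the BH step controls FDR only under
  independence/PRDS across sets; overlapping pathways violate this mildly.
- The DEG statistic has no dispersion moderation; at n = 3 its power and
  calibration are inferior to DESeq2/edgeR-style GLMs by design.
- The chi-square approximation of the log-rank test is slightly liberal in
  small cohorts with heavy ties (observed ~5.9% at n = 60, within the
  validation band).
- The screen assumes scores are comparable across cell lines (already
  normalized per line by the upstream score model); no batch or lineage
  covariates are modeled.
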