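# Methods

This note documents the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Sex-difference tests

For any pair of per-sex estimates with standard errors — heritability,
per-variant GWAS beta, or eQTL beta — the difference is tested with a Wald
z-statistic, female minus male:

    z = (STAT_f − STAT_m) / sqrt(SE_f² + SE_m²)

two-sided against the standard normal.  The test assumes the two estimates
are independent (they come from disjoint samples) and approximately Gaussian
at the available sample sizes.  The male–female genetic correlation is tested
against 1 with `t = (r_g − 1) / SE`; since no degrees of freedom accompany a
summary-level correlation estimate, the standard normal is the default
reference, with an explicit `df` argument for a t reference when the user has
one.  Note that near r_g = 1 the Gaussian approximation to a correlation
estimate is crude; the test is a screen, not a confidence statement.

All FDR control is Benjamini–Hochberg step-up (delegated to statsmodels,
cross-checked in the tests against a literal hand implementation).
P-values are clamped to (1e-300, 1] so downstream log-space code never sees
zero.

**SDE rule.** A variant is a sex-differentiated effect when (a) its z-test
q-value is below 0.05, the FDR being taken within trait across all supplied
(region-mapped) variants, and (b) min(p_male, p_female) < 5×10⁻⁸.  A
cross-trait global FDR scope is available as an option; within-trait is the
default because the z statistics are computed trait by trait.

## Regions, tagging, counting

Gene regions are closed 1-based intervals `[max(1, tss − flank), tss + flank]`
with flank defaulting to 1 Mb; the TSS is strand-aware (feature start on `+`,
feature end on `−`).  BED (0-based half-open) is converted at the reader
boundary; membership is inclusive on both bounds and tested explicitly at
them.  Regions are clamped at position 1 only — chromosome lengths are not
consumed by the mapper, so no upper clamp is applied.

The trait filters keep binary traits with ≥ 300 cases in each sex and a sex
difference in prevalence.  The prevalence rule is implemented as
`|prev_m − prev_f| / max(prev) > 0.02` behind a pluggable predicate, because
the natural literal reading of the published wording ("ratio of prevalence
> 0.02") is satisfied by essentially every trait and cannot be what was
meant; the predicate isolates this interpretation in one function.
Heritable-trait selection keeps traits strictly above the median
sex-combined h², so ties drop deterministically.

Tagging loci and independent-SNP counts both use greedy clumping on a
dosage-based r² matrix: repeatedly take the unassigned variant with the
smallest p-value (ties: position, then key), sweep in every unassigned
variant with r² ≥ threshold, and repeat.  Thresholds are r² = 0.2 for
tagging loci and r² = 0.8 for counting independent SNPs per gene region.
The greedy-partition reading was chosen because the index-SNP-by-significance
convention is the standard one and is deterministic; the output is always a
partition, and the locus count is monotone in the threshold (both are
property-tested).

## Colocalization

Per-SNP evidence is the Wakefield asymptotic Bayes factor
`log ABF = ½(log(1−r) + r z²)`, `r = W/(V+W)`, `V = se²`, `z = beta/se`.
Prior effect SD `sqrt(W)`: 0.2 on the log-odds scale for case-control
traits; `0.15 · sdY` for quantitative traits with
`sdY² ≈ median_j(se_j² · 2 maf_j (1−maf_j) · n_j)` because trait units are
generally absent from summary files; an explicit `sdY` override exists.
Priors default to p1 = p2 = 1e-4, p12 = 1e-5 (the documented defaults of the
established single-causal-variant colocalization method) and are exposed on
the CLI.  Case-control scans fitted as linear-probability models can be
converted to the log-odds scale beforehand with
`rescale_linear_prob_betas` (divide beta and SE by k(1−k), k the case
fraction); the conversion is explicit and off by default because it should
only be applied when the source model is known to be linear.

Hypothesis weights are assembled in log space; the H3 sum over ordered pairs
of distinct causal variants uses the identity
`Σ_{j≠k} ABF_a[j]·ABF_b[k] = (Σ_j ABF_a[j])(Σ_k ABF_b[k]) − Σ_j ABF_a[j]·ABF_b[j]`
via `logsumexp` and `log1p(−exp(·))`.  When the log-difference argument is
nonpositive (always for m = 1, occasionally from rounding on degenerate
loci), PPH3 is clamped to exactly 0 and a diagnostic flag is set.  The
implementation is checked against an oracle that enumerates every causal
configuration explicitly for loci up to 12 variants; agreement is required
to 1e-10.

Sex-stratified wrappers restrict both sexes to ±200 kb around a tagging
variant before colocalizing (trait 1 = male, trait 2 = female, so PPH1/PPH2
read male-only/female-only association), and the single-sex rule is
PPH4 > 0.5 in one sex and ≤ 0.5 in the other.  GWAS-vs-eQTL colocalization
reuses the same engine over the eQTL gene's ±1 Mb window; no separate
operation is needed.

## eQTL classification

Per sex, gene-level significance uses a two-step correction: within a gene,
Bonferroni over the number of LD-independent SNPs (greedy count at r² = 0.8)
applied to the minimum SNP p-value; across genes, BH-FDR at 0.1.  The
per-gene lead variant for the heterogeneity test is the variant with the
smallest of the two sex p-values; its z-test is BH-corrected across genes.
A gene that satisfies both the heterogeneity rule and the
one-sex-significance rule is labeled `sex_differentiated` — effect
heterogeneity is the stronger claim — but both raw flags are retained so the
two lists can be reported separately.

## MR-Egger

Instruments are exposure variants with p < 5×10⁻⁸, greedily clumped at
r² = 0.001 (the conventional two-sample default; exposed as a flag), then
allele-harmonized against the outcome.  Each instrument is oriented so its
exposure effect is nonnegative; the fit is WLS of outcome betas on exposure
betas with weights 1/se_y², a free intercept, coefficient SEs multiplied by
the residual overdispersion floored at 1, and t(n−2) p-values — the
conventional implementation of the estimator.  Sex-specificity is evaluated
on the slope p-value (the causal effect), not the intercept, at the
Bonferroni grid threshold 0.05/(186·29); a relationship is sex-specific when
significant in exactly one sex and in neither the other sex nor the combined
model.  The DMET-restricted pass refilters instruments by region membership
and refuses to re-fit fewer than 3 surviving instruments
(status `underpowered`); the multiplicity base for its Bonferroni re-test is
the number of relationships being re-tested, which the caller supplies.

## Enrichment permutation test

Observed statistic: the number of significant variants (p < 5×10⁻⁸) inside
the union of the target regions, each variant counted once.  Null: redraw
each target as a uniformly placed region of identical length on the same
chromosome (clamped to fit; overlaps permitted), recount, repeat B times
(default 1000).  Empirical p is add-one corrected, so it is never 0 and is
exact under exchangeability.  Same-chromosome matched-length resampling was
chosen because chromosome identity and region length drive local SNP
density; MAF- or LD-matched SNP-set resampling is deliberately out of scope.
An optional mode counts LD-tagged loci instead of variants to blunt
clumping inflation.

## Synthetic-data generator

The generator defines the study conditions for every test:

- **Genotypes**: two latent-Gaussian haplotypes per individual, AR(1)
  correlation `ld_rho` (default 0.6) within blocks of `block_size` (default
  10) variants, independent across blocks, thresholded at per-variant MAF
  quantiles (MAF ~ U(0.05, 0.5) unless pinned).  This reproduces
  Hardy–Weinberg dosages and monotone LD decay with one parameter; it does
  **not** reproduce realistic human LD maps, demography, or genome-wide
  scale (loci of at most a few thousand variants are intended).
- **Phenotypes**: `y = Σ β_sex,j g_j + ε`, ε ~ N(0, noise_sd²) with
  noise_sd = 1; binary traits threshold the same liability at the requested
  prevalence and report per-variant logistic (log-odds) summary betas, so
  the contrast between liability-scale truth and log-odds-scale estimates
  can be explored.  Surrogate-variable adjustment is replaced by explicit
  covariate matrices; the covariate path is exercised but makes no claim of
  matching any cohort's PC/age adjustments.
- **Sample sizes** in tests follow the scenario being emulated: 20,000/sex
  for biobank-style SDE recovery (planted β_m = 0.4, β_f = 0, MAF 0.3 —
  analytic power ≈ 1), 5,000/stratum with 1% variance explained for
  colocalization loci, ~100/sex with `equalize_n` for eQTL-style runs
  (down-sampling the larger sex mirrors sample-size parity in sex-stratified
  eQTL scans), and 2,000/sex for global-null FDR runs, where the calibration
  being measured is sample-size-free at summary level.
- **MR scenarios** are generated at the summary level: instrument effects
  `γ_j = |N(0, gamma_sd²)|` (pre-oriented to the exposure-increasing allele,
  the convention under which directional pleiotropy is defined), outcome
  effects `θγ_j + α_j + noise`, with α zero, zero-mean, or mean-shifted
  (default shift 0.05) by pleiotropy mode.
- **Determinism**: everything is a pure function of (config, master seed);
  per-component streams are derived from the master seed at fixed offsets
  (`sexstrat._util.STREAM_*`), so two sexes share keys and MAFs but not
  genotypes or residuals, and all outputs are bit-reproducible.

Because the generator's LD, effect architecture and covariates are stylized,
passing tests demonstrate the correctness and calibration of the statistical
machinery — not the field performance of the pipeline on real cohort data
with cryptic relatedness, population structure, or assortative mating.

## Numerical choices

- P-values clamp at 1e-300 rather than underflowing to 0.
- Perfect-fit regressions (zero residual) report SE and p at the clamp
  rather than 0, preserving record invariants.
- Serialization uses 17 significant digits and round-trip float parsing, so
  write→read is lossless including subnormals (e.g. 1e-320).
- Palindromic variants (A/T, C/G) are dropped during harmonization when both
  MAFs fall in (0.42, 0.5], mirroring standard two-sample harmonization
  defaults; the band is a parameter.
- Greedy ties break by p-value, then genomic position, then lexicographic
  key — fully deterministic.
- Degenerate inputs (zero-variance variants, empty genes, empty
  intersections) are excluded and counted, never fatal, except where the
  result would be meaningless (fewer than 3 MR instruments, missing tag
  variant in a coloc window).

## Known limitations

- Heritability and genetic-correlation *estimation* is out of scope; the
  pipeline consumes externally produced estimates with SEs.
- The colocalization engine assumes a single causal variant per trait per
  locus; multi-causal extensions are deliberately not implemented.
- MR is MR-Egger only (no weighted-median/mode estimators, no Steiger
  filtering), matching the decision rules built on it.
- Binary-trait simulation fits one logistic regression per variant, which is
  slow beyond a few hundred variants; quantitative scans are vectorized.
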