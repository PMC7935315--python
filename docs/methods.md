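# Methods

## Statistical conventions

**Mann–Whitney.** The screen's core test is the two-tailed unpaired
Wilcoxon–Mann–Whitney test.  The exact null distribution of U is computed
by the Gaussian-binomial recurrence and used whenever `min(n, m) ≤ 25` and
the pooled sample has no ties; otherwise a normal approximation with tie
correction and a 0.5 continuity correction is used.  The two-sided p is
`min(1, 2·min(tail p))`.  Which path produced each record is stored in the
output (`method` column).  Constant, identical groups (e.g. a gene with
zero expression in every sample of a tissue) are reported with p = 1 and
direction "none" rather than dropped, so consistency-score denominators
stay comparable across factors.

**Multiple testing.** Benjamini–Hochberg is applied by callers within
explicitly declared families: per (tissue, assay) across splicing factors
in the screen, and per tissue across coverage-surviving exons in the
inclusion analysis.  BH guarantees q ≥ p and monotonicity in p-rank; it is
*not* idempotent in general (re-adjusting an adjusted vector can inflate
interior values), so the tests assert the former properties plus equality
with an independent naive step-up, not idempotence.

**Exact tests.** Fisher's exact test and the binomial test at p₀ = 0.5 use
integer arithmetic (no floating-point tail accumulation), which makes
printed-precision cases such as 9/10 agreements → p = 22/1024 exact.  The
hypergeometric overrepresentation test is defined as Fisher's test on the
induced 2×2 table, so the two agree identically on the one-sided path; a
Holm (Bonferroni step-down) helper covers scans over several gene sets.

**Spearman.** Pairwise-complete average-rank correlation.  Fewer than 3
complete pairs or a constant margin returns `None` (an undefined
correlation is never reported as 0).  Per-exon mitotic-index correlations
attach a p-value from the t approximation `t = ρ·√((n−2)/(1−ρ²))`.

**Randomization test.** The observed statistic is the median over target
exons of the Spearman correlation between a per-sample profile and each
exon's PSI.  B background genes are drawn uniformly without replacement
from the supplied pool (the focal gene removed; no expression matching).
The add-one rule `p = (1 + #{background ≥ observed}) / (B + 1)` keeps p in
`[1/(B+1), 1]` and the whole test invariant under strictly monotone
transforms of any profile.  Because missing PSI cells give each exon its
own complete-sample subset, background profiles are argsorted once and
subset ranks derived by gather (with a `rankdata` fallback for tied rows);
this is exact, not an approximation.  The sample subset is an explicit
argument, so callers can test per tissue or pooled across tumors; the
recovery experiments pool all tumor samples.

## Thresholds and boundaries

| quantity | default | note |
|---|---|---|
| microexon band | 3–27 nt inclusive | `classify_microexon(27)=True`, `(28)=False` |
| exon coverage | ≥ 20 non-missing PSI per group | configurable `min_n` |
| differential exon | q < 0.01 and \|ΔPSI\| ≥ 5 | inclusive ≥; a strict > mode exists |
| ΔPSI definition | difference of group medians | `center="mean"` available |
| direction counting (screen) | q < 0.05 within (tissue, assay) | a knob, recorded in output headers |
| perturbation targets | ΔPSI ≥ 25 in both replicates | inclusive |
| expression response | fold ≥ 2, pseudocount 1 | `(case+1)/(control+1)` avoids division by zero |
| vast-style quality filter | grades below LOW masked | order N < VLOW < LOW < OK < SOK, both configurable |

Fold changes of medians use sentinels rather than infinities: both-zero
medians are "undefined-both-zero", a zero denominator is
"undefined-zero-denominator", and a zero tumor median over a positive
normal one is ratio 0.  Only strictly positive ratios enter the mean fold
magnitude `mean(max(r, 1/r))`.

## Mitotic-index score

The proliferation proxy is the mean over signature genes of z-scored
log2(x+1) expression, z computed within the cohort; genes with zero
variance are dropped and samples quantified for < 50 % of the signature
get an undefined score.  The formula is this package's construction — the
signature gene list is an input, and any per-sample score series can be
substituted in every downstream call.

## Synthetic cohort generator

The generator emits expression, methylation and PSI matrices plus sample,
target and annotation tables, fully determined by a seed.  Structure:

- per-sample latent proliferation `π ~ N(condition shift, 1)` with tumor
  shift 1.0;
- the planted factor's expression is `baseline(tissue)·exp(a·π + ε)/(s·[tumor])`
  with silencing divisor `s = 3.67` by default (matching the scale of
  cross-tissue silencing the screen is designed to detect),
  `a = mi_anticorrelation = −0.5`, ε of sd 0.3; other factors and
  background genes have tissue-specific lognormal baselines and no tumor
  effect;
- the planted factor's promoter beta is `logistic(logit(base) + 0.8·[tumor] + ε)`;
- target-exon PSI is `clip(baseline + 12·log1p(factor expression) + N(0, 8), 0, 100)`,
  with two-thirds of targets at baseline 0 (they carry only the coupling
  term); non-target exons are condition-independent;
- signature genes increase in π; each PSI cell is masked missing with
  probability 0.10;
- 66 % of target exons get microexon lengths (3–27 nt), non-targets 10 %.

Default cohort shape: 9 tissues × (40 tumor + 25 normal), 202 factors,
500 exons of which 314 are targets, 1000 background genes, 50 signature
genes.  These sizes keep a full pipeline run around three seconds while
preserving the ≥ 20-per-group regime the coverage filter assumes; the
randomization pool comfortably exceeds the default B = 500.  Note the
realized tumor/normal fold magnitude of the planted factor exceeds the
silencing divisor because the proliferation coupling suppresses tumor
expression further — the two effects compound by construction.

`GeneratorConfig.null()` switches every effect off (divisor 1, shifts 0,
slope 0) while keeping the cohort shape, giving exchangeable groups for
calibration.

**What the generator does not emulate:** empirical expression
distributions, batch structure, tumor purity confounding, correlated
missingness (dropout follows coverage in real data, uniform here),
inter-gene correlation beyond the planted program, and per-tissue target
heterogeneity.  Passing recovery tests therefore demonstrate that the
pipeline detects the planted structure it was built to detect — they are
statements about correctness and calibration, not about effect sizes in
real cohorts.

## Calibration and recovery experiments

- **Null exon calls:** 100 null cohorts (2 tissues, 30+30 samples, 200
  exons); pooled fraction of significant calls compared with the nominal
  0.01 plus three binomial standard errors.  Under a global null BH is
  conservative, so the observed rate is near zero.
- **Null randomization:** 200 null cohorts (1 tissue, 40 tumors, 25
  targets, pool 250, B = 199); the p-values are compared with Uniform(0,1)
  by Kolmogorov–Smirnov distance (< 0.1) and empirical size at α = 0.05
  (within [0.02, 0.09]).  B = 199 keeps the discrete p-grid fine enough
  for the KS comparison at this sample size.
- **Planted recovery:** 50 default cohorts; the planted factor should be
  the unique minimum expression consistency score and maximum methylation
  score in ≥ 95 % of runs, the randomization p < 0.05 in ≥ 80 % at
  B = 500, the pooled fraction of significant target calls decreasing
  > 0.7, and the MI–factor correlation negative in ≥ 95 %.

`scripts/acceptance.py` reruns all three experiments from a single seed
and writes the measured quantities as JSON.

## Known limitations

- The exact Mann–Whitney path is disabled by ties; heavily clipped PSI
  distributions therefore always use the tie-corrected approximation.
- The randomization background is not expression-matched; pools with a
  structure very different from the focal gene shift the null.
- The MI score treats signature genes as exchangeable; no weighting.
- Exon genome coordinates are opaque strings end to end; no coordinate
  arithmetic (strand, 0/1-based) is ever performed.
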