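# Methods

This note documents the statistical procedures implemented in `panmet`, the
synthetic-data model used to validate them, the numerical conventions, and
the places where a design choice was genuinely open.

## Data model

An `OmicsCohort` holds three gene×sample matrices — log2-transformed
expression (finite reals), binary non-synonymous mutation indicators, and
integer copy-number calls in {−2, −1, 0, 1, 2} (GISTIC2 convention:
−2 deep loss … +2 high-level gain) — column-aligned to a clinical table
(`sample_id, cancer_type, sample_type, os_days, os_event`). Sample types are
normalized to the fixed vocabulary {normal, primary, metastatic, blood} via
an editable mapping (`data/sample_types.yaml`). Matrices are required to be
genes×rows; input whose row labels look like sample identifiers is rejected
as transposed rather than silently flipped. Gene symbols are uppercased on
load so matching against configured gene lists is case-insensitive. Missing
expression values are an error by default; a flag drops affected genes
instead, because every downstream statistic assumes complete vectors.

Two configuration objects drive the analyses. The **gene model**
(`data/gene_model.yaml`) maps four metabolic categories — `warburg`,
`lipogenesis`, `fa_oxidation`, `fa_uptake` — to gene lists; categories must
be disjoint unless overlap is explicitly allowed. The **EMT gene sets**
(`data/emt_sets.yaml`) give 8 mesenchymal and 5 epithelial marker genes;
duplicates are dropped with a warning naming the gene (the shipped
mesenchymal list is deduplicated to 8 entries), and the two sets must be
disjoint.

## EMT score and stratification

For sample *j*,
`EMT_j = Σ_{g∈mes∩matrix} x_gj − Σ_{g∈epi∩matrix} x_gj` on log2 expression.
Markers absent from the matrix are dropped and recorded; the score is fatal
only when one side would be empty. Samples are classed `high` when the score
is ≥ the arithmetic mean of the set being stratified (ties go to `high` by
the ≥ rule), `low` otherwise. The stratification mean is computed over
exactly the sample set being analyzed — the tumor (primary + metastatic)
subset for pan-cohort analyses, the per-cancer tumor subset inside
per-cancer screens — and the threshold is recorded in every output. Normal
and blood samples are excluded from the pan-cohort stratification by default
since the survival analyses concern tumors.

Group comparison of scores across sample types uses one-way ANOVA
(`scipy.stats.f_oneway`) followed by Tukey's HSD
(`statsmodels pairwise_tukeyhsd`, which applies the Tukey–Kramer adjustment
for unequal group sizes). Groups with fewer than two observations are
excluded with a warning.

## Alteration enrichment, metastatic vs primary

Copy-number calls are discretized as gain ⇔ call ≥ 1 and loss ⇔ call ≤ −1.
For one gene and one alteration kind, with `O_met`, `O_pri` the observed
altered counts and `n_met`, `n_pri` the group sizes, the pooled frequency is
`f = (O_met + O_pri) / (n_met + n_pri)` (pooled over primary + metastatic
tumors only) and the expected counts are `E_grp = f · n_grp`. The default
test applies Fisher's exact test (two-sided, standard enumeration of tables
with probability ≤ the observed table's) to

```
[[O_met, O_pri],
 [E_met, E_pri]]
```

with expected counts rounded half-to-even to integers, since the exact test
requires integer counts; the rounding policy is echoed in the output. This
observed-vs-expected construction mixes a random row with a near-
deterministic one, which makes the test markedly conservative (see
*Limitations*); the conventional altered/unaltered × group table is
available as `table_mode="standard"` and, on planted-effect cohorts, agrees
with the default construction on ≥90% of significance calls.

Bonferroni correction is applied within each screen, with *m* equal to the
number of genes actually testable; genes altered in no sample are reported
as untestable (p = 1, direction `none`) and excluded from *m* so they
neither gain nor grant significance. Direction
(`metastatic_enriched`/`primary_enriched`) is assigned only to significant
genes, by the sign of the frequency difference.

Two mutation summaries complete the module: the basal mutation frequency
(total mutation count / (genes × samples)) and per-category mutation-burden
strata — a sample is `none`, `single` or `multiple` according to its summed
mutation count over the category's genes.

## Survival analysis

Kaplan-Meier estimation and the Mantel-Cox log-rank test are delegated to
`lifelines` (`KaplanMeierFitter`, `multivariate_logrank_test`, i.e. the
standard hypergeometric-variance statistic with k−1 degrees of freedom).
Deaths are processed before censorings at tied times, the standard
convention. Samples with missing survival data are dropped from survival
analyses only, with a warning giving the count. The test suite cross-checks
the log-rank statistic against an independent direct O−E/V implementation
(agreement to 1e-8) and the KM curve against hand-computed product-limit
values.

Stratifiers: single-gene mutation status; k-means (k = 2, Euclidean, best of
25 restarts at a fixed seed) over a CNA or expression submatrix, with the
cluster whose centroid has the larger mean deterministically labeled
`cluster_high` so "high cluster" is reproducible across runs; single-gene
expression splits by mean (default, consistent with the EMT convention),
median or k-means; and the combined mutation × expression scheme with three
groups — wild-type & low, exactly-one-altered, mutant & high.

## Cross-cancer signature

Per cancer type, candidate genes are screened two ways against the EMT
phenotype:

- **Pearson association** with the EMT score; p from the exact t transform
  `t = r·√((n−2)/(1−r²))` on n−2 df, two-tailed, Bonferroni-corrected across
  the genes tested within the cancer type (constant genes are flagged and
  excluded from the family).
- **Univariate logistic regression** of the EMT class (high = 1) on the
  gene's log2 expression (no standardization, so the odds ratio is per log2
  unit), Newton/IRLS maximum likelihood with tolerance 1e-8 and ≤100
  iterations. The two-sided Wald p is used for ranking; a
  likelihood-ratio p is also reported. Complete or quasi-complete separation
  (non-convergence or |β| diverging) is flagged and the p-value replaced by
  the smallest positive double so the gene ranks as maximally significant
  rather than crashing the screen.

Within each cancer type, genes are ranked by −log10(Wald p) so that rank 1 is
the largest p (least significant); ties receive average ranks; a gene absent
from one type's matrix receives that type's midpoint rank (n+1)/2 so it is
neither rewarded nor penalized. Rank-sums across types select the top genes
(largest rank-sum = most consistently significant under the default
`rank_order="significant_high"`) and bottom genes; both sets have size
min(5, n_genes // 2) and the ordering convention, tie policy and any
midpoint imputations are echoed in every output. The top/bottom signatures
are then used to k-means-cluster the cohort's expression and compare cluster
survival by log-rank.

## Synthetic-data model

The simulator generates the structure the analyses assume, with one seeded
generator split into named substreams (assignment, latent axis, expression,
CNA, mutation, survival) so that, e.g., adding genes never perturbs the
survival draws. Defaults below are the study conditions used throughout the
test suite.

- **Cohort layout**: `n_cancer_types` = 5 blocks (7 in the showcase
  configuration, matching the seven epithelial cancer types of the
  per-cancer screens) of `samples_per_type` = 200, `metastatic_fraction` =
  0.15, optional normal/blood fractions (0 by default). Group counts are
  deterministic (rounded fractions), not Bernoulli, so group sizes are exact.
- **Expression**: latent EMT axis `z ~ N(0,1)` plus `emt_shift` = 1.5 for
  metastatic samples. Mesenchymal genes are `baseline + a·z + σε`,
  epithelial genes `baseline − a·z + σε` (a = 1, σ = 1, baseline = 8 — a
  typical log2 RSEM magnitude). A gene planted at correlation ρ is
  `baseline + ρ·z + √(1−ρ²)·ε` with unit-variance noise so its population
  correlation with the axis is exactly ρ. An optional binary
  "signature cluster" (fraction 0.4) adds `signature_shift` = 2.0 to its
  members' signature-gene expression.
- **CNA**: planted gain genes draw calls in {0, 1} per sample with
  group-specific probability (π_primary, π_metastatic); all other genes are
  0. A flag spreads gains over {1, 2} and losses over {−1, −2} for the full
  call range. The default gain/neutral-only behaviour reflects the analyses'
  focus on gains.
- **Mutations**: Bernoulli per gene per sample, per-gene rates over a 2%
  background.
- **Survival**: exponential proportional hazards,
  `h_i = h₀·exp(Σ β_c x_ic)` with `h₀` = 1e-3/day and covariates drawn from
  the planted alterations (`mutation:GENE`, `gain:GENE`, `loss:GENE`,
  `signature_cluster`, `metastatic`); censoring is an independent
  exponential (2.5e-4/day by default, ~20% censoring at these hazards),
  observed time = min, event = death-first. This is the simplest model
  consistent with KM/log-rank assumptions. A simulator self-check recovers a
  planted log hazard ratio of 0.7 at n = 1000 within ±0.15 by a Cox
  partial-likelihood fit.
- `planted_truth` emits a machine-readable ledger of exactly the planted
  gene lists and effect sizes for automated recovery scoring.

The simulator deliberately does **not** model real marginal expression
distributions, batch effects, inter-gene co-expression beyond the single
latent axis, per-cancer-type baseline differences, or non-proportional
hazards. Passing recovery tests therefore demonstrates the correctness of
the statistical machinery under its own assumptions, not robustness to the
messiness of real tumor data.

## Validation strategy and problem sizes

- **Oracle equivalence**: Fisher's exact p vs exhaustive hypergeometric
  enumeration on 100 random 2×2 tables (1e-12); log-rank chi-square vs a
  direct O−E/V implementation on 100 random datasets of n ≤ 50 (1e-8);
  logistic β vs an independent plain-IRLS fit on 20 datasets (1e-6); KM vs
  hand-computed product-limit values.
- **Null calibration**: 500 replicate cohorts of 2 types × 60 samples with
  no planted effects. Raw p-values from the Pearson screen and the log-rank
  test are Kolmogorov–Smirnov-uniform; the family-wise error of the
  Bonferroni enrichment screen over 10 null genes stays ≤ 0.05 + 2
  Monte-Carlo SE across 200 replicates. The raw Fisher p-values themselves
  are *not* KS-uniform and cannot be: exact conditional tests have discrete,
  conservative null distributions (the observed-vs-expected construction is
  extremely conservative, median null p ≈ 0.8–1.0). The corresponding
  uniformity test is retained unmodified and documents this behaviour; the
  meaningful calibration guarantee for a conservative discrete test is FWER
  control, which holds.
- **Parameter recovery** (20 seeds each): 6 planted gain genes (0.10 vs
  0.45, 500 per group) among 34 testable nulls are detected at Bonferroni
  0.05 and recovered as the exact significant set; 5 genes planted at
  |ρ| = 0.7 among 30 candidates across 7 cancer types are recovered as the
  exact top-5 rank-sum signature; a planted log-HR of 0.7 on the signature
  cluster (n = 1000, ~20% censoring) yields signature-cluster log-rank
  p < 0.01.
- **Determinism**: two full `run-all` executions with the same configuration
  and seed produce byte-identical TSV/JSON trees (sorted-key JSON, no
  timestamps, shortest-round-trip float formatting).

Replicate counts and cohort sizes above were chosen so the full suite runs
in a couple of minutes on one CPU while keeping Monte-Carlo margins small
relative to the asserted thresholds.

## Known limitations

- The observed-vs-expected Fisher construction is implemented as the default
  for fidelity, but it is statistically unconventional: its null
  distribution is far more conservative than nominal, so its raw p-values
  understate evidence relative to the standard 2×2 test. Use
  `table_mode="standard"` when calibrated p-values matter.
- Logistic odds ratios are per log2-expression unit and therefore
  scale-dependent across genes; pass standardized expression if scale-free
  odds ratios are needed (ranking by p is unaffected).
- The expression split behind single-gene survival stratification defaults
  to the mean (matching the EMT convention); mean, median and k-means splits
  can disagree on skewed data, and no one rule is privileged.
- No Cox regression or hazard-ratio estimation is exposed; the survival
  module is limited to KM estimation, log-rank testing and stratification.
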