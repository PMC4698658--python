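# panmet

Pan-cancer analysis of metabolic-gene alterations in metastatic progression.

Metastatic tumors rewire cellular metabolism — aerobic glycolysis (the
Warburg effect), de novo lipogenesis, fatty-acid oxidation and fatty-acid
uptake — and some of those alterations are acquired specifically during
metastatic progression rather than tumorigenesis. `panmet` is a tested,
reusable implementation of the analysis chain that links such alterations to
metastasis and prognosis in multi-cancer cohorts of expression, mutation,
copy-number and clinical data. It is aimed at computational cancer-biology
groups who want the statistics of that analysis as library functions with a
validated synthetic-cohort simulator, rather than as a one-off script tied
to a particular download.

## What it computes

Given aligned gene×sample matrices (log2 expression, binary non-synonymous
mutation indicators, GISTIC2-style integer copy-number calls in −2..2) and a
clinical table (cancer type, sample type, overall survival):

1. **EMT score** per sample,
   `EMT = Σ_{g∈mesenchymal} x_g − Σ_{g∈epithelial} x_g` on log2 expression,
   with a mean split into low/high EMT classes (`high` ⇔ score ≥ mean),
   one-way ANOVA + Tukey HSD across sample types, and survival by EMT class.
2. **Alteration enrichment** in metastatic vs primary tumors. For each gene
   the observed altered counts per group are compared with the counts
   expected from the pooled frequency, `E_grp = f_pooled · n_grp`, via
   Fisher's exact test on the 2×2 table `[[O_met, O_pri], [E_met, E_pri]]`
   (expected counts rounded to integers; a conventional
   altered/unaltered × group table is available as `table_mode="standard"`),
   Bonferroni-corrected within each screen. Copy-number calls are
   discretized as gain ⇔ call ≥ 1, loss ⇔ call ≤ −1.
3. **Cross-cancer gene signature.** Per cancer type, each candidate gene is
   correlated with the EMT score (Pearson, exact t-based p, Bonferroni
   within type) and used in a univariate logistic regression of the EMT
   class, giving an odds ratio `exp(β)` and two-sided Wald p. Genes are
   ranked within each type by −log10 p (rank 1 = largest p, average ranks
   for ties) and rank-sums across types select the top and bottom 5 genes.
4. **Survival stratification**: Kaplan-Meier curves and Mantel-Cox log-rank
   tests for stratifiers used throughout — single-gene mutation status,
   k-means (k=2) clusters over CNA or expression submatrices with
   deterministic high/low relabeling, mean/median/k-means expression splits,
   mutation-burden strata (none / single / multiple), and the combined
   mutation × expression three-group scheme (wild-type low / mixed /
   mutant high).
5. **Synthetic cohorts with planted effects** (`panmet.simulate`): a latent
   per-sample EMT axis shifted in metastatic samples, genes correlated with
   that axis at chosen ρ, group-specific copy-number gain frequencies,
   Bernoulli mutations, and exponential proportional-hazards survival with
   independent censoring — so every stage is validated by parameter
   recovery, null calibration and oracle cross-checks without external data.

## Worked example

```python
from panmet import (default_config, generate_cohort, compute_emt_score,
                    run_enrichment_screen)
from panmet.simulate import emt_sets_for
from panmet.emt import compare_groups_anova
from panmet.signature import (per_cancer_logistic_screens, rank_and_aggregate,
                              signature_cluster_and_survive)

cfg = default_config(seed=1)          # 7 cancer types x 200 samples, planted effects
cohort = generate_cohort(cfg)

emt = compute_emt_score(cohort, emt_sets_for(cfg))
types = cohort.clinical.set_index("sample_id")["sample_type"]
anova = compare_groups_anova(emt.scores, types)
print("EMT metastatic vs primary Tukey p:", f"{anova.tukey_p('metastatic', 'primary'):.3g}")

genes = [g for g in cohort.gene_universe() if not g.startswith("NULL")
         and g not in cfg.mesenchymal_genes + cfg.epithelial_genes]
gains = run_enrichment_screen(cohort, genes, "cna_gain")
print("CNA-gain enriched:", ", ".join(sorted(gains.loc[gains["significant"], "gene"])))

screens = per_cancer_logistic_screens(cohort, emt, genes)
sig = rank_and_aggregate(screens)
print("top-5 signature:", ", ".join(sorted(sig.top_genes)))

surv = signature_cluster_and_survive(cohort, sig.top_genes, seed=1)
print("signature-cluster log-rank p:", f"{surv['logrank'].p_value:.3g}",
      "| cluster sizes:", surv["cluster_sizes"])
```

Output:

```
EMT metastatic vs primary Tukey p: 0
CNA-gain enriched: CAV1, CD36, MLXIPL, PPARA, PPARD, SCO2
top-5 signature: CAV1, CD36, CPT1C, CYP2E1, MLXIPL
signature-cluster log-rank p: 5.25e-13 | cluster sizes: {'cluster_low': 755, 'cluster_high': 645}
```

The default configuration plants a metastatic EMT shift, six genes with
elevated gain frequency in metastatic samples (0.45 vs 0.10), five genes
correlated with the EMT axis at ρ = 0.7 whose shared high-expression group
carries hazard ratio e^0.7, and frequent TP53 mutations with hazard ratio
e^0.5 — the printed results show each planted effect being recovered: the
EMT score separates metastatic from primary tumors (Tukey p below double
precision), the gain screen flags exactly the six planted genes, the
rank-sum signature returns exactly the five planted genes, and clustering on
that signature splits survival at p ≈ 5×10⁻¹³.

## Command line

`panmet simulate | emt | mutations | cna | survival | associate | signature |
run-all`. For example:

```bash
panmet simulate --seed 3 --out-dir cohort/        # four TSVs + truth.json
panmet cna --cohort cohort/ --kind gain --out gain.tsv
panmet run-all --seed 4 --out-dir results/        # everything + run_summary.json
```

Two `run-all` invocations with the same config and seed produce
byte-identical outputs.

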