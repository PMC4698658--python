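"""Per-sample EMT score, mean-split stratification, and group comparison.

The EMT (epithelial-mesenchymal transition) score of a sample is the sum of
its mesenchymal marker-gene expression minus the sum of its epithelial
marker-gene expression, on log2-transformed values. Samples at or above the
cohort mean score are classed "high EMT", the rest "low EMT".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import EmtGeneSets, OmicsCohort, validate_gene_sets


@dataclass
class EmtScores:
    """Per-sample EMT scores plus the marker genes actually used."""

    scores: pd.Series  # indexed by sample_id
    mesenchymal_used: tuple[str, ...]
    epithelial_used: tuple[str, ...]


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj
    group_sizes: dict[str, int]
    excluded_groups: tuple[str, ...]

    def tukey_p(self, group1: str, group2: str) -> float:
        t = self.tukey
        m = ((t["group1"] == group1) & (t["group2"] == group2)) | (
            (t["group1"] == group2) & (t["group2"] == group1)
        )
        return float(t.loc[m, "p_adj"].iloc[0])


def compute_emt_score(cohort: OmicsCohort, emt_sets: EmtGeneSets) -> EmtScores:
    """EMT score per sample: Σ mesenchymal expression − Σ epithelial expression.

    Marker genes absent from the expression matrix are dropped (they are
    reported by :func:`panmet.datamodel.validate_gene_sets`, which also
    raises if either side would be empty).
    """
    validate_gene_sets(cohort, None, emt_sets)
    expr = cohort.expression
    mes = tuple(g for g in emt_sets.mesenchymal if g in expr.index)
    epi = tuple(g for g in emt_sets.epithelial if g in expr.index)
    scores = expr.loc[list(mes)].sum(axis=0) - expr.loc[list(epi)].sum(axis=0)
    scores.name = "emt_score"
    return EmtScores(scores=scores, mesenchymal_used=mes, epithelial_used=epi)


def stratify_by_mean(values: pd.Series) -> tuple[pd.Series, float]:
    """Label each value ``high`` if ≥ the arithmetic mean, else ``low``.

    Returns the labels and the threshold used. Constant input puts every
    sample in ``high`` (the mean is attained) with a warning.
    """
    vals = values.astype(float)
    if len(vals) < 2:
        raise ValueError("need at least 2 values to stratify")
    if not np.isfinite(vals.to_numpy()).all():
        raise ValueError("non-finite values cannot be stratified")
    threshold = float(vals.mean())
    if float(vals.max()) == float(vals.min()):
        warnings.warn("all values identical: every sample labeled 'high'")
    labels = pd.Series(
        np.where(vals.to_numpy() >= threshold, "high", "low"),
        index=vals.index,
        name="emt_class",
    )
    return labels, threshold


def compare_groups_anova(values: pd.Series, groups: pd.Series) -> AnovaResult:
    """One-way ANOVA across groups followed by Tukey HSD pairwise tests.

    Unequal group sizes are handled by the Tukey-Kramer adjustment (as in
    statsmodels). Groups with fewer than 2 observations are excluded with a
    warning; fewer than 2 usable groups is an error.
    """
    values = values.astype(float)
    groups = groups.reindex(values.index)
    sizes = groups.value_counts()
    excluded = tuple(sorted(sizes.index[sizes < 2]))
    if excluded:
        warnings.warn(f"excluding groups with <2 samples: {excluded}")
        keep = ~groups.isin(excluded)
        values, groups = values[keep], groups[keep]
    usable = sorted(groups.dropna().unique())
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >=2 samples each")

    arrays = [values[groups == g].to_numpy() for g in usable]
    f_stat, p = stats.f_oneway(*arrays)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tukey warns on zero within-group variance
        res = pairwise_tukeyhsd(values.to_numpy(), groups.to_numpy())
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    tukey = tukey.rename(columns={"meandiff": "mean_diff", "p-adj": "p_adj"})[
        ["group1", "group2", "mean_diff", "p_adj"]
    ]
    # statsmodels rounds the summary table; recompute exact values
    tukey["p_adj"] = res.pvalues
    tukey["mean_diff"] = res.meandiffs
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        tukey=tukey,
        group_sizes={g: int((groups == g).sum()) for g in usable},
        excluded_groups=excluded,
    )
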