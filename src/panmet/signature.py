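"""Cross-cancer metabolic gene signature from EMT association ranks.

Per cancer type, each candidate gene is (a) correlated with the per-sample
EMT score (Pearson, exact t-based p, Bonferroni across genes within the
cancer type) and (b) used as the sole predictor in a univariate logistic
regression of the low/high EMT class, yielding an odds ratio and a two-sided
Wald p. Within each cancer type genes are ranked by −log10(Wald p) with rank
1 for the largest p (least significant) and average ranks for ties; rank
sums across cancer types give the cumulative rank-sum from which the top
(most consistently EMT-associated) and bottom gene sets are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata

from .datamodel import OmicsCohort
from .emt import EmtScores, compute_emt_score, stratify_by_mean
from . import survival as surv

#: ranking convention: with "significant_high", rank 1 = largest p-value and
#: the top genes are those with the LARGEST cumulative rank-sum.
RANK_ORDERS = ("significant_high", "significant_low")

_SMALLEST_P = float(np.nextafter(0, 1))


@dataclass
class LogisticResult:
    """Univariate logistic fit of EMT class on one gene's expression."""

    cancer_type: str
    gene: str
    beta: float
    odds_ratio: float
    p_wald: float
    p_lr: float
    n: int
    separation: bool


@dataclass
class SignatureResult:
    """Cumulative rank-sum aggregation across cancer types."""

    rank_matrix: pd.DataFrame   # genes x cancer types
    rank_sum: pd.Series
    top_genes: tuple[str, ...]
    bottom_genes: tuple[str, ...]
    rank_order: str
    midpoint_imputed: dict[str, list[str]] = field(default_factory=dict)


def pearson_emt_association(
    expression: pd.DataFrame,
    emt_scores: pd.Series,
    genes: list[str] | tuple[str, ...],
    cancer_type: str = "",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson association of each gene with the EMT score, Bonferroni-adjusted.

    p-values come from the exact t transform t = r sqrt((n−2)/(1−r²)) with
    n−2 df, two-tailed. Constant genes are reported untestable with sign
    ``none`` and excluded from the Bonferroni family.
    """
    samples = [s for s in expression.columns if s in emt_scores.index]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for Pearson association")
    y = emt_scores.loc[samples].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant EMT scores: association undefined")
    present = [g for g in genes if g in expression.index]
    rows = []
    for g in present:
        x = expression.loc[g, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((cancer_type, g, np.nan, np.nan, np.nan, "none", False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((cancer_type, g, float(r), float(p), np.nan, "none", True))
    df = pd.DataFrame(
        rows,
        columns=["cancer_type", "gene", "pearson_r", "p_raw", "p_adj", "sign", "testable"],
    )
    m = int(df["testable"].sum())
    adj = np.minimum(1.0, df["p_raw"] * max(1, m))
    df["p_adj"] = adj.where(df["testable"])
    sig = df["testable"] & (df["p_adj"] < alpha)
    df.loc[sig & (df["pearson_r"] > 0), "sign"] = "positive"
    df.loc[sig & (df["pearson_r"] < 0), "sign"] = "negative"
    return df


def logistic_emt_or(
    x: pd.Series, emt_class: pd.Series, gene: str = "", cancer_type: str = ""
) -> LogisticResult:
    """Univariate logistic regression of EMT class (high=1) on expression.

    Newton/IRLS maximum likelihood (tol 1e-8, ≤100 iterations). Complete or
    quasi-complete separation (non-convergence or |beta| diverging) is
    flagged and the Wald p replaced by the smallest positive float so the
    gene ranks as maximally significant.
    """
    x = x.astype(float)
    y = emt_class.reindex(x.index)
    y01 = (y == "high").astype(float) if y.dtype == object else y.astype(float)
    if y01.nunique() < 2:
        raise ValueError("both EMT classes must be present")
    if float(x.max()) == float(x.min()):
        raise ValueError(f"constant expression for gene {gene!r}")
    X = sm.add_constant(x.to_numpy())
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y01.to_numpy(), X).fit(
                method="newton", tol=1e-8, maxiter=100, disp=0
            )
            beta = float(res.params[1])
            p_wald = float(res.pvalues[1])
            p_lr = float(res.llr_pvalue)
            if not res.mle_retvals.get("converged", True) or abs(beta) > 30:
                separation = True
        except Exception:
            separation = True
            beta, p_wald, p_lr = np.nan, np.nan, np.nan
    if separation:
        p_wald = _SMALLEST_P
        p_lr = _SMALLEST_P
    odds = float(np.exp(np.clip(beta, -700, 700))) if np.isfinite(beta) else np.nan
    return LogisticResult(
        cancer_type=cancer_type,
        gene=gene,
        beta=beta,
        odds_ratio=odds,
        p_wald=p_wald,
        p_lr=p_lr,
        n=int(len(x)),
        separation=separation,
    )


def logistic_screen(
    expression: pd.DataFrame,
    emt_class: pd.Series,
    genes: list[str] | tuple[str, ...],
    cancer_type: str = "",
) -> pd.DataFrame:
    """Logistic EMT-class fit for every present, non-constant gene."""
    present = [g for g in genes if g in expression.index]
    if not present:
        raise ValueError("no requested gene present in expression matrix")
    samples = [s for s in expression.columns if s in emt_class.index]
    rows = []
    for g in present:
        x = expression.loc[g, samples]
        if float(x.max()) == float(x.min()):
            continue
        rows.append(
            logistic_emt_or(x, emt_class, gene=g, cancer_type=cancer_type).__dict__
        )
    return pd.DataFrame(rows)


def per_cancer_logistic_screens(
    cohort: OmicsCohort,
    emt: EmtScores,
    genes: list[str] | tuple[str, ...],
    tumor_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the logistic screen separately within each cancer type.

    The low/high EMT class is defined per cancer type from that type's mean
    EMT score, over tumor (primary + metastatic) samples by default.
    """
    clin = cohort.clinical
    mask = clin["sample_type"].isin(["primary", "metastatic"]) if tumor_only else pd.Series(True, index=clin.index)
    out: dict[str, pd.DataFrame] = {}
    for ct in sorted(clin["cancer_type"].unique()):
        ids = clin.loc[mask & (clin["cancer_type"] == ct), "sample_id"]
        if len(ids) < 4:
            warnings.warn(f"skipping cancer type {ct}: too few tumor samples")
            continue
        scores = emt.scores.loc[ids]
        labels, _ = stratify_by_mean(scores)
        if labels.nunique() < 2:
            warnings.warn(f"skipping cancer type {ct}: single EMT class")
            continue
        out[ct] = logistic_screen(
            cohort.expression[list(ids)], labels, genes, cancer_type=ct
        )
    return out


def rank_and_aggregate(
    per_cancer: dict[str, pd.DataFrame],
    n_top: int = 5,
    n_bottom: int = 5,
    rank_order: str = "significant_high",
    p_column: str = "p_wald",
) -> SignatureResult:
    """Rank genes within each cancer type by −log10 p and sum ranks.

    Rank 1 goes to the largest p (least significant); ties get average
    ranks; a gene missing from one cancer type receives that type's midpoint
    rank (n+1)/2. With the default ``significant_high`` order, the top genes
    are those with the largest cumulative rank-sum (most consistently
    significant); ``significant_low`` flips the selection.
    """
    if rank_order not in RANK_ORDERS:
        raise ValueError(f"rank_order must be one of {RANK_ORDERS}")
    if not per_cancer:
        raise ValueError("no per-cancer results to aggregate")
    if len(per_cancer) < 2:
        warnings.warn("aggregating a single cancer type: rank-sum degenerates to its ranks")
    all_genes = sorted({g for df in per_cancer.values() for g in df["gene"]})
    types = sorted(per_cancer)
    rank_matrix = pd.DataFrame(index=all_genes, columns=types, dtype=float)
    imputed: dict[str, list[str]] = {}
    for ct in types:
        df = per_cancer[ct]
        p = df[p_column].to_numpy(dtype=float)
        neglog = -np.log10(np.clip(p, _SMALLEST_P, 1.0))
        ranks = rankdata(neglog, method="average")  # rank 1 = largest p
        rank_matrix.loc[list(df["gene"]), ct] = ranks
        missing = [g for g in all_genes if g not in set(df["gene"])]
        if missing:
            rank_matrix.loc[missing, ct] = (len(df) + 1) / 2.0
            imputed[ct] = missing
    rank_sum = rank_matrix.sum(axis=1)
    k = min(n_top, len(all_genes) // 2)
    kb = min(n_bottom, len(all_genes) // 2)
    # deterministic tie-break on gene name
    by_sum = rank_sum.to_frame("rank_sum").reset_index(names="gene")
    desc = by_sum.sort_values(["rank_sum", "gene"], ascending=[False, True], kind="mergesort")
    asc = by_sum.sort_values(["rank_sum", "gene"], ascending=[True, True], kind="mergesort")
    if rank_order == "significant_high":
        top = tuple(desc["gene"].head(k))
        bottom = tuple(asc["gene"].head(kb))
    else:
        top = tuple(asc["gene"].head(k))
        bottom = tuple(desc["gene"].head(kb))
    return SignatureResult(
        rank_matrix=rank_matrix,
        rank_sum=rank_sum,
        top_genes=top,
        bottom_genes=bottom,
        rank_order=rank_order,
        midpoint_imputed=imputed,
    )


def signature_cluster_and_survive(
    cohort: OmicsCohort,
    genes: list[str] | tuple[str, ...],
    seed: int = 0,
    tumor_only: bool = True,
) -> dict:
    """Cluster samples (k-means, k=2) on a signature's expression and compare
    survival between the two clusters with the log-rank test."""
    present = [g for g in genes if g in cohort.expression.index]
    if not present:
        raise ValueError("no signature gene present in expression matrix")
    if tumor_only:
        mask = cohort.tumor_mask()
        samples = list(mask.index[mask])
    else:
        samples = cohort.sample_ids
    sub = cohort.expression.loc[present, samples]
    labels = surv.kmeans_stratify(sub, seed=seed)
    curves, lr = surv.survival_by_labels(cohort, labels)
    means = {
        lab: float(sub.loc[:, labels.index[labels == lab]].to_numpy().mean())
        for lab in ("cluster_low", "cluster_high")
        if (labels == lab).any()
    }
    return {
        "genes": list(present),
        "labels": labels,
        "cluster_sizes": {k: int(v) for k, v in labels.value_counts().items()},
        "cluster_mean_expression": means,
        "curves": curves,
        "logrank": lr,
    }
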