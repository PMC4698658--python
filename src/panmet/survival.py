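"""Kaplan-Meier estimation, log-rank testing, and sample stratifiers.

Estimation and testing are delegated to lifelines (product-limit estimator
and Mantel-Cox log-rank with the standard hypergeometric variance); this
module contributes the stratification schemes used throughout the analyses:
single-gene mutation status, k-means clusters over an omics submatrix,
single-gene expression splits, and the combined mutation × expression
three-group scheme. Deaths are processed before censorings at tied times
(the standard convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.cluster import KMeans

from .datamodel import OmicsCohort


@dataclass
class KmCurve:
    """Product-limit survival curve of one group, stepped at event times."""

    times: np.ndarray       # distinct times with >=1 event, ascending
    at_risk: np.ndarray     # risk-set size just before each event time
    events: np.ndarray      # deaths at each event time
    survival: np.ndarray    # S(t) just after each event time
    label: str
    n: int


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float
    group_sizes: dict[str, int]


def km_estimate(times, events, label: str = "") -> KmCurve:
    """Kaplan-Meier product-limit estimate. Censoring reduces the risk set
    without stepping the curve; with no events the curve is identically 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    t = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    return KmCurve(
        times=t,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
        label=label,
        n=int(times.size),
    )


def logrank_test(times, events, labels) -> LogrankResult:
    """Mantel-Cox log-rank test across ≥2 groups (chi-square, k−1 df).

    Groups with zero observations are excluded with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    keep = ~pd.isna(labels)
    times, events, labels = times[keep], events[keep], labels[keep]
    sizes = pd.Series(labels).value_counts()
    empty = [g for g in sizes.index if sizes[g] == 0]
    if empty:
        warnings.warn(f"excluding empty groups: {empty}")
    groups = sorted(sizes.index[sizes > 0])
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(
        chi_square=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
        group_sizes={str(g): int(sizes[g]) for g in groups},
    )


def survival_by_labels(cohort: OmicsCohort, labels: pd.Series) -> tuple[list[KmCurve], LogrankResult]:
    """KM curves + log-rank for cohort samples stratified by ``labels``.

    Samples with missing survival data are dropped (logged via warning count
    only when any are dropped).
    """
    clin = cohort.clinical.set_index("sample_id")
    labels = labels.reindex(clin.index)
    t = clin["os_days"].astype(float)
    e = clin["os_event"].astype(float)
    ok = t.notna() & e.notna() & labels.notna()
    n_drop = int((~ok).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} sample(s) with missing survival data or label")
    t, e, labels = t[ok], e[ok].astype(int), labels[ok]
    curves = [
        km_estimate(t[labels == g], e[labels == g], label=str(g))
        for g in sorted(labels.unique())
    ]
    lr = logrank_test(t.to_numpy(), e.to_numpy(), labels.to_numpy())
    return curves, lr


# ---------------------------------------------------------------------------
# stratifiers
# ---------------------------------------------------------------------------

def stratify_mutation(cohort: OmicsCohort, gene: str) -> pd.Series:
    """Two groups: samples with vs without a non-synonymous mutation in ``gene``."""
    if gene not in cohort.mutation.index:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    ind = cohort.mutation.loc[gene]
    return pd.Series(
        np.where(ind.to_numpy() == 1, "mutation", "no_mutation"),
        index=ind.index,
        name=f"{gene}_mutation",
    )


def kmeans_stratify(
    matrix: pd.DataFrame, seed: int = 0, n_restarts: int = 25
) -> pd.Series:
    """Split samples into two k-means clusters over a gene-by-sample submatrix.

    Euclidean distance, k = 2, best of ``n_restarts`` initializations.
    Cluster labels are made deterministic by calling the cluster whose
    centroid has the larger mean value ``cluster_high``.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate clustering input: all samples identical")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    high_cluster = int(np.argmax(km.cluster_centers_.mean(axis=1)))
    labels = np.where(assign == high_cluster, "cluster_high", "cluster_low")
    return pd.Series(labels, index=matrix.columns, name="cluster")


def stratify_expression(
    cohort: OmicsCohort, gene: str, method: str = "mean", seed: int = 0
) -> tuple[pd.Series, dict]:
    """Split samples into low/high expression of one gene.

    ``method``: ``mean`` (default; ties at the threshold go to high),
    ``median`` (same rule at the median), or ``kmeans`` (1-d k-means, k=2).
    Returns labels plus a record of the method and threshold used.
    """
    if gene not in cohort.expression.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    x = cohort.expression.loc[gene].astype(float)
    if method in ("mean", "median"):
        threshold = float(x.mean() if method == "mean" else x.median())
        if float(x.max()) == float(x.min()):
            warnings.warn(f"constant expression for {gene}: every sample labeled 'high'")
        labels = pd.Series(
            np.where(x.to_numpy() >= threshold, "high", "low"), index=x.index
        )
        meta = {"method": method, "threshold": threshold}
    elif method == "kmeans":
        clusters = kmeans_stratify(x.to_frame().T, seed=seed)
        labels = clusters.map({"cluster_high": "high", "cluster_low": "low"})
        meta = {"method": "kmeans", "threshold": None}
    else:
        raise ValueError("method must be one of: mean, median, kmeans")
    labels.name = f"{gene}_expression"
    return labels, meta


def stratify_combined_mut_expr(
    cohort: OmicsCohort,
    mut_gene: str,
    expr_gene: str,
    expr_method: str = "mean",
) -> pd.Series:
    """Three groups from mutation × expression state of two genes.

    ``wt_low`` = wild-type and low expression; ``mut_high`` = mutant and high
    expression; ``mixed`` = exactly one of the two altered.
    """
    mut = stratify_mutation(cohort, mut_gene) == "mutation"
    expr, _ = stratify_expression(cohort, expr_gene, method=expr_method)
    high = expr == "high"
    labels = np.where(
        ~mut & ~high, "wt_low", np.where(mut & high, "mut_high", "mixed")
    )
    return pd.Series(labels, index=expr.index, name=f"{mut_gene}_{expr_gene}_combined")
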