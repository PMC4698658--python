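"""Independent reference implementations used to cross-check the pipeline.

These are deliberately naive (enumeration, explicit loops, textbook
formulas) and share no code with the implementation paths they verify.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher exact p by enumerating all tables with fixed margins.

    Sums hypergeometric probabilities of every table whose probability does
    not exceed the observed table's (with the standard 1+1e-7 relative guard
    against ties lost to floating point).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    n_total = a + b + c + d
    col1 = a + c
    row1 = a + b
    lo = max(0, row1 - (n_total - col1))
    hi = min(col1, row1)
    p_obs = hypergeom.pmf(a, n_total, col1, row1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n_total, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def logrank_chi_square_oe(times, events, groups) -> float:
    """Two-group log-rank chi-square from the direct O−E / V formula."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    names = np.unique(groups)
    assert len(names) == 2
    g1 = groups == names[0]
    obs = exp = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float((obs - exp) ** 2 / var)


def km_product_limit(times, events) -> list[tuple[float, float]]:
    """(event time, S(t)) pairs computed step by step from the definition."""
    order = np.argsort(times, kind="mergesort")
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    s = 1.0
    out = []
    for t in np.unique(times[events == 1]):
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_t / n_t
        out.append((float(t), s))
    return out


def logistic_irls(x, y, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Maximum-likelihood logistic fit (intercept + slope) by plain IRLS."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = mu * (1.0 - mu)
        hessian = X.T @ (X * w[:, None])
        step = np.linalg.solve(hessian, X.T @ (y - mu))
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def pearson_direct(x, y) -> tuple[float, float]:
    """Pearson r by explicit covariance sums plus the exact t-transform p."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * t_dist.sf(abs(t), n - 2))
    return r, p
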