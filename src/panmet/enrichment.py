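"""Per-gene alteration enrichment in metastatic vs primary tumors.

For each gene, the observed numbers of altered samples (non-synonymous
mutation, copy-number gain, or copy-number loss) in the metastatic and
primary groups are compared against the counts expected from the pooled
alteration frequency: expected_group = pooled_frequency × n_group. The
default test applies Fisher's exact test to the 2×2 table

    [[observed_met, observed_primary],
     [expected_met, expected_primary]]

with expected counts rounded half-to-even to integers (the exact test needs
integer counts). This observed-vs-expected construction is statistically
unconventional; ``table_mode="standard"`` switches to the conventional
altered/unaltered × group table. Bonferroni correction is applied across the
genes actually testable within one screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import OmicsCohort

ALTERATION_KINDS = ("mutation", "cna_gain", "cna_loss")
TABLE_MODES = ("observed-expected", "standard")

#: rounding policy applied to expected counts before the exact test
ROUNDING_POLICY = "round half to even (numpy rint)"


@dataclass
class EnrichmentResult:
    """Enrichment test result for one gene and one alteration kind."""

    gene: str
    alteration_kind: str
    n_metastatic: int
    n_primary: int
    freq_metastatic: float
    freq_primary: float
    observed_met: int
    observed_primary: int
    expected_met: int
    expected_primary: int
    p_raw: float
    p_adj: float
    significant: bool
    direction: str  # metastatic_enriched | primary_enriched | none
    testable: bool
    table_mode: str


def discretize_cna(cna: pd.DataFrame) -> pd.DataFrame:
    """Map integer copy-number calls to {gain, loss, neutral}.

    A call ≥ 1 is a gain, ≤ −1 a loss, 0 neutral.
    """
    vals = cna.to_numpy()
    if not np.isin(vals, [-2, -1, 0, 1, 2]).all():
        raise ValueError("copy-number calls must be integers in [-2, 2]")
    out = np.where(vals >= 1, "gain", np.where(vals <= -1, "loss", "neutral"))
    return pd.DataFrame(out, index=cna.index, columns=cna.columns)


def _fisher_table(
    obs_met: int, obs_pri: int, n_met: int, n_pri: int, table_mode: str
) -> np.ndarray:
    if table_mode == "observed-expected":
        pooled = (obs_met + obs_pri) / (n_met + n_pri)
        exp_met = int(np.rint(pooled * n_met))
        exp_pri = int(np.rint(pooled * n_pri))
        return np.array([[obs_met, obs_pri], [exp_met, exp_pri]])
    # standard: altered / unaltered by group
    return np.array([[obs_met, n_met - obs_met], [obs_pri, n_pri - obs_pri]])


def enrichment_test(
    indicator: pd.Series,
    is_metastatic: pd.Series,
    gene: str = "",
    alteration_kind: str = "mutation",
    table_mode: str = "observed-expected",
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> EnrichmentResult:
    """Test one gene's alteration frequency, metastatic vs primary.

    ``indicator`` is the 0/1 altered status per sample; ``is_metastatic`` the
    boolean group label over the same samples. A gene altered in neither
    group is untestable: p = 1, direction ``none``.
    """
    if table_mode not in TABLE_MODES:
        raise ValueError(f"table_mode must be one of {TABLE_MODES}")
    ind = indicator.to_numpy(dtype=float)
    if not np.isin(ind, [0.0, 1.0]).all():
        raise ValueError(f"alteration indicator for {gene!r} must be 0/1")
    met = is_metastatic.reindex(indicator.index).to_numpy(dtype=bool)
    n_met, n_pri = int(met.sum()), int((~met).sum())
    if n_met == 0 or n_pri == 0:
        raise ValueError("both metastatic and primary groups must be non-empty")
    obs_met = int(ind[met].sum())
    obs_pri = int(ind[~met].sum())
    freq_met, freq_pri = obs_met / n_met, obs_pri / n_pri

    pooled = (obs_met + obs_pri) / (n_met + n_pri)
    exp_met = int(np.rint(pooled * n_met))
    exp_pri = int(np.rint(pooled * n_pri))

    testable = (obs_met + obs_pri) > 0
    if not testable:
        p_raw = 1.0
    else:
        table = _fisher_table(obs_met, obs_pri, n_met, n_pri, table_mode)
        _, p_raw = stats.fisher_exact(table, alternative="two-sided")
        p_raw = float(p_raw)
    p_adj = min(1.0, p_raw * max(1, bonferroni_m)) if testable else 1.0
    significant = testable and p_adj < alpha
    if significant and freq_met > freq_pri:
        direction = "metastatic_enriched"
    elif significant and freq_met < freq_pri:
        direction = "primary_enriched"
    else:
        direction = "none"
    return EnrichmentResult(
        gene=gene,
        alteration_kind=alteration_kind,
        n_metastatic=n_met,
        n_primary=n_pri,
        freq_metastatic=freq_met,
        freq_primary=freq_pri,
        observed_met=obs_met,
        observed_primary=obs_pri,
        expected_met=exp_met,
        expected_primary=exp_pri,
        p_raw=p_raw,
        p_adj=p_adj,
        significant=significant,
        direction=direction,
        testable=testable,
        table_mode=table_mode,
    )


def _alteration_matrix(cohort: OmicsCohort, alteration_kind: str) -> pd.DataFrame:
    if alteration_kind == "mutation":
        return cohort.mutation
    if alteration_kind == "cna_gain":
        return (cohort.cna >= 1).astype(int)
    if alteration_kind == "cna_loss":
        return (cohort.cna <= -1).astype(int)
    raise ValueError(f"alteration_kind must be one of {ALTERATION_KINDS}")


def run_enrichment_screen(
    cohort: OmicsCohort,
    genes: list[str] | tuple[str, ...],
    alteration_kind: str,
    table_mode: str = "observed-expected",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen a gene list for enrichment of one alteration kind.

    Only primary and metastatic tumors enter the test; the pooled frequency
    used for expected counts is computed over those two groups. Bonferroni's
    m is the number of genes with at least one altered sample (untestable
    genes are reported but not counted). Result is sorted by raw p.
    """
    mat = _alteration_matrix(cohort, alteration_kind)
    present = [g for g in genes if g in mat.index]
    if not present:
        raise ValueError(f"none of the requested genes are in the {alteration_kind} matrix")
    tumor = cohort.tumor_mask()
    samples = tumor.index[tumor]
    is_met = cohort.metastatic_mask().loc[samples]

    results = [
        enrichment_test(
            mat.loc[g, samples],
            is_met,
            gene=g,
            alteration_kind=alteration_kind,
            table_mode=table_mode,
            alpha=alpha,
        )
        for g in present
    ]
    m = sum(r.testable for r in results)
    for r in results:
        if r.testable:
            r.p_adj = min(1.0, r.p_raw * max(1, m))
            r.significant = r.p_adj < alpha
            if not r.significant:
                r.direction = "none"
            elif r.freq_metastatic > r.freq_primary:
                r.direction = "metastatic_enriched"
            elif r.freq_metastatic < r.freq_primary:
                r.direction = "primary_enriched"
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.sort_values(["p_raw", "gene"], kind="mergesort").reset_index(drop=True)


def basal_mutation_frequency(mutation: pd.DataFrame) -> float:
    """Cumulative mutation count over all genes / (n_genes × n_samples)."""
    if mutation.size == 0:
        raise ValueError("empty mutation matrix")
    return float(mutation.to_numpy(dtype=float).mean())


def mutation_burden_strata(
    mutation: pd.DataFrame, category_genes: list[str] | tuple[str, ...]
) -> pd.Series:
    """Per-sample mutation burden within a gene category: none/single/multiple."""
    present = [g for g in category_genes if g in mutation.index]
    if not present:
        raise ValueError("no category gene present in the mutation matrix")
    counts = mutation.loc[present].sum(axis=0)
    strata = pd.Series(
        np.where(counts == 0, "none", np.where(counts == 1, "single", "multiple")),
        index=mutation.columns,
        name="burden",
    )
    return strata
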