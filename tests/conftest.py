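"""Shared fixtures: small programmatically built cohorts and gene sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panmet.datamodel import EmtGeneSets, GeneModel, OmicsCohort


def make_cohort(
    expression: pd.DataFrame,
    mutation: pd.DataFrame | None = None,
    cna: pd.DataFrame | None = None,
    sample_type: list[str] | None = None,
    cancer_type: list[str] | None = None,
    os_days: list[float] | None = None,
    os_event: list[int] | None = None,
) -> OmicsCohort:
    """Assemble a valid cohort around an expression matrix, defaulting the rest."""
    samples = list(expression.columns)
    n = len(samples)
    if mutation is None:
        mutation = pd.DataFrame(0, index=expression.index, columns=samples)
    if cna is None:
        cna = pd.DataFrame(0, index=expression.index, columns=samples)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "cancer_type": cancer_type or ["BRCA"] * n,
            "sample_type": sample_type or ["primary"] * n,
            "os_days": os_days or list(np.linspace(100, 1000, n)),
            "os_event": os_event or [1] * n,
        }
    )
    return OmicsCohort(expression=expression, mutation=mutation, cna=cna, clinical=clinical)


@pytest.fixture
def emt_sets() -> EmtGeneSets:
    return EmtGeneSets.from_lists(
        ["CDH2", "FN1", "SNAI1", "SNAI2", "VIM", "TWIST1", "TWIST2", "ZEB2"],
        ["CDH1", "CLDN4", "CLDN7", "MUC1", "TJP3"],
    )


@pytest.fixture
def gene_model() -> GeneModel:
    return GeneModel.from_dict(
        {"warburg": ["TP53", "STK11", "SCO2"], "fa_uptake": ["CAV1", "CD36"]}
    )


@pytest.fixture
def tiny_cohort() -> OmicsCohort:
    """3 genes x 4 samples with non-trivial mutation/CNA entries."""
    genes = ["TP53", "CAV1", "SCO2"]
    samples = ["S1", "S2", "S3", "S4"]
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(
        np.round(rng.uniform(2, 10, (3, 4)), 3), index=genes, columns=samples
    )
    mut = pd.DataFrame([[1, 0, 0, 1], [0, 0, 1, 0], [0, 0, 0, 0]], index=genes, columns=samples)
    cna = pd.DataFrame([[0, 1, -1, 2], [2, 0, 0, -2], [0, 0, 1, 0]], index=genes, columns=samples)
    return make_cohort(
        expr, mut, cna, sample_type=["primary", "primary", "metastatic", "metastatic"]
    )


@pytest.fixture
def emt_cohort(emt_sets) -> OmicsCohort:
    """13-marker-gene cohort where every mesenchymal value is 2, epithelial 1."""
    genes = list(emt_sets.mesenchymal) + list(emt_sets.epithelial)
    samples = [f"S{i}" for i in range(6)]
    vals = np.array([[2.0] * 6] * 8 + [[1.0] * 6] * 5)
    expr = pd.DataFrame(vals, index=genes, columns=samples)
    return make_cohort(expr, sample_type=["primary"] * 3 + ["metastatic"] * 3)
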