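"""Core data structures for pan-cancer multi-omics analysis.

The central container is :class:`OmicsCohort`: gene-by-sample expression,
mutation and copy-number matrices, column-aligned to a per-sample clinical
table. Gene lists used by the analyses are carried by :class:`GeneModel`
(metabolic pathway categories, e.g. Warburg effect or fatty-acid uptake) and
:class:`EmtGeneSets` (mesenchymal and epithelial marker genes defining the
EMT score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Controlled vocabulary for the clinical ``sample_type`` column.
SAMPLE_TYPES = ("normal", "primary", "metastatic", "blood")

#: Required clinical table columns, in canonical order.
CLINICAL_COLUMNS = ("sample_id", "cancer_type", "sample_type", "os_days", "os_event")


class CohortValidationError(ValueError):
    """Raised when a cohort or gene-set configuration violates an invariant."""


def _upper_unique(genes: Iterable[str], context: str) -> tuple[str, ...]:
    """Uppercase gene symbols, dropping duplicates with a warning naming them."""
    seen: dict[str, None] = {}
    for g in genes:
        g = str(g).upper()
        if g in seen:
            warnings.warn(f"duplicate gene symbol {g!r} in {context}; keeping one copy")
        else:
            seen[g] = None
    return tuple(seen)


@dataclass(frozen=True)
class GeneModel:
    """Named gene categories of the metabolic pathway model.

    The shipped default has four categories: ``warburg`` (aerobic-glycolysis
    regulators), ``lipogenesis``, ``fa_oxidation`` and ``fa_uptake``.
    """

    categories: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_dict(
        cls, categories: Mapping[str, Sequence[str]], allow_overlap: bool = False
    ) -> "GeneModel":
        clean: dict[str, tuple[str, ...]] = {}
        for name, genes in categories.items():
            if not genes:
                raise CohortValidationError(f"gene-model category {name!r} is empty")
            clean[str(name)] = _upper_unique(genes, f"gene-model category {name!r}")
        if not allow_overlap:
            assignment: dict[str, str] = {}
            for name, genes in clean.items():
                for g in genes:
                    if g in assignment:
                        raise CohortValidationError(
                            f"gene {g} appears in both {assignment[g]!r} and {name!r}; "
                            "pass allow_overlap=True to permit this"
                        )
                    assignment[g] = name
        return cls(categories=clean)

    def all_genes(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for genes in self.categories.values():
            for g in genes:
                out[g] = None
        return tuple(out)


@dataclass(frozen=True)
class EmtGeneSets:
    """Mesenchymal and epithelial marker genes defining the EMT score."""

    mesenchymal: tuple[str, ...]
    epithelial: tuple[str, ...]

    @classmethod
    def from_lists(
        cls, mesenchymal: Sequence[str], epithelial: Sequence[str]
    ) -> "EmtGeneSets":
        mes = _upper_unique(mesenchymal, "mesenchymal gene set")
        epi = _upper_unique(epithelial, "epithelial gene set")
        if not mes or not epi:
            raise CohortValidationError("EMT gene sets must both be non-empty")
        overlap = set(mes) & set(epi)
        if overlap:
            raise CohortValidationError(
                f"EMT gene sets overlap: {sorted(overlap)}; the score is undefined "
                "for genes counted on both sides"
            )
        return cls(mesenchymal=mes, epithelial=epi)


@dataclass
class OmicsCohort:
    """Aligned expression / mutation / copy-number matrices plus clinical data.

    All matrices are gene-by-sample :class:`pandas.DataFrame` objects whose
    columns follow the clinical table's ``sample_id`` order exactly. The
    three matrices may carry different gene sets.
    """

    expression: pd.DataFrame
    mutation: pd.DataFrame
    cna: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])

    def gene_universe(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for mat in (self.expression, self.mutation, self.cna):
            for g in mat.index:
                out[g] = None
        return tuple(out)

    def tumor_mask(self) -> pd.Series:
        """Boolean mask (indexed by sample_id) selecting primary + metastatic."""
        m = self.clinical["sample_type"].isin(["primary", "metastatic"])
        m.index = self.clinical["sample_id"]
        return m

    def metastatic_mask(self) -> pd.Series:
        m = self.clinical["sample_type"].eq("metastatic")
        m.index = self.clinical["sample_id"]
        return m

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        clin = self.clinical
        missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
        if missing:
            raise CohortValidationError(f"clinical table lacks columns {missing}")
        ids = clin["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortValidationError(f"duplicate sample id {dup!r} in clinical table")
        bad_type = set(clin["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise CohortValidationError(
                f"unknown sample_type values {sorted(bad_type)}; expected {SAMPLE_TYPES}"
            )
        os_days = clin["os_days"].to_numpy(dtype=float)
        if np.nanmin(os_days, initial=0.0) < 0:
            raise CohortValidationError("os_days must be non-negative")
        ev = clin["os_event"].to_numpy(dtype=float)
        ok = np.isnan(ev) | (ev == 0) | (ev == 1)
        if not ok.all():
            raise CohortValidationError("os_event must be 0, 1 or missing")

        order = list(ids)
        for name, mat in (
            ("expression", self.expression),
            ("mutation", self.mutation),
            ("cna", self.cna),
        ):
            if list(mat.columns) != order:
                raise CohortValidationError(
                    f"{name} matrix columns are not aligned to the clinical sample order"
                )
            if mat.index.duplicated().any():
                dup = mat.index[mat.index.duplicated()][0]
                raise CohortValidationError(f"duplicate gene {dup!r} in {name} matrix")

        expr = self.expression.to_numpy(dtype=float)
        if expr.size and not np.isfinite(expr).all():
            i, j = np.argwhere(~np.isfinite(expr))[0]
            raise CohortValidationError(
                "non-finite expression value at gene "
                f"{self.expression.index[i]!r}, sample {self.expression.columns[j]!r}"
            )
        _check_integer_matrix(self.mutation, "mutation", {0, 1})
        _check_integer_matrix(self.cna, "cna", {-2, -1, 0, 1, 2})


def _check_integer_matrix(mat: pd.DataFrame, name: str, allowed: set[int]) -> None:
    vals = mat.to_numpy(dtype=float)
    if vals.size == 0:
        return
    ok = np.isin(vals, list(allowed))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise CohortValidationError(
            f"invalid {name} value {mat.iat[i, j]!r} at gene {mat.index[i]!r}, "
            f"sample {mat.columns[j]!r}; allowed: {sorted(allowed)}"
        )


def validate_gene_sets(
    cohort: OmicsCohort, gene_model: GeneModel | None, emt_sets: EmtGeneSets | None
) -> dict[str, dict[str, list[str]]]:
    """Report genes from the configured gene lists absent from each matrix.

    Returns ``{list_name: {matrix_name: [missing genes]}}`` with empty levels
    omitted, so a cohort containing every configured gene yields ``{}``.
    Raises :class:`CohortValidationError` if the EMT score is undefined, i.e.
    every mesenchymal or every epithelial gene is missing from expression.
    """
    matrices = {
        "expression": set(cohort.expression.index),
        "mutation": set(cohort.mutation.index),
        "cna": set(cohort.cna.index),
    }
    lists: dict[str, tuple[str, ...]] = {}
    if gene_model is not None:
        lists.update(gene_model.categories)
    if emt_sets is not None:
        lists["mesenchymal"] = emt_sets.mesenchymal
        lists["epithelial"] = emt_sets.epithelial

    report: dict[str, dict[str, list[str]]] = {}
    for list_name, genes in lists.items():
        per_matrix = {
            mat_name: sorted(set(genes) - present)
            for mat_name, present in matrices.items()
        }
        per_matrix = {k: v for k, v in per_matrix.items() if v}
        if per_matrix:
            report[list_name] = per_matrix

    if emt_sets is not None:
        expr = matrices["expression"]
        if not (set(emt_sets.mesenchymal) & expr):
            raise CohortValidationError(
                "no mesenchymal gene present in expression: EMT score undefined"
            )
        if not (set(emt_sets.epithelial) & expr):
            raise CohortValidationError(
                "no epithelial gene present in expression: EMT score undefined"
            )
    return report
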