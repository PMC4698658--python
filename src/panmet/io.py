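"""Reading and writing cohort matrices, clinical tables and gene-set configs.

File conventions: omics matrices are UTF-8 TSV with genes as rows, samples
as columns and the first column headed ``gene``; the clinical table is a TSV
with columns ``sample_id, cancer_type, sample_type, os_days, os_event``;
gene models and EMT gene sets are YAML. Gene symbols are uppercased on load
so matching against configured lists is case-insensitive.
"""

from __future__ import annotations

import json
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    CLINICAL_COLUMNS,
    SAMPLE_TYPES,
    CohortValidationError,
    EmtGeneSets,
    GeneModel,
    OmicsCohort,
)

logger = logging.getLogger(__name__)

# TCGA-style barcode, used only to detect transposed matrices heuristically.
_SAMPLE_ID_RE = re.compile(r"^TCGA-|-\d{2}$")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the file."""


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed TSV {path}: {exc}") from exc


def load_matrix(path: str | Path) -> pd.DataFrame:
    """Load one gene-by-sample matrix; uppercases gene symbols."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    return df


def load_sample_type_map(path: str | Path | None = None) -> dict[str, str]:
    """Normalization table from raw sample-type labels to the fixed vocabulary."""
    if path is None:
        text = resources.files("panmet.data").joinpath("sample_types.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    table = {str(k).strip().lower(): str(v) for k, v in raw.items()}
    bad = set(table.values()) - set(SAMPLE_TYPES)
    if bad:
        raise CohortValidationError(f"sample-type map targets unknown types {sorted(bad)}")
    return table


def load_clinical(
    path: str | Path, sample_type_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    if sample_type_map is None:
        sample_type_map = load_sample_type_map()
    clin = _read_tsv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise ParseError(f"clinical table {path} lacks columns {missing}")
    raw = clin["sample_type"].astype(str).str.strip().str.lower()
    clin["sample_type"] = raw.map(lambda s: sample_type_map.get(s, s))
    clin["sample_id"] = clin["sample_id"].astype(str)
    return clin


def load_cohort(
    expression_path: str | Path,
    mutation_path: str | Path,
    cna_path: str | Path,
    clinical_path: str | Path,
    sample_type_map: Mapping[str, str] | None = None,
    log2_transform: bool = False,
    drop_missing_expression: bool = False,
) -> OmicsCohort:
    """Load and align the three omics matrices with the clinical table.

    Samples are restricted to the intersection of the matrices' columns and
    the clinical sample ids (dropped samples are logged); matrix columns are
    reordered to the clinical order. With ``log2_transform`` the expression
    matrix is mapped through log2(x + 1) (for inputs not already on log
    scale). ``drop_missing_expression`` drops genes with any missing
    expression value instead of failing.
    """
    expression = load_matrix(expression_path)
    mutation = load_matrix(mutation_path)
    cna = load_matrix(cna_path)
    clinical = load_clinical(clinical_path, sample_type_map)
    clin_ids = set(clinical["sample_id"])

    for name, mat, path in (
        ("expression", expression, expression_path),
        ("mutation", mutation, mutation_path),
        ("cna", cna, cna_path),
    ):
        # A matrix whose *rows* look like sample ids was probably transposed.
        n_idlike = sum(
            1 for g in mat.index if g in clin_ids or _SAMPLE_ID_RE.search(str(g))
        )
        if len(mat.index) and n_idlike / len(mat.index) > 0.5:
            raise ParseError(
                f"{name} matrix {path} appears transposed (row labels look like "
                "sample ids); expected genes as rows and samples as columns"
            )

    common = [
        s
        for s in clinical["sample_id"]
        if s in expression.columns and s in mutation.columns and s in cna.columns
    ]
    if not common:
        raise CohortValidationError(
            "no sample id shared by all three matrices and the clinical table"
        )
    n_all = {len(expression.columns), len(mutation.columns), len(cna.columns), len(clinical)}
    dropped = max(n_all) - len(common)
    if dropped:
        logger.info("dropped %d sample(s) absent from some input", dropped)
    clinical = clinical[clinical["sample_id"].isin(common)].reset_index(drop=True)
    order = list(clinical["sample_id"])
    expression = expression.loc[:, order]
    mutation = mutation.loc[:, order]
    cna = cna.loc[:, order]

    if expression.isna().any().any():
        if drop_missing_expression:
            n0 = len(expression)
            expression = expression.dropna(axis=0)
            logger.info("dropped %d gene(s) with missing expression", n0 - len(expression))
        else:
            gene = expression.index[expression.isna().any(axis=1)][0]
            raise CohortValidationError(
                f"missing expression values (first at gene {gene!r}); "
                "set drop_missing_expression=True to drop such genes"
            )
    if log2_transform:
        expression = np.log2(expression.astype(float) + 1.0)

    return OmicsCohort(expression=expression, mutation=mutation, cna=cna, clinical=clinical)


def write_cohort(cohort: OmicsCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort files as TSV; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "mutation": out / "mutation.tsv",
        "cna": out / "cna.tsv",
        "clinical": out / "clinical.tsv",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    cohort.mutation.to_csv(paths["mutation"], sep="\t", index_label="gene")
    cohort.cna.to_csv(paths["cna"], sep="\t", index_label="gene")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    return paths


def load_cohort_dir(
    cohort_dir: str | Path, **kw
) -> OmicsCohort:
    """Load a cohort from a directory laid out as written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    return load_cohort(
        d / "expression.tsv", d / "mutation.tsv", d / "cna.tsv", d / "clinical.tsv", **kw
    )


def load_gene_model(path: str | Path | None = None, allow_overlap: bool = False) -> GeneModel:
    """Load a gene model from YAML; defaults to the shipped metabolic model."""
    if path is None:
        text = resources.files("panmet.data").joinpath("gene_model.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return GeneModel.from_dict(raw["categories"], allow_overlap=allow_overlap)


def load_emt_sets(path: str | Path | None = None) -> EmtGeneSets:
    """Load EMT marker gene sets from YAML; defaults to the shipped sets."""
    if path is None:
        text = resources.files("panmet.data").joinpath("emt_sets.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return EmtGeneSets.from_lists(raw["mesenchymal"], raw["epithelial"])


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer used for all run summaries."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
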