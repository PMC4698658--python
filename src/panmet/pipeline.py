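"""End-to-end pipeline: simulate (or load) a cohort and run every analysis.

``run_all`` produces a deterministic set of TSV tables plus a single
``run_summary.json``; given the same configuration and seed, two runs write
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import pandas as pd

from . import emt as emt_mod
from . import enrichment as enr
from . import signature as sig_mod
from . import survival as surv
from .datamodel import EmtGeneSets, GeneModel, OmicsCohort, validate_gene_sets
from .io import load_gene_model, write_json
from .simulate import SimulationConfig, emt_sets_for, simulate_to_dir


def _logrank_dict(lr: surv.LogrankResult) -> dict:
    return {
        "chi_square": lr.chi_square,
        "df": lr.df,
        "p_value": lr.p_value,
        "group_sizes": lr.group_sizes,
    }


def _curves_frame(curves: list[surv.KmCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, r, d, s in zip(c.times, c.at_risk, c.events, c.survival):
            rows.append((c.label, float(t), int(r), int(d), float(s)))
    return pd.DataFrame(rows, columns=["group", "time", "at_risk", "events", "survival"])


def run_all(
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int | None = None,
    gene_model: GeneModel | None = None,
    emt_sets: EmtGeneSets | None = None,
    table_mode: str = "observed-expected",
    rank_order: str = "significant_high",
    survival_mutation_genes: tuple[str, ...] = ("TP53", "STK11"),
    combined_pair: tuple[str, str] = ("TP53", "SCO2"),
) -> dict:
    """Simulate a cohort and run the full analysis suite into ``out_dir``."""
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_to_dir(config, out / "cohort")
    if emt_sets is None:
        emt_sets = emt_sets_for(config)
    if gene_model is None:
        gene_model = load_gene_model()
    return analyze_cohort(
        cohort,
        out,
        gene_model=gene_model,
        emt_sets=emt_sets,
        seed=config.seed,
        table_mode=table_mode,
        rank_order=rank_order,
        survival_mutation_genes=survival_mutation_genes,
        combined_pair=combined_pair,
    )


def analyze_cohort(
    cohort: OmicsCohort,
    out_dir: str | Path,
    gene_model: GeneModel,
    emt_sets: EmtGeneSets,
    seed: int = 0,
    table_mode: str = "observed-expected",
    rank_order: str = "significant_high",
    survival_mutation_genes: tuple[str, ...] = ("TP53", "STK11"),
    combined_pair: tuple[str, str] = ("TP53", "SCO2"),
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "table_mode": table_mode, "rank_order": rank_order,
                     "rounding_policy": enr.ROUNDING_POLICY, "tie_policy": "average ranks"}

    report = validate_gene_sets(cohort, gene_model, emt_sets)
    summary["gene_set_report"] = report

    # candidate genes for the screens: the gene-model genes present anywhere;
    # if the cohort carries none of them, fall back to every matrix gene that
    # is not an EMT marker.
    universe = set(cohort.gene_universe())
    marker = set(emt_sets.mesenchymal) | set(emt_sets.epithelial)
    candidates = [g for g in gene_model.all_genes() if g in universe]
    if len(candidates) < 2:
        candidates = [g for g in cohort.gene_universe() if g not in marker]
    summary["candidate_genes"] = candidates

    # ---- EMT score, class, group comparison, survival -------------------
    scores = emt_mod.compute_emt_score(cohort, emt_sets)
    tumor = cohort.tumor_mask()
    tumor_ids = list(tumor.index[tumor])
    labels, threshold = emt_mod.stratify_by_mean(scores.scores.loc[tumor_ids])
    emt_table = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "emt_score": scores.scores.loc[tumor_ids].to_numpy(),
            "emt_class": labels.to_numpy(),
        }
    )
    emt_table.to_csv(out / "emt_scores.tsv", sep="\t", index=False)
    emt_summary: dict = {
        "threshold": threshold,
        "n_scored": len(tumor_ids),
        "high_fraction": float((labels == "high").mean()),
        "mesenchymal_used": list(scores.mesenchymal_used),
        "epithelial_used": list(scores.epithelial_used),
    }
    stypes = cohort.clinical.set_index("sample_id")["sample_type"]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = emt_mod.compare_groups_anova(scores.scores, stypes)
        emt_summary["anova"] = {
            "f_statistic": anova.f_statistic,
            "p_value": anova.p_value,
            "group_sizes": anova.group_sizes,
            "tukey": anova.tukey.to_dict(orient="records"),
        }
    except ValueError as exc:
        emt_summary["anova"] = {"error": str(exc)}
    curves, lr = surv.survival_by_labels(cohort, labels.rename("emt_class"))
    _curves_frame(curves).to_csv(out / "km_emt_class.tsv", sep="\t", index=False)
    emt_summary["survival_by_emt_class"] = _logrank_dict(lr)
    summary["emt"] = emt_summary

    # ---- alteration enrichment screens ----------------------------------
    enrich: dict = {"basal_mutation_frequency": enr.basal_mutation_frequency(cohort.mutation)}
    for kind, fname in (
        ("mutation", "mutation_enrichment.tsv"),
        ("cna_gain", "cna_gain_enrichment.tsv"),
        ("cna_loss", "cna_loss_enrichment.tsv"),
    ):
        screen = enr.run_enrichment_screen(cohort, candidates, kind, table_mode=table_mode)
        screen.to_csv(out / fname, sep="\t", index=False)
        sig_rows = screen[screen["significant"]]
        enrich[kind] = {
            "n_tested": int(screen["testable"].sum()),
            "n_significant": int(len(sig_rows)),
            "significant_genes": sorted(sig_rows["gene"]),
        }
    summary["enrichment"] = enrich

    # ---- mutation burden strata and survival ----------------------------
    burden: dict = {}
    for cat, genes in gene_model.categories.items():
        present = [g for g in genes if g in cohort.mutation.index]
        if not present:
            continue
        strata = enr.mutation_burden_strata(cohort.mutation, present)
        entry: dict = {"strata_sizes": {k: int(v) for k, v in strata.value_counts().items()}}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, lr = surv.survival_by_labels(cohort, strata)
            entry["logrank"] = _logrank_dict(lr)
        except ValueError as exc:
            entry["logrank"] = {"error": str(exc)}
        burden[cat] = entry
    summary["mutation_burden"] = burden

    # ---- single-gene mutation survival ----------------------------------
    mut_surv: dict = {}
    for g in survival_mutation_genes:
        if g not in cohort.mutation.index:
            continue
        strat = surv.stratify_mutation(cohort, g)
        if strat.nunique() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, lr = surv.survival_by_labels(cohort, strat)
        mut_surv[g] = _logrank_dict(lr)
    summary["mutation_survival"] = mut_surv

    # ---- combined mutation x expression stratification ------------------
    mg, eg = combined_pair
    if mg in cohort.mutation.index and eg in cohort.expression.index:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expr_labels, meta = surv.stratify_expression(cohort, eg, method="mean")
            combined = surv.stratify_combined_mut_expr(cohort, mg, eg)
        entry = {"expression_split": meta,
                 "group_sizes": {k: int(v) for k, v in combined.value_counts().items()}}
        for name, lab in (("expression", expr_labels), ("combined", combined)):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, lr = surv.survival_by_labels(cohort, lab)
                entry[f"logrank_{name}"] = _logrank_dict(lr)
            except ValueError as exc:
                entry[f"logrank_{name}"] = {"error": str(exc)}
        summary["combined_stratification"] = {"mut_gene": mg, "expr_gene": eg, **entry}

    # ---- per-cancer Pearson association ---------------------------------
    assoc_frames = []
    clin = cohort.clinical
    tmask = clin["sample_type"].isin(["primary", "metastatic"])
    for ct in sorted(clin["cancer_type"].unique()):
        ids = list(clin.loc[tmask & (clin["cancer_type"] == ct), "sample_id"])
        if len(ids) < 3:
            continue
        assoc_frames.append(
            sig_mod.pearson_emt_association(
                cohort.expression[ids], scores.scores.loc[ids], candidates, cancer_type=ct
            )
        )
    assoc = pd.concat(assoc_frames, ignore_index=True) if assoc_frames else pd.DataFrame()
    assoc.to_csv(out / "emt_association.tsv", sep="\t", index=False)
    if len(assoc):
        sig_assoc = assoc[assoc["sign"] != "none"]
        summary["association"] = {
            "n_cancer_types": int(assoc["cancer_type"].nunique()),
            "n_significant": int(len(sig_assoc)),
            "significant_by_gene": {
                g: int(n) for g, n in sig_assoc.groupby("gene").size().items()
            },
        }

    # ---- logistic screens and rank-sum signature -------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_cancer = sig_mod.per_cancer_logistic_screens(cohort, scores, candidates)
    if per_cancer:
        pd.concat(per_cancer.values(), ignore_index=True).to_csv(
            out / "logistic_or.tsv", sep="\t", index=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig_res = sig_mod.rank_and_aggregate(per_cancer, rank_order=rank_order)
        sig_summary: dict = {
            "rank_order": sig_res.rank_order,
            "top_genes": list(sig_res.top_genes),
            "bottom_genes": list(sig_res.bottom_genes),
            "rank_sums": {g: float(v) for g, v in sig_res.rank_sum.sort_index().items()},
            "midpoint_imputed": sig_res.midpoint_imputed,
        }
        rank_out = sig_res.rank_matrix.copy()
        rank_out.insert(0, "gene", rank_out.index)
        rank_out.to_csv(out / "signature_ranks.tsv", sep="\t", index=False)
        for side in ("top", "bottom"):
            genes = getattr(sig_res, f"{side}_genes")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sig_mod.signature_cluster_and_survive(cohort, genes, seed=seed)
                _curves_frame(res["curves"]).to_csv(
                    out / f"km_signature_{side}.tsv", sep="\t", index=False
                )
                sig_summary[f"{side}_cluster"] = {
                    "genes": res["genes"],
                    "cluster_sizes": res["cluster_sizes"],
                    "cluster_mean_expression": res["cluster_mean_expression"],
                    "logrank": _logrank_dict(res["logrank"]),
                }
            except ValueError as exc:
                sig_summary[f"{side}_cluster"] = {"error": str(exc)}
        summary["signature"] = sig_summary

    write_json(summary, out / "run_summary.json")
    return summary
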