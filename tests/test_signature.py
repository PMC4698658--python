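"""Pearson association, logistic odds ratios and rank-sum signature selection."""

import numpy as np
import pandas as pd
import pytest

from panmet.emt import compute_emt_score, stratify_by_mean
from panmet.signature import (
    _SMALLEST_P,
    logistic_emt_or,
    pearson_emt_association,
    per_cancer_logistic_screens,
    rank_and_aggregate,
    signature_cluster_and_survive,
)
from panmet.simulate import SimulationConfig, emt_sets_for, generate_cohort

from oracles import logistic_irls, pearson_direct


def _expr(rows: dict, samples=None) -> pd.DataFrame:
    samples = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=samples).T


class TestPearsonAssociation:
    def test_self_correlation_is_one(self):
        y = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0], index=[f"s{i}" for i in range(5)])
        expr = _expr({"G": list(y)})
        df = pearson_emt_association(expr, y, ["G"])
        assert df.loc[0, "pearson_r"] == pytest.approx(1.0, abs=1e-12)

    def test_anti_correlation_is_minus_one(self):
        y = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0], index=[f"s{i}" for i in range(5)])
        expr = _expr({"G": list(-y)})
        df = pearson_emt_association(expr, y, ["G"])
        assert df.loc[0, "pearson_r"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(50)
        y = pd.Series(rng.standard_normal(50), index=[f"s{i}" for i in range(50)])
        df = pearson_emt_association(_expr({"G": list(x)}), y, ["G"])
        r, p = pearson_direct(x, y.to_numpy())
        assert df.loc[0, "pearson_r"] == pytest.approx(r, abs=1e-10)
        assert df.loc[0, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_constant_gene_flagged_untestable(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        rng = np.random.default_rng(0)
        df = pearson_emt_association(
            _expr({"C": [5.0] * 4, "G": list(rng.standard_normal(4))}), y, ["C", "G"]
        )
        row = df.set_index("gene").loc["C"]
        assert not row["testable"] and row["sign"] == "none"
        # Bonferroni family counts only the testable gene
        g = df.set_index("gene").loc["G"]
        assert g["p_adj"] == pytest.approx(min(1.0, g["p_raw"]), rel=1e-12)

    def test_bonferroni_within_cancer_type(self):
        rng = np.random.default_rng(1)
        y = pd.Series(rng.standard_normal(30), index=[f"s{i}" for i in range(30)])
        rows = {f"G{i}": list(rng.standard_normal(30)) for i in range(5)}
        df = pearson_emt_association(_expr(rows), y, list(rows))
        np.testing.assert_allclose(
            df["p_adj"], np.minimum(1.0, df["p_raw"] * 5), rtol=1e-12
        )

    def test_constant_emt_scores_fatal(self):
        y = pd.Series([2.0] * 5, index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="constant EMT"):
            pearson_emt_association(_expr({"G": [1, 2, 3, 4, 5]}), y, ["G"])


class TestLogisticOddsRatio:
    def test_no_information_gives_unit_odds_ratio(self):
        x = pd.Series([1.0, 1.0, 2.0, 2.0, 3.0, 3.0], index=[f"s{i}" for i in range(6)])
        y = pd.Series(["low", "high"] * 3, index=x.index)
        res = logistic_emt_or(x, y)
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)
        assert res.p_wald == pytest.approx(1.0, abs=1e-6)

    def test_recovers_generative_slope(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            x = rng.standard_normal(n)
            p = 1 / (1 + np.exp(-(0.2 + 1.0 * x)))
            y = np.where(rng.random(n) < p, "high", "low")
            res = logistic_emt_or(
                pd.Series(x, index=[f"s{i}" for i in range(n)]),
                pd.Series(y, index=[f"s{i}" for i in range(n)]),
            )
            hits += np.exp(1.0 - 0.15) <= res.odds_ratio <= np.exp(1.0 + 0.15)
        assert hits >= 19

    def test_matches_irls_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 150
            x = rng.standard_normal(n)
            p = 1 / (1 + np.exp(-(0.5 * x)))
            y = np.where(rng.random(n) < p, "high", "low")
            res = logistic_emt_or(
                pd.Series(x, index=range(n)), pd.Series(y, index=range(n))
            )
            beta = logistic_irls(x, (np.asarray(y) == "high").astype(float))[1]
            assert res.beta == pytest.approx(beta, abs=1e-6)

    def test_complete_separation_flagged(self):
        x = pd.Series(np.arange(20.0), index=range(20))
        y = pd.Series(["low"] * 10 + ["high"] * 10, index=range(20))
        res = logistic_emt_or(x, y)
        assert res.separation
        assert res.p_wald == _SMALLEST_P

    def test_single_class_is_error(self):
        x = pd.Series([1.0, 2.0, 3.0], index=range(3))
        with pytest.raises(ValueError, match="both EMT classes"):
            logistic_emt_or(x, pd.Series(["high"] * 3, index=range(3)))


class TestRankAggregation:
    def _table(self, ps: dict, ct: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"cancer_type": ct, "gene": list(ps), "p_wald": list(ps.values())}
        )

    def test_single_type_ranks_follow_printed_rule(self):
        per = {"BRCA": self._table({"A": 0.5, "B": 0.01, "C": 0.2}, "BRCA")}
        with pytest.warns(UserWarning, match="single cancer type"):
            res = rank_and_aggregate(per, n_top=1, n_bottom=1)
        assert res.rank_matrix.loc["A", "BRCA"] == 1  # largest p -> rank 1
        assert res.rank_matrix.loc["C", "BRCA"] == 2
        assert res.rank_matrix.loc["B", "BRCA"] == 3
        assert res.top_genes == ("B",)

    def test_identical_types_double_the_ranks(self):
        ps = {"A": 0.5, "B": 0.01, "C": 0.2}
        per = {"BRCA": self._table(ps, "BRCA"), "LUAD": self._table(ps, "LUAD")}
        res = rank_and_aggregate(per, n_top=1, n_bottom=1)
        single = {"A": 1.0, "C": 2.0, "B": 3.0}
        for g, r in single.items():
            assert res.rank_sum[g] == 2 * r

    def test_rank_invariance_under_p_rescaling(self):
        rng = np.random.default_rng(0)
        ps = {f"G{i}": float(p) for i, p in enumerate(rng.uniform(0.001, 1, 10))}
        scaled = {g: p * 0.1 for g, p in ps.items()}
        a = rank_and_aggregate(
            {"X": self._table(ps, "X"), "Y": self._table(ps, "Y")}
        )
        b = rank_and_aggregate(
            {"X": self._table(scaled, "X"), "Y": self._table(ps, "Y")}
        )
        pd.testing.assert_series_equal(a.rank_sum, b.rank_sum)

    def test_tied_pvalues_get_average_ranks(self):
        per = {
            "X": self._table({"A": 0.5, "B": 0.5, "C": 0.01}, "X"),
            "Y": self._table({"A": 0.9, "B": 0.5, "C": 0.01}, "Y"),
        }
        res = rank_and_aggregate(per)
        assert res.rank_matrix.loc["A", "X"] == 1.5
        assert res.rank_matrix.loc["B", "X"] == 1.5

    def test_missing_gene_receives_midpoint_rank(self):
        per = {
            "X": self._table({"A": 0.5, "B": 0.01, "C": 0.2}, "X"),
            "Y": self._table({"A": 0.5, "B": 0.01}, "Y"),
        }
        res = rank_and_aggregate(per)
        assert res.rank_matrix.loc["C", "Y"] == 1.5  # (n+1)/2 with n=2
        assert res.midpoint_imputed == {"Y": ["C"]}

    def test_rank_order_switch_flips_selection(self):
        per = {
            "X": self._table({"A": 0.9, "B": 0.001, "C": 0.3, "D": 0.5}, "X"),
            "Y": self._table({"A": 0.8, "B": 0.002, "C": 0.4, "D": 0.6}, "Y"),
        }
        hi = rank_and_aggregate(per, n_top=1, n_bottom=1)
        lo = rank_and_aggregate(per, n_top=1, n_bottom=1, rank_order="significant_low")
        assert hi.top_genes == lo.bottom_genes == ("B",)
        assert hi.bottom_genes == lo.top_genes == ("A",)

    def test_top_and_bottom_disjoint_and_sized(self):
        rng = np.random.default_rng(5)
        ps = {f"G{i}": float(p) for i, p in enumerate(rng.uniform(0, 1, 7))}
        res = rank_and_aggregate(
            {"X": self._table(ps, "X"), "Y": self._table(ps, "Y")}
        )
        assert len(res.top_genes) == len(res.bottom_genes) == min(5, 7 // 2)
        assert not set(res.top_genes) & set(res.bottom_genes)


class TestEndToEndSignature:
    def test_planted_genes_dominate_ranks_and_clusters_predict_survival(self):
        sig = ("SIGA", "SIGB", "SIGC", "SIGD", "SIGE")
        cfg = SimulationConfig(
            seed=77,
            n_cancer_types=3,
            samples_per_type=150,
            n_genes=30,
            emt_assoc_genes={g: 0.7 for g in sig},
            signature_genes=sig,
            signature_fraction=0.5,
            survival_effects={"signature_cluster": 0.7},
            censoring_rate=3.5e-4,
        )
        cohort = generate_cohort(cfg)
        emt = compute_emt_score(cohort, emt_sets_for(cfg))
        genes = [g for g in cohort.gene_universe()
                 if g not in cfg.mesenchymal_genes + cfg.epithelial_genes]
        per = per_cancer_logistic_screens(cohort, emt, genes)
        res = rank_and_aggregate(per)
        assert set(res.top_genes) == set(sig)
        out = signature_cluster_and_survive(cohort, res.top_genes, seed=1)
        assert out["logrank"].p_value < 0.01
        # the high-expression cluster is the one carrying the planted hazard
        assert (
            out["cluster_mean_expression"]["cluster_high"]
            > out["cluster_mean_expression"]["cluster_low"]
        )
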