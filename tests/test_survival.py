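"""Kaplan-Meier estimation, log-rank testing and the sample stratifiers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from panmet.simulate import SimulationConfig, generate_cohort
from panmet.survival import (
    km_estimate,
    kmeans_stratify,
    logrank_test,
    stratify_combined_mut_expr,
    stratify_expression,
    stratify_mutation,
    survival_by_labels,
)

from conftest import make_cohort
from oracles import km_product_limit, logrank_chi_square_oe


class TestKaplanMeier:
    def test_no_censoring_steps_through_empirical_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_censoring_reduces_risk_set_without_step(self):
        # (1, event), (2, censored), (3, event): S(1)=2/3, S(3)=0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_array_equal(curve.times, [1.0, 3.0])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0], atol=1e-12)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        assert curve.times.size == 0  # no steps: S identically 1
        assert curve.n == 3

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 60)
        curve = km_estimate(t, np.ones(60, dtype=int))
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(1 - (t <= time).mean(), abs=1e-12)

    def test_matches_hand_product_limit_on_random_data(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(5, 40), 1)
        e = rng.integers(0, 2, 40)
        if e.sum() == 0:
            e[0] = 1
        curve = km_estimate(t, e)
        expected = km_product_limit(t, e)
        assert [(float(x), pytest.approx(s, abs=1e-12)) for x, s in zip(curve.times, curve.survival)] == expected

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero_chi_square(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a"] * 3 + ["b"] * 3
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)
        assert res.df == 1

    def test_matches_oe_variance_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            t = np.round(rng.exponential(10, n), 0) + 1
            e = rng.integers(0, 2, n)
            g = np.where(rng.random(n) < 0.5, "a", "b")
            if len(set(g)) < 2 or e.sum() == 0:
                continue
            res = logrank_test(t, e, g)
            assert res.chi_square == pytest.approx(
                logrank_chi_square_oe(t, e, g), abs=1e-8
            )

    def test_power_against_planted_hazard_ratio(self):
        detected = 0
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed,
                n_cancer_types=1,
                samples_per_type=1000,
                n_genes=15,
                mutation_rates={"MG": 0.5},
                survival_effects={"mutation:MG": 0.7},
                censoring_rate=3.5e-4,
            )
            cohort = generate_cohort(cfg)
            labels = stratify_mutation(cohort, "MG")
            _, res = survival_by_labels(cohort, labels)
            detected += res.p_value < 0.001
        assert detected == 5

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestStratifiers:
    def test_mutation_stratifier_maps_indicator(self, tiny_cohort):
        labels = stratify_mutation(tiny_cohort, "TP53")
        expected = [
            "mutation" if v == 1 else "no_mutation"
            for v in tiny_cohort.mutation.loc["TP53"]
        ]
        assert list(labels) == expected

    def test_mutation_stratifier_missing_gene(self, tiny_cohort):
        with pytest.raises(KeyError):
            stratify_mutation(tiny_cohort, "NOPE")

    def test_expression_mean_split_rule(self, tiny_cohort):
        expr = tiny_cohort.expression.copy()
        expr.loc["TP53"] = [1.0, 2.0, 3.0, 2.0]
        cohort = make_cohort(expr, tiny_cohort.mutation, tiny_cohort.cna)
        labels, meta = stratify_expression(cohort, "TP53", method="mean")
        assert list(labels) == ["low", "high", "high", "high"]
        assert meta["threshold"] == 2.0

    def test_mean_and_median_agree_on_symmetric_data(self, tiny_cohort):
        expr = tiny_cohort.expression.copy()
        expr.loc["TP53"] = [1.0, 2.0, 4.0, 5.0]  # symmetric about 3
        cohort = make_cohort(expr, tiny_cohort.mutation, tiny_cohort.cna)
        mean_labels, _ = stratify_expression(cohort, "TP53", method="mean")
        med_labels, _ = stratify_expression(cohort, "TP53", method="median")
        assert list(mean_labels) == list(med_labels)

    def test_combined_stratifier_matches_truth_table(self):
        rng = np.random.default_rng(11)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(
            rng.standard_normal((2, n)), index=["SCO2", "X"], columns=samples
        )
        mut = pd.DataFrame(
            rng.integers(0, 2, size=(2, n)), index=["TP53", "X"], columns=samples
        )
        cohort = make_cohort(expr, mut)
        labels = stratify_combined_mut_expr(cohort, "TP53", "SCO2")
        threshold = expr.loc["SCO2"].mean()
        for s in samples:
            m = mut.loc["TP53", s] == 1
            h = expr.loc["SCO2", s] >= threshold
            expected = {  # exhaustive 2x2 state mapping
                (False, False): "wt_low",
                (False, True): "mixed",
                (True, False): "mixed",
                (True, True): "mut_high",
            }[(m, h)]
            assert labels[s] == expected


class TestKmeansStratify:
    def _matrix(self, values, n_genes=3):
        samples = [f"s{i}" for i in range(len(values))]
        return pd.DataFrame(
            np.tile(values, (n_genes, 1)), index=[f"G{i}" for i in range(n_genes)],
            columns=samples,
        )

    def test_separated_masses_split_deterministically(self):
        mat = self._matrix([0.0] * 5 + [10.0] * 5)
        labels = kmeans_stratify(mat, seed=0)
        assert list(labels[:5]) == ["cluster_low"] * 5
        assert list(labels[5:]) == ["cluster_high"] * 5

    def test_negating_matrix_swaps_cluster_labels(self):
        mat = self._matrix([0.0] * 5 + [10.0] * 5)
        labels = kmeans_stratify(mat, seed=0)
        flipped = kmeans_stratify(-mat, seed=0)
        swap = {"cluster_low": "cluster_high", "cluster_high": "cluster_low"}
        assert list(flipped) == [swap[v] for v in labels]

    def test_recovers_planted_gaussian_mixture(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            truth = rng.random(400) < 0.5
            X = rng.standard_normal((4, 400)) + 4.0 * truth  # 4-sigma separation
            mat = pd.DataFrame(X, columns=[f"s{i}" for i in range(400)])
            labels = kmeans_stratify(mat, seed=seed)
            ari = adjusted_rand_score(truth, (labels == "cluster_high").to_numpy())
            hits += ari >= 0.95
        assert hits == 5

    def test_identical_samples_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_stratify(self._matrix([1.0] * 6))

    def test_duplicate_samples_co_cluster(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.standard_normal(10), [2.5, 2.5]])
        labels = kmeans_stratify(self._matrix(vals), seed=1)
        assert labels.iloc[-1] == labels.iloc[-2]


class TestSurvivalByLabels:
    def test_missing_survival_dropped_with_warning(self, tiny_cohort):
        clin = tiny_cohort.clinical.copy()
        clin.loc[0, "os_days"] = np.nan
        cohort = make_cohort(
            tiny_cohort.expression, tiny_cohort.mutation, tiny_cohort.cna
        )
        cohort.clinical = clin
        labels = pd.Series(
            ["a", "a", "b", "b"], index=clin["sample_id"], name="grp"
        )
        with pytest.warns(UserWarning, match="missing survival"):
            curves, res = survival_by_labels(cohort, labels)
        assert sum(res.group_sizes.values()) == 3
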