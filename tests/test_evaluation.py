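"""ROC machinery against brute-force pair counting and analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serostack.evaluation import (
    analytic_ppv,
    auc_ci_stratified_bootstrap,
    compare_roc_bootstrap,
    metrics_at_specificity,
    metrics_at_threshold,
    pairwise_kappa,
    prevalence_rescan,
    roc_auc,
)


def brute_force_auc(scores, y):
    scores = np.asarray(scores, dtype=float)
    case = scores[np.asarray(y) == 1]
    ctrl = scores[np.asarray(y) == 0]
    total = 0.0
    for s in case:
        total += (s > ctrl).sum() + 0.5 * (s == ctrl).sum()
    return total / (len(case) * len(ctrl))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_enumerated_four_pair_example(self):
        # pairs: .9>.85, .9>.1, .8<.85, .8>.1 -> 3/4
        assert roc_auc([0.9, 0.8, 0.85, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 30, size=2)
        scores = np.round(rng.random(n1 + n0), 2)  # rounding induces ties
        y = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
        assert roc_auc(scores, y) == pytest.approx(brute_force_auc(scores, y))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        y = np.concatenate([np.ones(15, int), np.zeros(25, int)])
        a = roc_auc(scores, y)
        assert roc_auc(np.exp(3 * scores), y) == pytest.approx(a)
        assert roc_auc(np.log(scores + 1e-9), y) == pytest.approx(a)


class TestBootstrapCI:
    def test_perfect_separation_collapses_to_one(self):
        y = np.concatenate([np.ones(20, int), np.zeros(20, int)])
        scores = np.concatenate([np.ones(20), np.zeros(20)])
        assert auc_ci_stratified_bootstrap(scores, y, n_boot=200, seed=1) == (1.0, 1.0)

    def test_null_interval_contains_half(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([np.ones(100, int), np.zeros(100, int)])
        lo, hi = auc_ci_stratified_bootstrap(rng.random(200), y, n_boot=500, seed=2)
        assert lo <= 0.5 <= hi

    def test_reproducible_by_seed(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([np.ones(30, int), np.zeros(30, int)])
        s = rng.random(60)
        assert auc_ci_stratified_bootstrap(s, y, 300, seed=9) == \
            auc_ci_stratified_bootstrap(s, y, 300, seed=9)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            auc_ci_stratified_bootstrap([1, 0], [1, 0], n_boot=10)


class TestCompareRoc:
    def test_identical_scores_give_p_one(self):
        y = np.concatenate([np.ones(20, int), np.zeros(20, int)])
        s = np.linspace(0, 1, 40)
        assert compare_roc_bootstrap(s, s, y, n_boot=200, seed=0) == 1.0

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(13)
        y = np.concatenate([np.ones(30, int), np.zeros(30, int)])
        a, b = rng.random(60), rng.random(60)
        assert compare_roc_bootstrap(a, b, y, 400, seed=3) == pytest.approx(
            compare_roc_bootstrap(b, a, y, 400, seed=3)
        )

    def test_detects_strong_vs_null_predictor(self):
        rng = np.random.default_rng(17)
        n = 250
        y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
        strong = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
        null = rng.random(2 * n)
        assert compare_roc_bootstrap(strong, null, y, 500, seed=4) < 0.01


class TestMetricsAtSpecificity:
    def test_perfect_separation(self):
        y = np.concatenate([np.ones(10, int), np.zeros(10, int)])
        s = np.concatenate([np.full(10, 0.9), np.full(10, 0.1)])
        thr, sens, ppv, npv, mcc = metrics_at_specificity(s, y, 0.9)
        assert (sens, ppv, npv, mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_anti_predictor_has_zero_sensitivity(self):
        y = np.concatenate([np.ones(10, int), np.zeros(10, int)])
        s = np.concatenate([np.zeros(10), np.ones(10)])
        _, sens, *_ = metrics_at_specificity(s, y, 0.9)
        assert sens == 0.0

    def test_hand_enumerated_thirty_point_grid(self):
        ctrl = np.arange(1, 21, dtype=float)  # 20 controls scored 1..20
        case = np.arange(15, 25, dtype=float)  # 10 cases scored 15..24
        s = np.concatenate([case, ctrl])
        y = np.concatenate([np.ones(10, int), np.zeros(20, int)])
        thr, sens, ppv, npv, mcc = metrics_at_specificity(s, y, 0.9)
        assert thr >= 18
        assert sens == pytest.approx(0.6)  # cases 19..24 called positive
        tp, fp = 6, 2
        assert ppv == pytest.approx(tp / (tp + fp))

    def test_lowering_target_never_lowers_sensitivity(self):
        rng = np.random.default_rng(23)
        y = np.concatenate([np.ones(40, int), np.zeros(60, int)])
        s = rng.random(100)
        sens = [
            metrics_at_specificity(s, y, t)[1] for t in (0.95, 0.9, 0.8, 0.5)
        ]
        assert all(a <= b for a, b in zip(sens, sens[1:]))

    def test_controls_sharing_max_score_give_zero_sensitivity(self):
        # controls exactly at the threshold count as negative, so the cutoff
        # lands on the shared control score and no case clears it
        y = np.array([1, 1, 0, 0])
        s = np.array([0.2, 0.3, 0.5, 0.5])
        thr, sens, *_ = metrics_at_specificity(s, y, 0.9)
        assert thr == 0.5 and sens == 0.0

    def test_fixed_threshold_mode(self):
        y = np.concatenate([np.ones(5, int), np.zeros(5, int)])
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.5, 0.3, 0.2, 0.1])
        sens, ppv, npv, mcc = metrics_at_threshold(s, y, 0.55)
        assert sens == pytest.approx(3 / 5)
        assert ppv == pytest.approx(3 / 4)


class TestPrevalenceRescan:
    def _scores(self):
        rng = np.random.default_rng(31)
        n1, n0 = 80, 120
        y = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
        s = np.concatenate([rng.normal(1.5, 1, n1), rng.normal(0, 1, n0)])
        return s, y

    def test_low_prevalence_limits(self):
        s, y = self._scores()
        out = prevalence_rescan(s, y, [0.02], n_rep=40, seed=1)
        assert out["ppv"].median() < 0.4
        assert out["npv"].median() > 0.95

    def test_empirical_ppv_matches_analytic_formula(self):
        s, y = self._scores()
        out = prevalence_rescan(s, y, [0.1], n_rep=200, seed=2)
        expected = out["ppv_analytic"].iloc[0]
        assert out["ppv"].mean() == pytest.approx(expected, abs=0.12)

    def test_unachievable_prevalence_rejected(self):
        s, y = self._scores()
        with pytest.raises(ValueError):
            prevalence_rescan(s, y, [1.5], n_rep=5)

    def test_analytic_ppv_closed_form(self):
        assert analytic_ppv(1.0, 1.0, 0.3) == 1.0
        assert analytic_ppv(0.8, 0.9, 0.1) == pytest.approx(
            0.8 * 0.1 / (0.8 * 0.1 + 0.1 * 0.9)
        )


class TestPairwiseKappa:
    def test_duplicate_columns_have_kappa_one(self):
        rng = np.random.default_rng(41)
        y = np.concatenate([np.ones(50, int), np.zeros(50, int)])
        col = rng.random(100)
        P = pd.DataFrame({"a": col, "b": col})
        out = pairwise_kappa(P, y)
        assert out.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_have_small_kappa(self):
        rng = np.random.default_rng(43)
        y = np.concatenate([np.ones(500, int), np.zeros(500, int)])
        P = pd.DataFrame(rng.random((1000, 3)), columns=list("abc"))
        out = pairwise_kappa(P, y)
        off = out.values[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_complementary_predictions_negative(self):
        rng = np.random.default_rng(47)
        y = np.concatenate([np.ones(100, int), np.zeros(100, int)])
        col = rng.random(200)
        P = pd.DataFrame({"a": col, "b": 1 - col})
        out = pairwise_kappa(P, y)
        assert out.loc["a", "b"] < 0

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            pairwise_kappa(pd.DataFrame({"a": [0.1, 0.9]}), [0, 1])
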