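"""Meta-learners (BMA, pooling, AVNNET) and the three architectures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from serostack.cohort import assign_time_groups, stratified_split
from serostack.evaluation import roc_auc
from serostack.learners import CVPlan
from serostack.simulate import simulate_cohort
from serostack.stacking import (
    AVNNetStack,
    build_jtg2l,
    build_stg2l,
    build_stg3l,
    fit_bma_stack,
    fit_pooling_stack,
    fit_stack_model,
    predict,
    train_base_layer,
)

from conftest import persistent_effects, small_config

FAST3 = ("glmnet", "xgboost", "naive_bayes")


class TestPoolingStacks:
    def test_row_arithmetic(self):
        P = pd.DataFrame({"a": [0.2], "b": [0.8]})
        assert fit_pooling_stack(P, "mean").predict(P)[0] == pytest.approx(0.5)
        assert fit_pooling_stack(P, "geomean").predict(P)[0] == pytest.approx(0.4)
        assert fit_pooling_stack(P, "max").predict(P)[0] == pytest.approx(0.8)

    def test_identical_columns_reproduce_the_column(self):
        col = np.array([0.1, 0.5, 0.9])
        P = pd.DataFrame({"a": col, "b": col, "c": col})
        for kind in ("mean", "geomean", "max"):
            np.testing.assert_allclose(fit_pooling_stack(P, kind).predict(P), col)

    @given(arrays(float, (20, 6), elements=st.floats(1e-6, 1 - 1e-6)))
    @settings(max_examples=50, deadline=None)
    def test_geomean_mean_max_ordering(self, mat):
        P = pd.DataFrame(mat, columns=list("abcdef"))
        g = fit_pooling_stack(P, "geomean").predict(P)
        m = fit_pooling_stack(P, "mean").predict(P)
        x = fit_pooling_stack(P, "max").predict(P)
        assert np.all(g <= m + 1e-12) and np.all(m <= x + 1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        P = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"))
        stack = fit_pooling_stack(P, "mean")
        np.testing.assert_allclose(
            stack.predict(P), stack.predict(P[["d", "b", "a", "c"]])
        )


class TestBMAStack:
    def _data(self, n=400, informative=True, n_noise=9, seed=5):
        rng = np.random.default_rng(seed)
        y = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
        cols = {}
        if informative:
            signal = np.clip(0.5 + 0.35 * (2 * y - 1) + 0.15 * rng.standard_normal(n),
                             0.01, 0.99)
            cols["signal"] = signal
        for i in range(n_noise):
            cols[f"noise{i}"] = rng.random(n)
        return pd.DataFrame(cols), y

    def test_single_column_reduces_to_one_logistic(self):
        P, y = self._data(n_noise=0)
        stack = fit_bma_stack(P, y)
        assert len(stack.models_) == 1
        assert stack.weights_[0] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_are_positive(self):
        P, y = self._data()
        stack = fit_bma_stack(P, y, max_subset=2)
        assert stack.weights_.sum() == pytest.approx(1.0)
        assert (stack.weights_ > 0).all()

    def test_duplicate_columns_get_symmetric_weights(self):
        P, y = self._data(n_noise=0)
        P = pd.DataFrame({"a": P["signal"], "b": P["signal"]})
        stack = fit_bma_stack(P, y, max_subset=1)
        by_col = {tuple(s): w for (s, _i, _m), w in zip(stack.models_, stack.weights_)}
        assert by_col[("a",)] == pytest.approx(by_col[("b",)], rel=1e-6)

    def test_posterior_mass_concentrates_on_informative_column(self):
        P, y = self._data(n=1000, seed=7)
        stack = fit_bma_stack(P, y, max_subset=3)
        assert stack.column_weight("signal") >= 0.9

    def test_schema_alignment_by_name(self):
        P, y = self._data()
        stack = fit_bma_stack(P, y, max_subset=2)
        shuffled = P[list(reversed(P.columns))]
        np.testing.assert_allclose(stack.predict(P), stack.predict(shuffled))

    def test_wide_matrix_screens_columns(self):
        rng = np.random.default_rng(11)
        y = np.concatenate([np.ones(100, int), np.zeros(100, int)])
        P = pd.DataFrame(rng.random((200, 20)),
                         columns=[f"c{i}" for i in range(20)])
        stack = fit_bma_stack(P, y, max_subset=2)
        assert stack.weights_.sum() == pytest.approx(1.0)

    def test_probabilities_outside_unit_interval_rejected(self):
        P = pd.DataFrame({"a": [0.5, 1.2]})
        with pytest.raises(ValueError):
            fit_bma_stack(P, np.array([0, 1]))


class TestAVNNet:
    def test_committee_predicts_probabilities(self):
        rng = np.random.default_rng(13)
        y = np.concatenate([np.ones(60, int), np.zeros(60, int)])
        P = pd.DataFrame({
            "a": np.clip(0.5 + 0.3 * (2 * y - 1) + 0.1 * rng.standard_normal(120), 0, 1),
            "b": rng.random(120),
        })
        stack = AVNNetStack(n_nets=3, seed=0).fit(P, y)
        p = stack.predict(P)
        assert np.all((p >= 0) & (p <= 1))
        assert roc_auc(p, y) > 0.8


@pytest.fixture(scope="module")
def grouped_split(fast_spaces):
    cfg = small_config(n_cases=90, n_controls=140, n_markers=10,
                       effects=persistent_effects(4, 2.0), seed=71)
    cohort = assign_time_groups(simulate_cohort(cfg))
    part = stratified_split(cohort, seed=72)
    train = cohort.subset((part == "train").to_numpy())
    test = cohort.subset((part == "test").to_numpy())
    return cohort, train, test


class TestArchitectures:
    plan = CVPlan(n_folds=4, n_repeats=1, seed=5)

    def test_jtg2l_has_one_column_per_family(self, grouped_split, fast_spaces):
        _, train, test = grouped_split
        panel = train.marker_cols[:6] + ["age", "diabetes"]
        model = build_jtg2l(train, "0-4+", panel, "bma", plan=self.plan,
                            n_search=1, seed=1, spaces=fast_spaces,
                            families=FAST3, max_subset=2)
        assert len(model.base) == len(FAST3)
        scores = predict(model, test)
        assert len(scores) == len(test.df)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_stg_layer_has_families_times_groups_columns(self, grouped_split,
                                                         fast_spaces):
        _, train, _ = grouped_split
        panel = train.marker_cols[:6] + ["age"]
        layer = train_base_layer(train, "stg", panel, plan=self.plan,
                                 n_search=1, families=FAST3, seed=2,
                                 spaces=fast_spaces)
        assert layer.P.shape[1] == len(FAST3) * len(layer.groups)

    def test_stg3l_intermediate_matrix_has_one_column_per_group(
            self, grouped_split, fast_spaces):
        _, train, test = grouped_split
        panel = train.marker_cols[:6] + ["age"]
        model = build_stg3l(train, panel, "mean", plan=self.plan, n_search=1,
                            families=FAST3, seed=3, spaces=fast_spaces,
                            max_subset=2)
        assert set(model.group_stacks) == set(
            g for g in model.scheme.single_names
            if (train.df["time_group"] == g).any()
        )
        scores = predict(model, test)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_avnnet_only_for_stg2l(self, grouped_split, fast_spaces):
        _, train, _ = grouped_split
        panel = train.marker_cols[:4]
        with pytest.raises(ValueError, match="STG2L"):
            build_jtg2l(train, "0-4+", panel, "avnnet", plan=self.plan,
                        n_search=1, families=FAST3, spaces=fast_spaces)

    def test_prediction_invariant_to_test_column_order(self, grouped_split,
                                                       fast_spaces):
        _, train, test = grouped_split
        panel = train.marker_cols[:5] + ["age"]
        model = build_jtg2l(train, "0-4+", panel, "mean", plan=self.plan,
                            n_search=1, seed=4, families=FAST3,
                            spaces=fast_spaces)
        shuffled = test.subset(np.ones(len(test.df), dtype=bool))
        shuffled.df = shuffled.df[list(reversed(shuffled.df.columns))]
        np.testing.assert_allclose(predict(model, test), predict(model, shuffled))

    def test_single_row_prediction(self, grouped_split, fast_spaces):
        _, train, test = grouped_split
        panel = train.marker_cols[:5]
        model = build_jtg2l(train, "0-4+", panel, "mean", plan=self.plan,
                            n_search=1, seed=4, families=FAST3,
                            spaces=fast_spaces)
        one = test.subset(test.df.index == test.df.index[0])
        assert predict(model, one).shape == (1,)

    def test_end_to_end_determinism(self, grouped_split, fast_spaces):
        _, train, test = grouped_split
        panel = train.marker_cols[:5] + ["age"]
        runs = [
            predict(
                build_jtg2l(train, "0-4+", panel, "bma", plan=self.plan,
                            n_search=2, seed=9, families=FAST3,
                            spaces=fast_spaces, max_subset=2),
                test,
            )
            for _ in range(2)
        ]
        np.testing.assert_allclose(runs[0], runs[1])

    def test_cross_time_group_matrix_structure(self, grouped_split, fast_spaces):
        """Identical models in every row give identical rows, and each cell
        evaluates the row's model on the column's joined test group."""
        from serostack.evaluation import cross_time_group_matrix, roc_auc as _auc

        _, train, test = grouped_split
        panel = train.marker_cols[:5] + ["age"]
        model = build_jtg2l(train, "0-4+", panel, "mean", plan=self.plan,
                            n_search=1, seed=8, families=FAST3,
                            spaces=fast_spaces)
        groups = ["0-2", "0-4+"]
        mat = cross_time_group_matrix({g: model for g in groups}, test,
                                      joined_groups=groups, n_boot=200, seed=1)
        for h in groups:
            reports = [mat.loc[g, h] for g in groups]
            assert reports[0].auc == pytest.approx(reports[1].auc)
            sub = test.time_group_subset(h)
            direct = _auc(predict(model, sub), sub.status.to_numpy())
            assert reports[0].auc == pytest.approx(direct)
            assert reports[0].n_controls == test.n_controls  # controls shared

    def test_bma_stack_tracks_best_base_learner(self, grouped_split, fast_spaces):
        """The stacked ensemble's out-of-fold AUC is not much below the best
        single family's (the point of stacking)."""
        _, train, test = grouped_split
        panel = train.marker_cols[:6] + ["age", "diabetes"]
        layer = train_base_layer(train, "jtg2l", panel, "0-4+", plan=self.plan,
                                 n_search=1, families=FAST3, seed=6,
                                 spaces=fast_spaces)
        model = fit_stack_model(layer, "jtg2l", "bma", max_subset=2)
        stack_auc = roc_auc(model.stack.predict(layer.P), layer.y)
        best_base = max(roc_auc(layer.P[c], layer.y) for c in layer.P.columns)
        assert stack_auc > best_base - 0.02
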