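"""Stacking-layer tests: fold plans, segmentation, out-of-fold honesty,
super-learner variants, weight normalization and group screening."""

import numpy as np
import pandas as pd
import pytest

from nsstack.evaluation import auc
from nsstack.stacking import (
    GroupStructure,
    LassoLearner,
    cv_base_predictions,
    fit_base_lasso,
    fit_super,
    make_folds,
    normalize_weights,
    refit_and_stack,
    screen_groups,
    segment,
)


class TestMakeFolds:
    def test_exact_division(self):
        y = np.tile([0.0, 1.0], 5)
        plan = make_folds(y, K=5, seed=0)
        sizes = np.bincount(plan.assignment)[1:]
        assert list(sizes) == [2] * 5

    def test_stratification_balances_events(self):
        y = np.array([1.0] * 4 + [0.0] * 12)
        plan = make_folds(y, K=4, seed=1, stratified=True)
        for k in range(1, 5):
            assert np.sum(y[plan.assignment == k]) == 1

    def test_same_seed_same_assignment(self):
        y = np.tile([0.0, 1.0], 20)
        a = make_folds(y, K=5, seed=7).assignment
        b = make_folds(y, K=5, seed=7).assignment
        np.testing.assert_array_equal(a, b)
        c = make_folds(y, K=5, seed=8).assignment
        assert not np.array_equal(a, c)

    def test_mutually_exclusive_exhaustive_nearly_equal(self):
        y = np.tile([0.0, 1.0, 1.0], 11)  # N=33
        plan = make_folds(y, K=5, seed=3)
        assert set(plan.assignment) == {1, 2, 3, 4, 5}
        sizes = np.bincount(plan.assignment)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_events_for_stratification_is_an_error(self):
        y = np.array([1.0] + [0.0] * 9)
        with pytest.raises(ValueError):
            make_folds(y, K=5, seed=0, stratified=True)

    def test_unstratified_zero_event_fold_warns(self):
        y = np.array([1.0] + [0.0] * 9)
        with pytest.warns(RuntimeWarning):
            make_folds(y, K=5, seed=0, stratified=False)


class TestSegment:
    X = pd.DataFrame(np.arange(12.0).reshape(3, 4),
                     columns=["a", "b", "c", "d"])

    def test_single_group_of_all_features_is_identity(self):
        sub = segment(self.X, GroupStructure({"all": ["a", "b", "c", "d"]}))
        np.testing.assert_array_equal(sub["all"], self.X.to_numpy())

    def test_overlapping_feature_duplicated(self):
        sub = segment(self.X, GroupStructure({"g1": ["a", "b"], "g2": ["b", "c"]}))
        np.testing.assert_array_equal(sub["g1"][:, 1], sub["g2"][:, 0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupStructure({"g": []})

    def test_unknown_feature_named_in_error(self):
        with pytest.raises(KeyError, match="zzz"):
            segment(self.X, GroupStructure({"g": ["a", "zzz"]}))


class TestBaseLasso:
    def test_perfectly_predictive_column_selected(self, rng):
        n = 120
        y = np.tile([0.0, 1.0], n // 2)
        Xg = rng.normal(size=(n, 5))
        Xg[:, 2] = y * 2 - 1 + rng.normal(scale=0.1, size=n)
        sub = fit_base_lasso(Xg, y, seed=0, group_id="g")
        assert sub.coefficients[2] != 0.0

    def test_pure_noise_mostly_zeroed(self):
        rng = np.random.default_rng(42)
        n = 200
        y = np.tile([0.0, 1.0], n // 2)
        Xg = rng.normal(size=(n, 20))
        sub = fit_base_lasso(Xg, y, seed=0)
        assert np.sum(sub.coefficients == 0.0) >= 15

    def test_deterministic_given_seed(self, rng):
        n = 80
        y = np.tile([0.0, 1.0], n // 2)
        Xg = rng.normal(size=(n, 6))
        a = fit_base_lasso(Xg, y, seed=3)
        b = fit_base_lasso(Xg, y, seed=3)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_too_few_events_gives_intercept_only_with_warning(self, rng):
        Xg = rng.normal(size=(20, 4))
        y = np.zeros(20)
        y[0] = 1.0
        with pytest.warns(RuntimeWarning):
            sub = fit_base_lasso(Xg, y, seed=0)
        assert np.all(sub.coefficients == 0.0)


class _TrainMeanLearner:
    """Oracle learner predicting the training-set outcome mean."""

    name = "train-mean"

    def fit(self, Xg, y, seed=0):
        mean = float(np.mean(y))

        class F:
            def predict(self, X):
                return np.full(X.shape[0], mean)

        return F()


class _RecordingLearner:
    """Instrumented learner that records the rows it was trained on."""

    name = "recorder"

    def __init__(self):
        self.seen = []

    def fit(self, Xg, y, seed=0):
        self.seen.append(Xg.copy())

        class F:
            def __init__(self, train_rows):
                self.train_rows = train_rows

            def predict(self, X):
                return np.full(X.shape[0], 0.5)

        return F(Xg)


class TestCvBasePredictions:
    def _data(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = np.tile([0.0, 1.0], 10)
        groups = GroupStructure({"g1": ["a", "b"], "g2": ["c", "d"]})
        return X, y, groups

    def test_training_mean_oracle_forced_by_contract(self):
        X, y, groups = self._data()
        plan = make_folds(y, K=5, seed=1)
        Z = cv_base_predictions(X, y, groups, _TrainMeanLearner(), plan)
        assert Z.shape == (20, 2)
        for k in range(1, 6):
            in_fold = plan.assignment == k
            expected = y[~in_fold].mean()
            np.testing.assert_allclose(Z[in_fold, :], expected)

    def test_learner_never_sees_its_own_validation_rows(self):
        X, y, groups = self._data()
        plan = make_folds(y, K=4, seed=2)
        rec = _RecordingLearner()
        cv_base_predictions(X, y, groups, rec, plan)
        Xv = X.to_numpy()
        fits_per_group = plan.K
        for j, name in enumerate(groups.names):
            sub = segment(X, groups)[name]
            for k, (tr, va) in enumerate(plan.split()):
                seen = rec.seen[j * fits_per_group + k]
                np.testing.assert_array_equal(seen, sub[tr])
                # validation rows are disjoint from the training rows shown
                assert seen.shape[0] + len(va) == Xv.shape[0]


class TestFitSuper:
    def _informative_Z(self, seed=12, n=200, J=5):
        rng = np.random.default_rng(seed)
        prob = rng.uniform(0.1, 0.9, size=n)
        Z = rng.uniform(0.3, 0.7, size=(n, J))
        Z[:, 0] = prob
        y = (rng.random(n) < prob).astype(float)
        return Z, y

    def test_nsslasso_puts_dominant_weight_on_true_probability_column(self):
        Z, y = self._informative_Z()
        w0, w, info = fit_super(Z, y, "nsslasso", seed=0)
        assert np.all(w >= 0)
        assert w[0] == w.max() > 0
        assert w[0] >= 0.9 * w.sum()

    def test_lbfgs_matches_unconstrained_mle_when_interior(self):
        """With J=2 and a non-negative unconstrained optimum, the bounded
        fit equals the plain GLM (statsmodels oracle)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 400
        Z = rng.uniform(0.2, 0.8, size=(n, 2))
        eta = -2.0 + 1.5 * Z[:, 0] + 2.0 * Z[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        w0, w, _ = fit_super(Z, y, "lbfgs")
        ref = sm.GLM(y, sm.add_constant(Z), family=sm.families.Binomial()).fit()
        assert ref.params[1] > 0 and ref.params[2] > 0  # interior optimum
        assert w0 == pytest.approx(ref.params[0], abs=1e-4)
        np.testing.assert_allclose(w, ref.params[1:], atol=1e-4)

    def test_all_supers_return_nonnegative_weights(self):
        Z, y = self._informative_Z(seed=21)
        for sup in ("nsslasso", "nlasso", "lbfgs"):
            _, w, _ = fit_super(Z, y, sup, seed=1)
            assert np.all(w >= 0), sup

    def test_unknown_super_rejected(self):
        Z, y = self._informative_Z()
        with pytest.raises(ValueError):
            fit_super(Z, y, "boosting")


class TestNormalizeWeights:
    def test_equal_weights_halved(self):
        np.testing.assert_allclose(normalize_weights([2.0, 2.0]), [0.5, 0.5])

    def test_relative_weights_sum_to_one(self):
        w = np.array([0.084, 0.297, 0.215, 0.232, 0.172])
        assert normalize_weights(w).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_passthrough_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = normalize_weights([0.0, 0.0])
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights([-0.1, 1.0])


class TestRefitAndStack:
    def _dataset(self, seed=5, n=120, p=6):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i}" for i in range(p)])
        eta = 1.5 * X["f0"].to_numpy() - 1.0 * X["f3"].to_numpy()
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return X, y

    def test_single_perfect_submodel_preserves_ranking(self):
        X, y = self._dataset()
        groups = GroupStructure({"only": ["f0", "f1", "f2"]})
        model = refit_and_stack(X, y, groups, super_learner="nlasso", seed=0)
        sub_pred = model.sub_predictions(X)[:, 0]
        stacked = model.predict(X)
        if model.weights[0] > 0:
            assert auc(y, stacked) == pytest.approx(auc(y, sub_pred), abs=1e-12)

    def test_zero_weights_give_constant_prediction(self):
        X, y = self._dataset()
        groups = GroupStructure({"g": ["f5"]})  # uninformative feature
        model = refit_and_stack(X, y, groups, super_learner="nlasso", seed=0)
        if np.all(model.weights == 0):
            pred = model.predict(X)
            assert np.ptp(pred) == pytest.approx(0.0, abs=1e-12)

    def test_group_relabelling_permutes_weights(self):
        X, y = self._dataset(seed=8)
        g1 = GroupStructure({"A": ["f0", "f1"], "B": ["f2", "f3"], "C": ["f4", "f5"]})
        g2 = GroupStructure({"C": ["f4", "f5"], "A": ["f0", "f1"], "B": ["f2", "f3"]})
        m1 = refit_and_stack(X, y, g1, super_learner="lbfgs", seed=0)
        m2 = refit_and_stack(X, y, g2, super_learner="lbfgs", seed=0)
        w1 = dict(zip(m1.group_ids, m1.weights))
        w2 = dict(zip(m2.group_ids, m2.weights))
        for k in w1:
            assert w1[k] == pytest.approx(w2[k], abs=1e-6)

    def test_end_to_end_determinism(self):
        X, y = self._dataset(seed=9)
        groups = GroupStructure({"A": ["f0", "f1"], "B": ["f2", "f3"]})
        m1 = refit_and_stack(X, y, groups, super_learner="nsslasso", seed=4)
        m2 = refit_and_stack(X, y, groups, super_learner="nsslasso", seed=4)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class _ScaledColumnLearner:
    """Deterministic learner whose prediction is the first column of the
    group, so group AUC is controlled by that column's informativeness."""

    name = "first-column"

    def fit(self, Xg, y, seed=0):
        class F:
            def predict(self, X):
                return 1 / (1 + np.exp(-X[:, 0]))

        return F()


class TestScreenGroups:
    def _data(self, seed=30):
        rng = np.random.default_rng(seed)
        n = 300
        y = np.tile([0.0, 1.0], n // 2)
        strong = (y * 2 - 1) + rng.normal(scale=0.6, size=n)
        weak = (y * 2 - 1) * 0.3 + rng.normal(size=n)
        noise = rng.normal(size=n)
        X = pd.DataFrame({"s": strong, "w": weak, "n": noise})
        groups = GroupStructure({"strong": ["s"], "weak": ["w"], "noise": ["n"]})
        return X, y, groups

    def test_min_auc_threshold_filter(self):
        X, y, groups = self._data()
        plan = make_folds(y, K=5, seed=1)
        kept, table = screen_groups(X, y, groups, learner=_ScaledColumnLearner(),
                                    fold_plan=plan, min_auc=0.577)
        assert "strong" in kept.names
        assert "noise" not in kept.names
        assert list(table["cv_auc"]) == sorted(table["cv_auc"], reverse=True)

    def test_top_m_keeps_single_best(self):
        X, y, groups = self._data()
        plan = make_folds(y, K=5, seed=1)
        kept, table = screen_groups(X, y, groups, learner=_ScaledColumnLearner(),
                                    fold_plan=plan, top_m=1)
        assert kept.names == [table["group"].iloc[0]] == ["strong"]

    def test_exactly_one_rule_required(self):
        X, y, groups = self._data()
        with pytest.raises(ValueError):
            screen_groups(X, y, groups, min_auc=0.5, top_m=2)

    def test_pure_noise_group_lands_near_half(self):
        X, y, groups = self._data()
        plan = make_folds(y, K=5, seed=2)
        _, table = screen_groups(X, y, groups, learner=_ScaledColumnLearner(),
                                 fold_plan=plan, min_auc=0.577)
        noise_auc = table.loc[table["group"] == "noise", "cv_auc"].iloc[0]
        assert abs(noise_auc - 0.5) < 0.08
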