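"""Tuning fitness, random search, stacking and voting ensembles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier

import icpg.evaluation
from icpg.model import (ALGOS, DEFAULT_SPACES, HyperParamSpace, TunedModel,
                        build_estimator, cv_fitness, fit_stacking, fit_voting,
                        oof_probabilities, predict, predict_proba, tune)


class ConstantClassifier(BaseEstimator, ClassifierMixin):
    """Always predicts one class with a fixed probability."""

    def __init__(self, proba=0.5):
        self.proba = proba

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.proba)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class MemorizingClassifier(BaseEstimator, ClassifierMixin):
    """Stores training rows verbatim; predicts the memorized label for a
    seen row and the training majority otherwise.  Used to prove that
    stacking meta-features are strictly out-of-fold."""

    def fit(self, X, y):
        self.memory_ = {tuple(row): int(lab) for row, lab in zip(X, y)}
        self.majority_ = int(np.asarray(y).mean() >= 0.5)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.array([float(self.memory_.get(tuple(row), self.majority_))
                      for row in X])
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.predict_proba(X)[:, 1].astype(int)


def leaked_data(n=200, seed=0):
    """y is a literal column of X: any depth-1 tree is perfect."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = np.column_stack([y.astype(float), rng.normal(size=n)])
    return X, y


class TestCvFitness:
    def test_leaked_label_gives_fitness_one(self):
        X, y = leaked_data()
        assert cv_fitness(DecisionTreeClassifier(max_depth=1), X, y,
                          seed=0) == 1.0

    def test_is_mean_of_per_fold_mcc(self, monkeypatch):
        scores = iter([0.5, 0.6, 0.7, 0.8, 0.9])
        monkeypatch.setattr(icpg.evaluation, "mcc",
                            lambda t, p: next(scores))
        X, y = leaked_data()
        assert cv_fitness(ConstantClassifier(), X, y,
                          n_folds=5, seed=0) == pytest.approx(0.7)

    def test_constant_predictor_scores_zero(self):
        X, y = leaked_data()
        assert cv_fitness(ConstantClassifier(0.9), X, y, seed=0) == 0.0

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            cv_fitness(ConstantClassifier(), X, np.ones(10, dtype=int))

    def test_degenerate_fold_warns_and_scores_zero(self):
        # 2 folds over 2 positives / 8 negatives: sklearn keeps class
        # balance, so force a degenerate fold with unstratifiable n_folds
        X, y = leaked_data(11)
        y = np.array([1] + [0] * 10)
        with pytest.warns(UserWarning):
            score = cv_fitness(DecisionTreeClassifier(max_depth=1), X, y,
                               n_folds=2, seed=0)
        assert -1.0 <= score <= 1.0


class TestTune:
    tiny = HyperParamSpace("rf", {"n_estimators": [10, 20],
                                  "max_depth": (2, 4)})

    def test_single_trial_returns_sampled_point(self):
        X, y = leaked_data(80)
        t = tune(self.tiny, X, y, n_trials=1, seed=3)
        assert t.algo == "rf"
        assert t.params["n_estimators"] in (10, 20)
        assert 2 <= t.params["max_depth"] <= 4

    def test_single_point_space_matches_direct_cv(self):
        X, y = leaked_data(80)
        space = HyperParamSpace("rf", {"n_estimators": [15],
                                       "max_depth": [3]})
        t = tune(space, X, y, n_trials=3, seed=5)
        direct = cv_fitness(t.build(), X, y, seed=5)
        assert t.fit_score == pytest.approx(direct)

    def test_rerun_same_seed_identical(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] + rng.normal(scale=0.5, size=100) > 0).astype(int)
        a = tune(self.tiny, X, y, n_trials=20, seed=7)
        b = tune(self.tiny, X, y, n_trials=20, seed=7)
        assert a == b

    def test_sampled_points_stay_in_range(self):
        rng = np.random.default_rng(2)
        for algo in ALGOS:
            space = DEFAULT_SPACES[algo]
            for _ in range(20):
                p = space.sample(rng)
                for name, spec in space.ranges.items():
                    if isinstance(spec, list):
                        assert p[name] in spec
                    else:
                        assert spec[0] <= p[name] <= spec[1]

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            HyperParamSpace("rf", {})

    def test_all_algos_build_and_fit(self):
        X, y = leaked_data(60)
        for algo in ALGOS:
            est = build_estimator(algo, {"n_estimators": 10}, seed=0)
            est.fit(X, y)
            assert predict(est, X).shape == (60,)


class TestVoting:
    def test_probability_mean_and_boundary_label(self):
        X, y = leaked_data(20)
        vm = fit_voting([ConstantClassifier(0.2), ConstantClassifier(0.8)],
                        X, y)
        proba = vm.predict_proba(X)
        assert np.allclose(proba, 0.5)
        assert (vm.predict(X) == 1).all()  # >= 0.5 rule at the boundary

    def test_agreeing_bases_pass_through(self):
        X, y = leaked_data(20)
        vm = fit_voting([ConstantClassifier(0.9), ConstantClassifier(0.9)],
                        X, y)
        assert np.allclose(vm.predict_proba(X), 0.9)

    def test_voting_identical_models_equals_single(self):
        X, y = leaked_data(100, seed=4)
        single = DecisionTreeClassifier(max_depth=3, random_state=0)
        single.fit(X, y)
        vm = fit_voting([DecisionTreeClassifier(max_depth=3, random_state=0)
                         for _ in range(3)], X, y)
        assert np.allclose(vm.predict_proba(X),
                           single.predict_proba(X)[:, 1])

    def test_fewer_than_two_bases_rejected(self):
        X, y = leaked_data(20)
        with pytest.raises(ValueError):
            fit_voting([ConstantClassifier()], X, y)


class TestStacking:
    def test_identical_bases_agree_with_base_labels(self):
        X, y = leaked_data(200, seed=6)
        bases = [DecisionTreeClassifier(max_depth=1, random_state=0)
                 for _ in range(3)]
        sm = fit_stacking(X, y, bases, seed=0)
        base = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        assert (sm.predict(X) == base.predict(X)).all()

    def test_beats_random_bases_given_one_perfect(self):
        from icpg.positional_features import assemble_feature_matrix
        from icpg.synthetic_data import SimulationParams, simulate_dataset

        for seed in (1, 2, 3):
            params = SimulationParams(
                chroms=(("chr1", 300_000), ("chr2", 300_000)), seed=seed)
            ds, _ = simulate_dataset(params)
            Xtr, ytr, _ = assemble_feature_matrix(ds, "cell00", ["chr1"])
            Xte, yte, _ = assemble_feature_matrix(ds, "cell00", ["chr2"])
            perfect = DecisionTreeClassifier(max_depth=6, random_state=0)
            randos = [ConstantClassifier(0.5), ConstantClassifier(0.4)]
            sm = fit_stacking(Xtr, ytr, [perfect, *randos], seed=seed)
            stacked = icpg.evaluation.mcc(yte, sm.predict(Xte))
            best_rando = max(
                icpg.evaluation.mcc(yte, r.fit(
                    Xtr.to_numpy(), ytr).predict(Xte.to_numpy()))
                for r in randos)
            assert stacked >= best_rando

    def test_oof_columns_are_out_of_fold(self):
        # a memorizer scores near chance out-of-fold on coin-flip labels
        rng = np.random.default_rng(10)
        X = rng.normal(size=(400, 5))
        y = rng.integers(0, 2, 400)
        Z = oof_probabilities([MemorizingClassifier()], X, y,
                              n_folds=5, seed=0)
        oof_mcc = icpg.evaluation.mcc(y, (Z[:, 0] >= 0.5).astype(int))
        assert abs(oof_mcc) <= 0.1
        # sanity: in-fold the same learner is perfect
        mem = MemorizingClassifier().fit(X, y)
        assert (mem.predict(X) == y).all()

    def test_meta_consumes_one_column_per_base(self):
        X, y = leaked_data(100, seed=2)
        bases = [DecisionTreeClassifier(max_depth=1, random_state=i)
                 for i in range(3)]
        sm = fit_stacking(X, y, bases, seed=0)
        assert sm.meta.n_features_in_ == 3

    def test_predictions_are_label_free(self):
        X, y = leaked_data(120, seed=9)
        sm = fit_stacking(X, y, [DecisionTreeClassifier(max_depth=2,
                                                        random_state=0),
                                 ConstantClassifier(0.3)], seed=0)
        before = sm.predict(X)
        rng = np.random.default_rng(0)
        _ = rng.permutation(y)  # shuffled labels are never shown to predict
        assert (sm.predict(X) == before).all()

    def test_fewer_than_two_bases_rejected(self):
        X, y = leaked_data(40)
        with pytest.raises(ValueError):
            fit_stacking(X, y, [ConstantClassifier()], seed=0)


class TestPredictHelpers:
    def test_threshold_extremes(self):
        X, y = leaked_data(30)
        est = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        assert (predict(est, X, threshold=0.0) == 1).all()
        proba = predict_proba(est, X)
        assert (predict(est, X, threshold=1.0) == (proba >= 1.0)).all()

    def test_predict_consistent_with_proba(self):
        X, y = leaked_data(50, seed=12)
        est = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
        assert (predict(est, X) == (predict_proba(est, X) >= 0.5)).all()

    def test_column_mismatch_names_first_offender(self):
        X = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        y = np.array([0, 1] * 5)
        vm = fit_voting([ConstantClassifier(), ConstantClassifier()], X, y)
        bad = X.rename(columns={"b": "zzz"})
        with pytest.raises(ValueError, match="'b'"):
            vm.predict_proba(bad)


def test_tuned_model_fit_score_in_range():
    X, y = leaked_data(80)
    t = tune(HyperParamSpace("rf", {"n_estimators": [10]}), X, y,
             n_trials=1, seed=0)
    assert -1.0 <= t.fit_score <= 1.0
    assert isinstance(t, TunedModel)
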