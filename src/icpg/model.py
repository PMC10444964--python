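"""Base classifiers, MCC-driven cross-validated tuning, stacking and voting.

Four gradient-tree base learners (random forest, AdaBoost, XGBoost,
LightGBM) are tuned by maximizing the cross-validated fitness

    Fit = (1 / N_FCV) * sum_j MCC_j,

the mean Matthews correlation coefficient over N_FCV stratified folds
(default 5), each MCC computed on the held-out fold.  A fold whose test
half contains a single class has an undefined MCC; it contributes 0 with
a warning, keeping the fitness finite.

The search is a seeded random search over the declared hyperparameter
space; the best trial wins, ties broken by earliest trial, and the whole
procedure is reproducible bit-for-bit given the seed (all estimators are
pinned to one thread).

Tuned bases combine two ways:

* **stacking** — an extra-trees meta-predictor fitted on the bases'
  out-of-fold probabilities (the same stratified folds for every base, so
  no base model ever predicts a row it trained on), bases then refit on
  the full training data for deployment;
* **soft voting** — arithmetic mean of base probabilities.

Labels are probability >= 0.5 (configurable threshold).
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              RandomForestClassifier)
from sklearn.model_selection import StratifiedKFold

ALGOS = ("rf", "adaboost", "xgb", "lgbm")


@contextmanager
def _quiet_feature_names():
    """LightGBM's sklearn wrapper invents column names for ndarray input,
    which trips sklearn's name check on every array predict; spurious here
    because fit and predict always go through the same array path."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names",
            category=UserWarning)
        yield


def build_estimator(algo: str, params: Mapping[str, Any],
                    seed: int = 0) -> BaseEstimator:
    """Instantiate a single-threaded base learner with the given
    hyperparameters and seed."""
    p = dict(params)
    if algo == "rf":
        return RandomForestClassifier(
            n_estimators=int(p.get("n_estimators", 300)),
            max_depth=int(p["max_depth"]) if p.get("max_depth") else None,
            random_state=seed, n_jobs=1)
    if algo == "adaboost":
        return AdaBoostClassifier(
            n_estimators=int(p.get("n_estimators", 200)),
            learning_rate=float(p.get("learning_rate", 0.1)),
            random_state=seed)
    if algo == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(
            n_estimators=int(p.get("n_estimators", 300)),
            max_depth=int(p.get("max_depth", 6)),
            learning_rate=float(p.get("learning_rate", 0.1)),
            reg_lambda=float(p.get("reg_lambda", 1.0)),
            tree_method="hist", n_jobs=1, random_state=seed,
            verbosity=0, eval_metric="logloss")
    if algo == "lgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(
            n_estimators=int(p.get("n_estimators", 300)),
            max_depth=int(p.get("max_depth", 6)),
            learning_rate=float(p.get("learning_rate", 0.1)),
            reg_lambda=float(p.get("reg_lambda", 1.0)),
            num_leaves=int(2 ** min(int(p.get("max_depth", 6)), 10)),
            random_state=seed, n_jobs=1, verbosity=-1,
            deterministic=True, force_row_wise=True)
    raise ValueError(f"unknown algo {algo!r}; choose from {ALGOS}")


@dataclass(frozen=True)
class HyperParamSpace:
    """Named parameter ranges for one algorithm.

    ``ranges`` maps a parameter name to either a (low, high) interval —
    tagged ``"log"`` as a third element for log-uniform sampling, sampled
    as an int when both ends are ints — or an explicit list of choices.
    """

    algo: str
    ranges: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algo not in ALGOS:
            raise ValueError(f"unknown algo {self.algo!r}")
        if not self.ranges:
            raise ValueError("empty hyperparameter space")

    def sample(self, rng: np.random.Generator) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name, spec in self.ranges.items():
            if isinstance(spec, (list,)):
                out[name] = spec[int(rng.integers(len(spec)))]
            else:
                lo, hi = spec[0], spec[1]
                log = len(spec) > 2 and spec[2] == "log"
                if log:
                    val = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    val = float(rng.uniform(lo, hi))
                if isinstance(lo, int) and isinstance(hi, int) and not log:
                    val = int(round(val))
                out[name] = val
        return out


#: Default search spaces: standard gradient-boosting ranges.
DEFAULT_SPACES: dict[str, HyperParamSpace] = {
    "rf": HyperParamSpace("rf", {
        "n_estimators": (100, 1000), "max_depth": (3, 10)}),
    "adaboost": HyperParamSpace("adaboost", {
        "n_estimators": (100, 1000), "learning_rate": (1e-3, 0.3, "log")}),
    "xgb": HyperParamSpace("xgb", {
        "n_estimators": (100, 1000), "max_depth": (3, 10),
        "learning_rate": (1e-3, 0.3, "log"), "reg_lambda": (1.0, 10.0)}),
    "lgbm": HyperParamSpace("lgbm", {
        "n_estimators": (100, 1000), "max_depth": (3, 10),
        "learning_rate": (1e-3, 0.3, "log"), "reg_lambda": (1.0, 10.0)}),
}

#: Reduced spaces for quick runs (small data, smoke tests, benchmarks).
FAST_SPACES: dict[str, HyperParamSpace] = {
    "rf": HyperParamSpace("rf", {
        "n_estimators": (50, 200), "max_depth": (3, 10)}),
    "adaboost": HyperParamSpace("adaboost", {
        "n_estimators": (50, 200), "learning_rate": (1e-2, 0.3, "log")}),
    "xgb": HyperParamSpace("xgb", {
        "n_estimators": (50, 300), "max_depth": (3, 8),
        "learning_rate": (1e-2, 0.3, "log"), "reg_lambda": (1.0, 10.0)}),
    "lgbm": HyperParamSpace("lgbm", {
        "n_estimators": (50, 300), "max_depth": (3, 8),
        "learning_rate": (1e-2, 0.3, "log"), "reg_lambda": (1.0, 10.0)}),
}


def _fresh(learner, seed: int | None = None):
    """A fresh unfitted copy of a learner spec (estimator or factory)."""
    if callable(learner) and not isinstance(learner, BaseEstimator):
        return learner()
    est = clone(learner)
    if seed is not None and "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def _as_array(X) -> np.ndarray:
    return X.to_numpy(dtype=np.float64) if isinstance(X, pd.DataFrame) \
        else np.asarray(X, dtype=np.float64)


def cv_fitness(learner, X, y, n_folds: int = 5, seed: int = 0) -> float:
    """Mean held-out-fold MCC over a seeded stratified K-fold split.

    ``learner`` is an unfitted sklearn-style estimator (cloned per fold)
    or a zero-argument factory returning one.
    """
    from .evaluation import mcc

    Xa, ya = _as_array(X), np.asarray(y, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(np.unique(ya)) < 2:
        raise ValueError("labels must contain both classes")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(Xa, ya):
        if len(np.unique(ya[te])) < 2:
            warnings.warn("single-class held-out fold: MCC set to 0")
            scores.append(0.0)
            continue
        est = _fresh(learner)
        with _quiet_feature_names():
            est.fit(Xa[tr], ya[tr])
            scores.append(mcc(ya[te], est.predict(Xa[te])))
    return float(np.mean(scores))


@dataclass(frozen=True)
class TunedModel:
    """A base learner identifier with its tuned hyperparameters and the
    cross-validated fitness achieved."""

    algo: str
    params: dict[str, Any]
    fit_score: float
    seed: int

    def build(self) -> BaseEstimator:
        return build_estimator(self.algo, self.params, self.seed)


def tune(space: HyperParamSpace, X, y, n_trials: int = 50,
         n_folds: int = 5, seed: int = 0) -> TunedModel:
    """Random search over ``space`` maximizing :func:`cv_fitness`.

    All trials share one fold split (fair comparison); the argmax trial
    wins, earliest trial on ties.  Fully reproducible given the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    est_seed = int(rng.integers(2 ** 31 - 1))
    best: TunedModel | None = None
    for _ in range(n_trials):
        params = space.sample(rng)
        est = build_estimator(space.algo, params, est_seed)
        score = cv_fitness(est, X, y, n_folds=n_folds, seed=seed)
        if best is None or score > best.fit_score:
            best = TunedModel(space.algo, params, score, est_seed)
    assert best is not None
    return best


def oof_probabilities(learners, X, y, n_folds: int = 5,
                      seed: int = 0) -> np.ndarray:
    """Out-of-fold positive-class probability matrix (rows x learners).

    Every learner sees the same stratified folds; each row's probability
    comes from the model that did NOT train on that row.
    """
    Xa, ya = _as_array(X), np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.zeros((len(ya), len(learners)), dtype=np.float64)
    for tr, te in skf.split(Xa, ya):
        for k, learner in enumerate(learners):
            est = _fresh(learner)
            with _quiet_feature_names():
                est.fit(Xa[tr], ya[tr])
                oof[te, k] = est.predict_proba(Xa[te])[:, 1]
    return oof


def _check_columns(feature_names, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame) and feature_names is not None:
        got = list(X.columns)
        if got != list(feature_names):
            for a, b in zip(feature_names, got):
                if a != b:
                    raise ValueError(
                        f"feature column mismatch: expected {a!r}, got {b!r}")
            raise ValueError(
                f"feature count mismatch: expected {len(feature_names)}, "
                f"got {len(got)}")
    return _as_array(X)


class VotingModel:
    """Soft-voting ensemble: mean of base positive-class probabilities."""

    def __init__(self, bases: list[BaseEstimator],
                 feature_names: list[str] | None = None) -> None:
        if len(bases) < 2:
            raise ValueError("voting needs at least 2 base models")
        self.bases = bases
        self.feature_names = feature_names

    def predict_proba(self, X) -> np.ndarray:
        Xa = _check_columns(self.feature_names, X)
        with _quiet_feature_names():
            probas = [b.predict_proba(Xa)[:, 1] for b in self.bases]
        return np.mean(probas, axis=0)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int8)


class StackingModel:
    """Stacked ensemble with an extra-trees meta-predictor.

    The meta learner consumes exactly one probability column per base
    model; its training rows are strictly out-of-fold.
    """

    def __init__(self, bases: list[BaseEstimator], meta: BaseEstimator,
                 feature_names: list[str] | None = None) -> None:
        self.bases = bases
        self.meta = meta
        self.feature_names = feature_names

    def predict_proba(self, X) -> np.ndarray:
        Xa = _check_columns(self.feature_names, X)
        with _quiet_feature_names():
            Z = np.column_stack([b.predict_proba(Xa)[:, 1]
                                 for b in self.bases])
        return self.meta.predict_proba(Z)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int8)


def fit_stacking(X, y, tuned: list, n_folds: int = 5, seed: int = 0,
                 meta_trees: int = 200) -> StackingModel:
    """Fit the stacked ensemble.

    ``tuned`` is a list of :class:`TunedModel` (or unfitted estimators /
    factories).  The meta extra-trees classifier is fitted on the bases'
    out-of-fold probabilities; the bases are then refit on all of ``X``
    for deployment.
    """
    if len(tuned) < 2:
        raise ValueError("stacking needs at least 2 base models")
    learners = [t.build() if isinstance(t, TunedModel) else t for t in tuned]
    ya = np.asarray(y, dtype=int)
    if len(np.unique(ya)) < 2:
        raise ValueError("labels must contain both classes")
    Z = oof_probabilities(learners, X, ya, n_folds=n_folds, seed=seed)
    meta = ExtraTreesClassifier(n_estimators=meta_trees, random_state=seed,
                                n_jobs=1)
    meta.fit(Z, ya)
    Xa = _as_array(X)
    fitted = []
    for learner in learners:
        est = _fresh(learner)
        est.fit(Xa, ya)
        fitted.append(est)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    return StackingModel(fitted, meta, names)


def fit_voting(tuned: list, X, y) -> VotingModel:
    """Fit the soft-voting ensemble: each base refit on all of ``X``."""
    learners = [t.build() if isinstance(t, TunedModel) else t for t in tuned]
    Xa, ya = _as_array(X), np.asarray(y, dtype=int)
    fitted = []
    for learner in learners:
        est = _fresh(learner)
        est.fit(Xa, ya)
        fitted.append(est)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    return VotingModel(fitted, names)


def predict_proba(model, X) -> np.ndarray:
    """Positive-class probabilities from any fitted model or ensemble."""
    with _quiet_feature_names():
        p = np.asarray(model.predict_proba(_as_array(X)
                                           if not hasattr(model, "bases")
                                           else X))
    return p[:, 1] if p.ndim == 2 else p


def predict(model, X, threshold: float = 0.5) -> np.ndarray:
    """Labels from probabilities at the given threshold (>= rule)."""
    return (predict_proba(model, X) >= threshold).astype(np.int8)
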