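"""Model/Results surface for CpG methylation-state imputation.

:class:`CpGImputer` is built from a :class:`~icpg.methdata.MethylationDataset`
and a feature scheme; ``fit()`` tunes and trains one classifier per target
cell on the training chromosomes (donor features always come from the
other cells) and returns a :class:`CpGImputerResults` carrying the tuned
hyperparameters, cross-validated fitness, held-out-chromosome metrics and
a ``summary()`` table.

A model is trained per cell because cell-specific coverage and state
composition differ; the donor-block layout ties a fitted model to the
dataset's cell count and ordering, and prediction on a dataset with a
different cell count is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import model as _model
from .evaluation import evaluate_per_cell
from .methdata import ChromosomeSplit, MethylationDataset, binarize_and_filter, read_manifest
from .positional_features import DEFAULT_SENTINEL, assemble_feature_matrix
from .sequence_features import assemble_sequence_matrix

ENSEMBLES = ("stacking", "voting")


@dataclass
class CpGImputer:
    """Per-cell CpG methylation-state imputation model.

    Parameters
    ----------
    dataset
        Binarized, depth-filtered multi-cell methylome.
    target_cells
        Cells to train models for; default all cells.
    features
        ``positional`` (intra-cell skip-K neighbors + cross-cell F/D
        blocks), ``ngram`` or ``onehot`` (sequence-window baselines;
        require ``reference``).
    algo
        One of ``rf``, ``adaboost``, ``xgb``, ``lgbm``, ``stacking``,
        ``voting``.
    split
        Chromosome holdout; defaults to the train 1,3,5,7,9,11 /
        test 2,4,6,8,10,12 / validation 13-19 scheme.
    reference
        Chromosome -> sequence mapping for the sequence encoders.
    """

    dataset: MethylationDataset
    target_cells: list[str] | None = None
    features: str = "positional"
    algo: str = "lgbm"
    split: ChromosomeSplit = field(default_factory=ChromosomeSplit)
    J: int = 2
    sentinel: float = DEFAULT_SENTINEL
    flank: int = 50
    reference: Mapping[str, str] | None = None
    spaces: Mapping[str, _model.HyperParamSpace] | None = None

    def __post_init__(self) -> None:
        if self.features not in ("positional", "ngram", "onehot"):
            raise ValueError(f"unknown feature scheme {self.features!r}")
        if self.algo not in (*_model.ALGOS, *ENSEMBLES):
            raise ValueError(f"unknown algo {self.algo!r}")
        if self.features != "positional" and self.reference is None:
            raise ValueError(f"{self.features} features need a reference")
        if self.target_cells is None:
            self.target_cells = list(self.dataset.cell_ids)
        for cid in self.target_cells:
            self.dataset.cell(cid)  # raises on unknown id

    @classmethod
    def from_files(cls, manifest: str, dialect: str = "simple_tsv",
                   min_depth: int = 4, meth_threshold: float = 0.5,
                   **kwargs: Any) -> "CpGImputer":
        """Build from a manifest of per-cell coverage files, applying the
        depth filter and state binarization."""
        raw = read_manifest(manifest, dialect=dialect)
        ds = MethylationDataset(
            [binarize_and_filter(c, min_depth, meth_threshold)
             for c in raw.cells])
        return cls(ds, **kwargs)

    # ---- feature assembly -------------------------------------------------

    def design_matrix(self, cell_id: str, chroms: list[str] | None
                      ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
        """(X, y, site index) for one target cell on a chromosome subset."""
        if self.features == "positional":
            return assemble_feature_matrix(
                self.dataset, cell_id, chroms, J=self.J,
                sentinel=self.sentinel)
        return assemble_sequence_matrix(
            self.dataset.cell(cell_id), self.reference, chroms,
            encoding=self.features, flank=self.flank)

    # ---- fitting ----------------------------------------------------------

    def fit(self, n_trials: int = 20, n_folds: int = 5, seed: int = 0,
            fast: bool = False) -> "CpGImputerResults":
        """Tune and fit per-cell models on the training chromosomes and
        evaluate them on the held-out test chromosomes.

        ``fast`` selects the reduced search spaces (smaller forests) for
        quick runs; ``n_trials`` random-search trials per base learner.
        """
        spaces = self.spaces or (_model.FAST_SPACES if fast
                                 else _model.DEFAULT_SPACES)
        train_chroms = sorted(self.split.train)
        test_chroms = sorted(self.split.test)
        fitted: dict[str, Any] = {}
        tuned_all: dict[str, list[_model.TunedModel]] = {}
        pred_rows = []
        truth_rows = []
        fitness_rows = []
        for ci, cell_id in enumerate(self.target_cells):
            cell_seed = (seed * 1009 + ci * 101) % (2 ** 31 - 1)
            X, y, _ = self.design_matrix(cell_id, train_chroms)
            if len(np.unique(y)) < 2:
                raise ValueError(
                    f"cell {cell_id}: single-class training labels")
            base_algos = (list(_model.ALGOS) if self.algo in ENSEMBLES
                          else [self.algo])
            tuned = [_model.tune(spaces[a], X, y, n_trials=n_trials,
                                 n_folds=n_folds, seed=cell_seed)
                     for a in base_algos]
            tuned_all[cell_id] = tuned
            for t in tuned:
                fitness_rows.append({"cell_id": cell_id, "algo": t.algo,
                                     "fit_score": t.fit_score,
                                     **{f"param_{k}": v
                                        for k, v in t.params.items()}})
            if self.algo == "stacking":
                m = _model.fit_stacking(X, y, tuned, n_folds=n_folds,
                                        seed=cell_seed)
            elif self.algo == "voting":
                m = _model.fit_voting(tuned, X, y)
            else:
                m = tuned[0].build()
                m.fit(_model._as_array(X), np.asarray(y, dtype=int))
            fitted[cell_id] = m
            Xt, yt, idx = self.design_matrix(cell_id, test_chroms)
            if len(Xt):
                proba = _model.predict_proba(m, Xt)
                label = (proba >= 0.5).astype(int)
                for (chrom, pos), p, lab, s in zip(
                        idx.itertuples(index=False), proba, label, yt):
                    pred_rows.append((cell_id, chrom, int(pos),
                                      float(p), int(lab)))
                    truth_rows.append((cell_id, chrom, int(pos), int(s)))
        predictions = pd.DataFrame(
            pred_rows,
            columns=["cell_id", "chrom", "pos", "probability", "label"])
        truth = pd.DataFrame(
            truth_rows, columns=["cell_id", "chrom", "pos", "state"])
        if len(predictions):
            metrics = evaluate_per_cell(
                predictions[["cell_id", "chrom", "pos", "label"]], truth)
        else:
            metrics = pd.DataFrame()
        return CpGImputerResults(
            imputer=self, models=fitted, tuned=tuned_all,
            fitness=pd.DataFrame(fitness_rows), metrics=metrics,
            predictions=predictions, seed=seed, n_trials=n_trials,
            n_folds=n_folds)


@dataclass
class CpGImputerResults:
    """Fitted per-cell models plus their tuning and held-out diagnostics.

    Attributes
    ----------
    fitness
        One row per (cell, base algo): cross-validated mean-MCC fitness
        and the winning hyperparameters.
    metrics
        Held-out test-chromosome metric table, one row per cell plus a
        macro-average row (sen/spe/acc/f1/mcc).
    predictions
        Per-site probabilities and labels on the test chromosomes.
    """

    imputer: CpGImputer
    models: dict[str, Any]
    tuned: dict[str, list[_model.TunedModel]]
    fitness: pd.DataFrame
    metrics: pd.DataFrame
    predictions: pd.DataFrame
    seed: int
    n_trials: int
    n_folds: int

    @property
    def macro(self) -> pd.Series:
        """Macro-average metric row across cells."""
        if not len(self.metrics):
            raise ValueError("no held-out metrics (empty test view)")
        return self.metrics[self.metrics.cell_id == "macro_avg"].iloc[0]

    def evaluate_on(self, chroms: list[str]) -> pd.DataFrame:
        """Per-cell metric table on an arbitrary chromosome subset
        (e.g. the validation chromosomes, for choosing between ensemble
        variants).  Empty when no target cell has sites there."""
        pred_rows, truth_rows = [], []
        for cell_id, m in self.models.items():
            X, y, idx = self.imputer.design_matrix(cell_id, sorted(chroms))
            if not len(X):
                continue
            proba = _model.predict_proba(m, X)
            for (chrom, pos), p, s in zip(idx.itertuples(index=False),
                                          proba, y):
                pred_rows.append((cell_id, chrom, int(pos),
                                  int(p >= 0.5)))
                truth_rows.append((cell_id, chrom, int(pos), int(s)))
        if not pred_rows:
            return pd.DataFrame()
        cols = ["cell_id", "chrom", "pos"]
        return evaluate_per_cell(
            pd.DataFrame(pred_rows, columns=[*cols, "label"]),
            pd.DataFrame(truth_rows, columns=[*cols, "state"]))

    def predict(self, dataset: MethylationDataset | None = None,
                cell_id: str | None = None,
                chroms: list[str] | None = None,
                threshold: float = 0.5) -> pd.DataFrame:
        """Impute states for a target cell's sites on given chromosomes.

        The dataset must have the same cell count and ordering as the
        one the model was trained on (the donor-block layout depends on
        both).
        """
        ds = dataset or self.imputer.dataset
        if ds.w != self.imputer.dataset.w:
            raise ValueError(
                f"dataset has {ds.w} cells but the model was trained "
                f"with {self.imputer.dataset.w}")
        cell_id = cell_id or self.imputer.target_cells[0]
        if cell_id not in self.models:
            raise KeyError(f"no fitted model for cell {cell_id!r}")
        imp = CpGImputer(ds, target_cells=[cell_id],
                         features=self.imputer.features,
                         algo=self.imputer.algo, split=self.imputer.split,
                         J=self.imputer.J, sentinel=self.imputer.sentinel,
                         flank=self.imputer.flank,
                         reference=self.imputer.reference)
        X, _, idx = imp.design_matrix(cell_id, chroms)
        proba = _model.predict_proba(self.models[cell_id], X)
        out = idx.copy()
        out.insert(0, "cell_id", cell_id)
        out["probability"] = proba
        out["label"] = (proba >= threshold).astype(int)
        return out

    def summary(self) -> str:
        """Readable fit report: configuration, per-cell fitness, held-out
        metrics."""
        imp = self.imputer
        lines = [
            "CpG methylation imputation results",
            "==================================",
            f"cells: {imp.dataset.w} (targets: {len(imp.target_cells)})  "
            f"features: {imp.features}  algo: {imp.algo}",
            f"trials: {self.n_trials}  folds: {self.n_folds}  "
            f"seed: {self.seed}",
            f"train chroms: {','.join(sorted(imp.split.train))}",
            f"test chroms:  {','.join(sorted(imp.split.test))}",
            "",
            "Cross-validated fitness (mean fold MCC):",
        ]
        if len(self.fitness):
            short = self.fitness[["cell_id", "algo", "fit_score"]]
            lines.append(short.to_string(index=False,
                                         float_format=lambda v: f"{v:.4f}"))
        if len(self.metrics):
            lines += ["", "Held-out test-chromosome metrics:",
                      self.metrics[["cell_id", "n_sites", "sen", "spe",
                                    "acc", "f1", "mcc"]].to_string(
                          index=False,
                          float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)
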