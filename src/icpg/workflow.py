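"""End-to-end orchestration: simulate -> featurize -> train -> predict ->
evaluate, plus the desk-scale method-comparison benchmark.

A run is described by a :class:`RunConfig` (every CLI flag has a config
counterpart; the CLI wins on conflict).  Training writes a model bundle —
a directory with a JSON run manifest (config, seed, library versions,
config hash) and a pickled results object — so any output is reproducible
from config + seed alone.  All outputs are written temp-then-rename.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .imputer import CpGImputer, CpGImputerResults
from .methdata import ChromosomeSplit, write_predictions
from .synthetic_data import SimulationParams, simulate_dataset, simulate_null

BENCH_ALGOS = ("rf", "adaboost", "xgb", "lgbm", "stacking", "voting")
BENCH_FEATURES = ("positional", "ngram", "onehot")


@dataclass
class RunConfig:
    """Everything needed to reproduce a training or benchmark run."""

    manifest: str | None = None       # None -> simulate instead
    dialect: str = "simple_tsv"
    fasta: str | None = None
    features: str = "positional"
    algo: str = "lgbm"
    trials: int = 20
    folds: int = 5
    seed: int = 0
    min_depth: int = 4
    meth_threshold: float = 0.5
    J: int = 2
    flank: int = 50
    fast: bool = False
    target_cells: list[str] | None = None
    sim: SimulationParams | None = None
    split: ChromosomeSplit = field(default_factory=ChromosomeSplit)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["split"] = {k: sorted(getattr(self.split, k))
                      for k in ("train", "test", "validation")}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _library_versions() -> dict[str, str]:
    import lightgbm
    import sklearn
    import xgboost

    return {"python": platform.python_version(),
            "numpy": np.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
            "lightgbm": lightgbm.__version__}


def random_reference(chroms, seed: int) -> dict[str, str]:
    """Uniform-random A/C/G/T reference for the sequence encoders.

    Used when benchmarking on simulated data, which plants positional but
    no sequence signal: windows drawn from this reference carry no label
    information by construction.
    """
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for label, length in chroms:
        codes = rng.integers(0, 4, size=int(length))
        out[label] = lut[codes].tobytes().decode("ascii")
    return out


def _build_imputer(config: RunConfig, dataset=None) -> CpGImputer:
    if dataset is None:
        if config.manifest is not None:
            return CpGImputer.from_files(
                config.manifest, dialect=config.dialect,
                min_depth=config.min_depth,
                meth_threshold=config.meth_threshold,
                target_cells=config.target_cells, features=config.features,
                algo=config.algo, split=config.split, J=config.J,
                flank=config.flank, reference=_load_reference(config))
        sim = config.sim or SimulationParams(seed=config.seed)
        dataset, _ = simulate_dataset(sim)
    return CpGImputer(dataset, target_cells=config.target_cells,
                      features=config.features, algo=config.algo,
                      split=config.split, J=config.J, flank=config.flank,
                      reference=_load_reference(config, dataset))


def _load_reference(config: RunConfig, dataset=None):
    if config.features == "positional":
        return None
    if config.fasta is not None:
        from pyfaidx import Fasta

        return Fasta(config.fasta, as_raw=True)
    if config.sim is not None or config.manifest is None:
        sim = config.sim or SimulationParams(seed=config.seed)
        return random_reference(sim.chroms, seed=config.seed + 7919)
    raise ValueError(f"{config.features} features need --fasta")


def run_train(config: RunConfig, outdir: str | Path) -> CpGImputerResults:
    """Tune and fit per-cell models; write a reproducible model bundle.

    The bundle holds ``manifest.json`` (config, seed, versions, config
    hash), ``metrics.tsv`` (held-out test-chromosome metrics per cell),
    ``fitness.tsv`` (cross-validated fitness per cell and base learner),
    ``metrics_validation.tsv`` (validation-chromosome metrics, written
    when the split reserves validation chromosomes with data) and
    ``results.pkl``.
    """
    imputer = _build_imputer(config)
    results = imputer.fit(n_trials=config.trials, n_folds=config.folds,
                          seed=config.seed, fast=config.fast)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config.digest(),
                "versions": _library_versions(),
                "cells": imputer.dataset.cell_ids}
    _write_text(outdir / "manifest.json",
                json.dumps(manifest, indent=2, default=str) + "\n")
    _write_text(outdir / "metrics.tsv",
                results.metrics.to_csv(sep="\t", index=False,
                                       float_format="%.6f"))
    _write_text(outdir / "fitness.tsv",
                results.fitness.to_csv(sep="\t", index=False,
                                       float_format="%.6f"))
    val_metrics = results.evaluate_on(sorted(config.split.validation)) \
        if config.split.validation else pd.DataFrame()
    if len(val_metrics):
        _write_text(outdir / "metrics_validation.tsv",
                    val_metrics.to_csv(sep="\t", index=False,
                                       float_format="%.6f"))
    tmp = outdir / "results.pkl.tmp"
    with open(tmp, "wb") as fh:
        pickle.dump(results, fh)
    tmp.replace(outdir / "results.pkl")
    return results


def load_bundle(bundle: str | Path) -> CpGImputerResults:
    with open(Path(bundle) / "results.pkl", "rb") as fh:
        return pickle.load(fh)


def run_predict(bundle: str | Path, out: str | Path,
                cell_ids: list[str] | None = None,
                chroms: list[str] | None = None) -> pd.DataFrame:
    """Impute states with a trained bundle; write a BED-like TSV."""
    results = load_bundle(bundle)
    cell_ids = cell_ids or list(results.models)
    frames = [results.predict(cell_id=cid, chroms=chroms)
              for cid in cell_ids]
    preds = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["cell_id", "chrom", "pos",
                              "probability", "label"])
    write_predictions(
        [(r.cell_id, r.chrom, int(r.pos), float(r.probability), int(r.label))
         for r in preds.itertuples(index=False)], out)
    return preds


def run_benchmark(config: RunConfig, seeds: tuple[int, ...] = (1, 2, 3),
                  algos=BENCH_ALGOS, features=BENCH_FEATURES,
                  null: bool = False,
                  out: str | Path | None = None) -> pd.DataFrame:
    """Compare classifiers x feature schemes on simulated data.

    One target cell (the first) per run keeps the table desk-scale.
    Returns per-(algo, feature, seed) held-out metrics plus mean/SD rows;
    ``null`` swaps in the no-signal simulator.  Orderings against
    expectations (positional > sequence encodings on data with only
    positional signal; ensembles competitive with bases) are for the
    reader to check in the table — they are data-dependent, not asserted.
    """
    rows = []
    for seed in seeds:
        sim = dataclasses.replace(config.sim or SimulationParams(),
                                  seed=seed)
        dataset, _ = (simulate_null if null else simulate_dataset)(sim)
        reference = random_reference(sim.chroms, seed=seed + 7919)
        target = dataset.cell_ids[0]
        for feat in features:
            for algo in algos:
                imp = CpGImputer(
                    dataset, target_cells=[target], features=feat,
                    algo=algo, split=config.split, J=config.J,
                    flank=config.flank,
                    reference=None if feat == "positional" else reference)
                res = imp.fit(n_trials=config.trials, n_folds=config.folds,
                              seed=seed, fast=True)
                m = res.macro
                rows.append({"features": feat, "algo": algo, "seed": seed,
                             "n_sites": int(m.n_sites),
                             **{k: float(m[k]) for k in
                                ("sen", "spe", "acc", "f1", "mcc")}})
    table = pd.DataFrame(rows)
    agg = (table.groupby(["features", "algo"], sort=True)
           [["sen", "spe", "acc", "f1", "mcc"]]
           .agg(["mean", "std"]))
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    summary = agg.reset_index()
    if out is not None:
        _write_text(Path(out), table.to_csv(sep="\t", index=False,
                                            float_format="%.6f"))
        summary_path = Path(out).with_name(Path(out).stem + "_summary.tsv")
        _write_text(summary_path, summary.to_csv(sep="\t", index=False,
                                                 float_format="%.6f"))
    return table


def _write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)
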