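"""Binary classification metrics for methylation-state prediction.

Five figures of merit, all derived from the confusion counts with the
methylated class (1) as positive:

    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    F1  = TP / (TP + 0.5 (FP + FN))
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP))

Any metric whose denominator is zero is reported as 0.0 and flagged, so
per-cell tables over sparse cells stay rectangular.  Per-cell reports
carry an unweighted (macro) average row across cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_NAMES = ("sen", "spe", "acc", "f1", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN with methylated (1) as the positive class."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den != 0 else (0.0, True)


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """All five metrics from one set of confusion counts.

    Returns sen/spe/acc/f1/mcc plus a ``flagged`` entry naming how many
    metrics had a zero denominator (reported as 0.0).
    """
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    sen, f_sen = _safe_div(tp, tp + fn)
    spe, f_spe = _safe_div(tn, tn + fp)
    acc, f_acc = _safe_div(tp + tn, tp + fp + tn + fn)
    f1, f_f1 = _safe_div(tp, tp + 0.5 * (fp + fn))
    den2 = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    mcc, f_mcc = _safe_div(tp * tn - fp * fn, math.sqrt(den2))
    return {"sen": sen, "spe": spe, "acc": acc, "f1": f1, "mcc": mcc,
            "flagged": float(sum((f_sen, f_spe, f_acc, f_f1, f_mcc)))}


def mcc(y_true, y_pred) -> float:
    """Matthews correlation coefficient (degenerate denominator -> 0)."""
    return compute_metrics(confusion_counts(y_true, y_pred))["mcc"]


def evaluate_per_cell(predictions: pd.DataFrame,
                      truth: pd.DataFrame) -> pd.DataFrame:
    """Per-cell metric table plus a macro-average row.

    Both frames need columns (cell_id, chrom, pos) plus ``label`` on the
    predictions and ``state`` on the truth; every prediction must join to
    exactly one truth record.
    """
    keys = ["cell_id", "chrom", "pos"]
    merged = predictions.merge(truth, on=keys, how="left",
                               validate="one_to_one")
    orphan = merged["state"].isna()
    if orphan.any():
        first = merged.loc[orphan, keys].iloc[0].tolist()
        raise ValueError(f"prediction with no truth record: {first}")
    rows = []
    for cell_id, grp in merged.groupby("cell_id", sort=True):
        c = confusion_counts(grp["state"].to_numpy(dtype=int),
                             grp["label"].to_numpy(dtype=int))
        m = compute_metrics(c)
        rows.append({"cell_id": cell_id, "n_sites": c.n, "TP": c.TP,
                     "TN": c.TN, "FP": c.FP, "FN": c.FN, **m})
    report = pd.DataFrame(rows)
    macro = {"cell_id": "macro_avg",
             "n_sites": int(report["n_sites"].sum()),
             "TP": int(report["TP"].sum()), "TN": int(report["TN"].sum()),
             "FP": int(report["FP"].sum()), "FN": int(report["FN"].sum())}
    for name in (*METRIC_NAMES, "flagged"):
        macro[name] = float(report[name].mean())
    return pd.concat([report, pd.DataFrame([macro])], ignore_index=True)
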