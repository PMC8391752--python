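"""Binary classification reports with FLD as the positive class."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived metrics (FLD = positive class).

    Precision/recall/F1 follow the 0-when-undefined convention; AUROC is
    NaN when scores are unavailable or the test set is single-class.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    n: int

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[int],
        y_pred: Sequence[int],
        scores: Optional[Sequence[float]] = None,
    ) -> "EvalReport":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred length mismatch")
        tp = int(((yt == 1) & (yp == 1)).sum())
        fp = int(((yt == 0) & (yp == 1)).sum())
        tn = int(((yt == 0) & (yp == 0)).sum())
        fn = int(((yt == 1) & (yp == 0)).sum())
        n = len(yt)
        accuracy = (tp + tn) / n if n else math.nan
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        if scores is not None and len(set(yt.tolist())) == 2:
            auroc = float(roc_auc_score(yt, np.asarray(scores, dtype=float)))
        else:
            auroc = math.nan
        return cls(tp, fp, tn, fn, accuracy, precision, recall, f1, auroc, n)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auroc": self.auroc, "n": self.n,
        }


__all__ = ["EvalReport"]
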