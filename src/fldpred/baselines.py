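"""Next-visit prediction baselines and the error-reduction comparison.

Baseline 1 (majority) always predicts the larger training class.
Baseline 2 (persistence) always predicts the previous (anchor) visit's
label; its accuracy equals the label-persistence rate of the test pairs,
which is what a useful sequence model must beat.  The error reduction
rate of a model against a baseline is (e_b - e_m) / e_b with
e = 1 - accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import NFLD
from .metrics import EvalReport
from .recurrent import TrainedModel, predict
from .sequences import SequenceSample


@dataclass
class BaselineReport:
    baseline: str  # "majority" | "persistence"
    report: EvalReport
    error_reduction_by_model: dict[str, float] = field(default_factory=dict)
    n_skipped: int = 0


def error_reduction(model_accuracy: float, baseline_accuracy: float) -> float:
    """Fractional reduction of the model's error relative to the
    baseline's: (e_b - e_m) / e_b with e = 1 - accuracy."""
    e_b = 1.0 - baseline_accuracy
    if e_b <= 0.0:
        raise ValueError("baseline accuracy is 1; error reduction undefined")
    return (e_b - (1.0 - model_accuracy)) / e_b


def baseline_majority(train_labels: Sequence[int], test: Sequence[SequenceSample]) -> BaselineReport:
    """Constant prediction of the larger training class (ties -> NFLD)."""
    y_train = np.asarray(train_labels, dtype=int)
    counts = np.bincount(y_train, minlength=2)[:2]
    if counts.min() == 0:
        raise ValueError("both classes must be present in the training labels")
    if counts[0] == counts[1]:
        warnings.warn("exact class tie in training labels; predicting NFLD")
        majority = NFLD
    else:
        majority = int(np.argmax(counts))
    y_true = np.array([s.target for s in test], dtype=int)
    y_pred = np.full(len(y_true), majority)
    return BaselineReport("majority", EvalReport.from_predictions(y_true, y_pred))


def baseline_persistence(test: Sequence[SequenceSample]) -> BaselineReport:
    """Predict the anchor (previous) visit's label for every sample."""
    y_true, y_pred, skipped = [], [], 0
    for s in test:
        if s.anchor_label is None:
            skipped += 1
            continue
        y_true.append(s.target)
        y_pred.append(s.anchor_label)
    if skipped:
        warnings.warn(f"{skipped} samples without an anchor label skipped")
    return BaselineReport(
        "persistence",
        EvalReport.from_predictions(np.array(y_true, dtype=int), np.array(y_pred, dtype=int)),
        n_skipped=skipped,
    )


def evaluate_nvp(model: TrainedModel, test: Sequence[SequenceSample]) -> EvalReport:
    """EvalReport of a trained sequence model on test samples (FLD
    positive; scores drive the AUROC)."""
    if not test:
        raise ValueError("test set must be non-empty")
    scores, labels = predict(model, test)
    y_true = np.array([s.target for s in test], dtype=int)
    return EvalReport.from_predictions(y_true, labels, scores)


def compare_to_baseline(
    model_reports: Mapping[str, EvalReport],
    baseline_report: BaselineReport,
) -> BaselineReport:
    """Attach per-model error reduction rates to a baseline report."""
    out = BaselineReport(baseline_report.baseline, baseline_report.report, n_skipped=baseline_report.n_skipped)
    for name, rep in model_reports.items():
        out.error_reduction_by_model[name] = error_reduction(rep.accuracy, baseline_report.report.accuracy)
    return out


__all__ = [
    "BaselineReport",
    "error_reduction",
    "baseline_majority",
    "baseline_persistence",
    "evaluate_nvp",
    "compare_to_baseline",
]
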