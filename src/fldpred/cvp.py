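"""Current-visit prediction (CVP) experiments.

Classify FLD status from the same visit's features: an eight-classifier
train/test harness, a training-year-window sweep against a fixed test
year, an age-threshold ("menopause/andropause") split analysis, and
class-imbalance diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .classifiers import decision_scores, make_classifier
from .metrics import EvalReport
from .preprocessing import FeatureTable


def train_eval_cvp(
    train: FeatureTable,
    test: FeatureTable,
    classifier: str,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
    knn_k: int = 1,
) -> EvalReport:
    """Fit on the training table only, report on the test table."""
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test tables must be non-empty")
    cols = list(features) if features is not None else train.feature_names
    missing = [c for c in cols if c not in test.X.columns]
    if missing:
        raise ValueError(f"test table lacks columns {missing}")
    y_train = train.y.to_numpy(dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_classifier(classifier, seed=seed, knn_k=knn_k)
    clf.fit(train.X[cols].to_numpy(dtype=float), y_train)
    Xte = test.X[cols].to_numpy(dtype=float)
    pred = clf.predict(Xte)
    scores = decision_scores(clf, Xte)
    return EvalReport.from_predictions(test.y.to_numpy(dtype=int), pred, scores)


@dataclass
class WindowSweepResult:
    windows: list[tuple[int, int, Optional[EvalReport]]]  # (start, end, report)
    best_window: tuple[int, int]

    def accuracies(self) -> dict[tuple[int, int], float]:
        return {(s, e): r.accuracy for s, e, r in self.windows if r is not None}


def year_window_sweep(
    tables_by_year: Mapping[int, FeatureTable],
    test_year: int,
    classifier: str,
    feature_selector: Optional[Callable[[FeatureTable], Sequence[str]]] = None,
    seed: int = 0,
    knn_k: int = 1,
) -> WindowSweepResult:
    """Sweep suffix training windows ending the year before the test
    year: (end), (end-1, end), ... down to the earliest year.  Feature
    selection, when given, runs on the training window only (the test
    year is firewalled).  Best window: max accuracy, ties to the longest
    window."""
    years = sorted(y for y in tables_by_year if y < test_year)
    if not years:
        raise ValueError("no training years before the test year")
    if test_year not in tables_by_year:
        raise ValueError(f"no table for test year {test_year}")
    end = years[-1]
    test = tables_by_year[test_year]
    results: list[tuple[int, int, Optional[EvalReport]]] = []
    for start in reversed(years):  # shortest window first
        span = [y for y in years if start <= y <= end]
        parts = [tables_by_year[y] for y in span]
        train = _concat_tables(parts)
        if len(train) == 0:
            warnings.warn(f"window {start}-{end} is empty; skipped")
            results.append((start, end, None))
            continue
        cols = list(feature_selector(train)) if feature_selector is not None else None
        report = train_eval_cvp(train, test, classifier, seed=seed, features=cols, knn_k=knn_k)
        results.append((start, end, report))
    scored = [(s, e, r) for s, e, r in results if r is not None]
    best = max(scored, key=lambda t: (t[2].accuracy, t[1] - t[0]))
    return WindowSweepResult(windows=results, best_window=(best[0], best[1]))


def _concat_tables(parts: Sequence[FeatureTable]) -> FeatureTable:
    import pandas as pd

    first = parts[0]
    return FeatureTable(
        pd.concat([p.X for p in parts], ignore_index=True),
        pd.concat([p.y for p in parts], ignore_index=True),
        pd.concat([p.meta for p in parts], ignore_index=True),
        first.schema,
        first.norm_stats,
    )


def menopause_split(
    table: FeatureTable,
    age_thresholds: Sequence[int] = (53, 54, 55, 56, 57),
    classifier: str = "gaussian_nb",
    train_years: Sequence[int] = (),
    test_year: int = 0,
    seed: int = 0,
) -> dict[int, tuple[Optional[EvalReport], Optional[EvalReport]]]:
    """Partition visits by age-at-visit below/at-or-above each threshold
    and run an independent train/test evaluation inside each side.  An
    empty or single-class side is reported as None."""
    age = (table.meta["visit_year"] - table.meta["birth_year"]).to_numpy()
    out: dict[int, tuple[Optional[EvalReport], Optional[EvalReport]]] = {}
    for thr in age_thresholds:
        reports = []
        for side_mask in (age < thr, age >= thr):
            sub = table.select_rows(side_mask)
            if len(sub) == 0:
                warnings.warn(f"threshold {thr}: empty side; reported as missing")
                reports.append(None)
                continue
            train = sub.rows_in_years(train_years)
            test = sub.rows_in_years([test_year])
            if len(train) == 0 or len(test) == 0 or train.y.nunique() < 2:
                warnings.warn(f"threshold {thr}: unusable train/test split; reported as missing")
                reports.append(None)
                continue
            reports.append(train_eval_cvp(train, test, classifier, seed=seed))
        out[thr] = (reports[0], reports[1])
    return out


def imbalance_factor(labels: Sequence[int]) -> float:
    """Size of the bigger class divided by the smaller; infinity when a
    class is absent."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)[:2]
    if counts.min() == 0:
        warnings.warn("one class absent; imbalance factor reported as infinity")
        return math.inf
    return float(counts.max() / counts.min())


__all__ = [
    "train_eval_cvp",
    "WindowSweepResult",
    "year_window_sweep",
    "menopause_split",
    "imbalance_factor",
]
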