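"""Wrapper feature selection.

Two wrapper schemes around a pluggable classifier and evaluation scheme:

* one-pass ranking (OPR): every feature is scored *alone* by the
  evaluation accuracy of the classifier trained on that single feature;
  features are ranked by score and the top-k taken.  Cost: exactly F
  evaluations for F features.
* sequential forward selection (SFS): greedy; at each step the feature
  whose addition maximizes evaluation accuracy joins the set.  Cost:
  sum_{i=0}^{k-1} (F - i) evaluations.

Agreement between a selected set S2 and an expert set S1 is measured by
IoU(S1,S2) = |S1 n S2| / |S1 u S2| and coverage(S1,S2) = |S1 n S2| / |S1|.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .classifiers import make_classifier
from .preprocessing import FeatureTable


@dataclass(frozen=True)
class EvalSpec:
    """Evaluation scheme for wrapper scoring.

    scheme: "loo" (leave-one-out), "kfold" (stratified k-fold) or
    "holdout" (explicit train/test row masks); metric is classification
    accuracy throughout.
    """

    scheme: str = "loo"
    k: int = 3
    train_rows: Optional[np.ndarray] = None
    test_rows: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("loo", "kfold", "holdout"):
            raise ValueError(f"unknown evaluation scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k-fold needs k >= 2")
        if self.scheme == "holdout" and (self.train_rows is None or self.test_rows is None):
            raise ValueError("holdout needs explicit train_rows and test_rows")


@dataclass
class SelectionResult:
    """Ranked features with scores and the selected top-k subset."""

    ranking: list[tuple[str, float]]  # OPR: per-feature accuracy; SFS: running accuracy
    selected: list[str]
    classifier: str
    eval_spec: EvalSpec
    elapsed_seconds: float
    n_evaluations: int

    @property
    def selected_set(self) -> frozenset[str]:
        return frozenset(self.selected)


def _loo_knn_accuracy(X: np.ndarray, y: np.ndarray, k: int) -> float:
    """Exact leave-one-out accuracy of k-NN: query k+1 neighbors on the
    full fit and discard the query point itself."""
    n = len(y)
    if n < 2:
        return float("nan")
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    _, idx = nn.kneighbors(X)
    votes = np.empty((n, min(k, n - 1)), dtype=int)
    for i in range(n):
        neigh = idx[i][idx[i] != i][: votes.shape[1]]
        if len(neigh) < votes.shape[1]:  # self not returned among ties
            neigh = idx[i][1:][: votes.shape[1]]
        votes[i] = y[neigh]
    frac = votes.mean(axis=1)
    pred = np.where(frac == 0.5, y[idx[:, 1] if idx.shape[1] > 1 else 0], (frac > 0.5).astype(int))
    return float((pred == y).mean())


def evaluate_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str,
    spec: EvalSpec,
    knn_k: int = 1,
) -> float:
    """Evaluation accuracy of ``classifier`` on (X, y) under ``spec``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if spec.scheme == "loo":
        if classifier == "knn":
            return _loo_knn_accuracy(X, y, knn_k)
        correct = 0
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            clf = make_classifier(classifier, seed=spec.seed, knn_k=knn_k)
            clf.fit(X[mask], y[mask])
            correct += int(clf.predict(X[i : i + 1])[0] == y[i])
        return correct / len(y)
    if spec.scheme == "kfold":
        cv = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
        accs = []
        for tr, te in cv.split(X, y):
            clf = make_classifier(classifier, seed=spec.seed, knn_k=knn_k)
            clf.fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        return float(np.mean(accs))
    # holdout
    tr = np.asarray(spec.train_rows, dtype=bool)
    te = np.asarray(spec.test_rows, dtype=bool)
    clf = make_classifier(classifier, seed=spec.seed, knn_k=knn_k)
    clf.fit(X[tr], y[tr])
    return float((clf.predict(X[te]) == y[te]).mean())


def _score_or_chance(X, y, classifier, spec, knn_k, feature_names) -> float:
    try:
        return evaluate_accuracy(X, y, classifier, spec, knn_k)
    except Exception as exc:  # classifier failure -> chance level
        warnings.warn(f"classifier failed on {feature_names}: {exc}; scored at chance")
        counts = np.bincount(np.asarray(y, dtype=int), minlength=2)
        return float(counts.max() / counts.sum())


def opr_rank(
    table: FeatureTable,
    classifier: str = "knn",
    eval_spec: EvalSpec = EvalSpec(),
    k: int = 24,
    features: Optional[Sequence[str]] = None,
    knn_k: int = 1,
) -> SelectionResult:
    """One-pass ranking: score each feature alone, rank by accuracy
    (descending, ties broken by schema order), select the top-k."""
    names = list(features) if features is not None else table.feature_names
    if k > len(names):
        raise ValueError(f"k={k} exceeds {len(names)} features")
    t0 = time.perf_counter()
    y = table.y.to_numpy(dtype=int)
    scores = []
    for name in names:
        x = table.X[name].to_numpy(dtype=float)[:, None]
        scores.append(_score_or_chance(x, y, classifier, eval_spec, knn_k, [name]))
    order = sorted(range(len(names)), key=lambda i: (-scores[i], i))  # stable tie-break
    ranking = [(names[i], scores[i]) for i in order]
    return SelectionResult(
        ranking=ranking,
        selected=[name for name, _ in ranking[:k]],
        classifier=classifier,
        eval_spec=eval_spec,
        elapsed_seconds=time.perf_counter() - t0,
        n_evaluations=len(names),
    )


def sfs_select(
    table: FeatureTable,
    classifier: str = "knn",
    eval_spec: EvalSpec = EvalSpec(),
    k: int = 24,
    features: Optional[Sequence[str]] = None,
    knn_k: int = 1,
) -> SelectionResult:
    """Sequential forward selection: greedily add the feature maximizing
    evaluation accuracy of the current set; stop at k features.  The
    ranking records inclusion order with the running accuracy."""
    names = list(features) if features is not None else table.feature_names
    if k > len(names):
        raise ValueError(f"k={k} exceeds {len(names)} features")
    t0 = time.perf_counter()
    y = table.y.to_numpy(dtype=int)
    selected: list[str] = []
    ranking: list[tuple[str, float]] = []
    remaining = list(names)
    n_evals = 0
    for _ in range(k):
        best_name, best_acc = None, -np.inf
        for name in remaining:  # schema order => stable tie-break via strict >
            cols = selected + [name]
            X = table.X[cols].to_numpy(dtype=float)
            acc = _score_or_chance(X, y, classifier, eval_spec, knn_k, cols)
            n_evals += 1
            if acc > best_acc:
                best_name, best_acc = name, acc
        selected.append(best_name)
        remaining.remove(best_name)
        ranking.append((best_name, best_acc))
    return SelectionResult(
        ranking=ranking,
        selected=selected,
        classifier=classifier,
        eval_spec=eval_spec,
        elapsed_seconds=time.perf_counter() - t0,
        n_evaluations=n_evals,
    )


def iou(s1, s2) -> float:
    """Intersection over union of two feature sets; empty-vs-empty is 1."""
    s1, s2 = set(s1), set(s2)
    union = s1 | s2
    if not union:
        warnings.warn("IoU of two empty sets defined as 1")
        return 1.0
    return len(s1 & s2) / len(union)


def coverage(s1_expert, s2) -> float:
    """Fraction of the expert set covered by the selected set."""
    s1, s2 = set(s1_expert), set(s2)
    if not s1:
        raise ValueError("expert feature set must be non-empty")
    return len(s1 & s2) / len(s1)


__all__ = [
    "EvalSpec",
    "SelectionResult",
    "evaluate_accuracy",
    "opr_rank",
    "sfs_select",
    "iou",
    "coverage",
]
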