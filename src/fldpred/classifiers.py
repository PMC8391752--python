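"""Registry of the cross-sectional classifiers used by the current-visit
prediction harness and the feature-selection wrappers.

Hyperparameters are library defaults with fixed seeds; "c45_tree" is an
entropy-criterion decision tree (an approximation of C4.5 on numeric
inputs) and "cart_tree" the Gini-criterion tree.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_NAMES = (
    "knn",
    "adaboost",
    "svm",
    "logistic",
    "random_forest",
    "gaussian_nb",
    "c45_tree",
    "cart_tree",
)


def make_classifier(name: str, seed: int = 0, knn_k: int = 1) -> Any:
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "svm":
        return SVC(random_state=seed)
    if name == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "c45_tree":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if name == "cart_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def decision_scores(model: Any, X: np.ndarray) -> np.ndarray:
    """Continuous scores for AUROC: predicted class-1 probability where
    available (k-NN vote fractions included), else a squashed decision
    function, else the hard labels."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "decision_function"):
        raw = np.asarray(model.decision_function(X), dtype=float)
        return 1.0 / (1.0 + np.exp(-raw))
    return np.asarray(model.predict(X), dtype=float)


__all__ = ["CLASSIFIER_NAMES", "make_classifier", "decision_scores"]
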