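"""Patch-level tissue classification over the six fixed categories.

The classification stage is an interface with two small backends: a
multinomial logistic model on patch embedding vectors (default, fast) and
a multilayer perceptron on raw pixel patches.  Evaluation reports one-vs-
rest AUC per class (midrank tie handling) and a 6x6 confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from .tilemap import BLANK, CATEGORIES, TissueMap, ValueGrid

N_CLASSES = len(CATEGORIES)


@dataclass
class PatchDataset:
    """Feature vectors (or raw patches) with integer labels 0..5."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.y) and not ((self.y >= 0) & (self.y < N_CLASSES)).all():
            raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")

    @property
    def flat_x(self) -> np.ndarray:
        return self.x.reshape(len(self.x), -1)


@dataclass
class PatchClassifier:
    """Fitted backend plus the class bookkeeping to expose all six classes."""

    backend: str
    estimator: object = field(repr=False)
    n_features: int = 0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(len(x), -1)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dim {x.shape[1]} != trained dim {self.n_features}")
        raw = self.estimator.predict_proba(x)
        probs = np.zeros((len(x), N_CLASSES))
        for j, cls in enumerate(self.estimator.classes_):
            probs[:, int(cls)] = raw[:, j]
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)


def fit_patch_classifier(train: PatchDataset, backend: str = "logistic",
                         seed: int = 0) -> PatchClassifier:
    """Train a patch classifier; deterministic under the seed."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set contains a single class")
    x = train.flat_x
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite training features")
    if backend == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif backend == "mlp":
        est = MLPClassifier(hidden_layer_sizes=(32, 16), max_iter=500,
                            random_state=seed)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    est.fit(x, train.y)
    return PatchClassifier(backend, est, x.shape[1])


def predict_patch_labels(model: PatchClassifier, features: np.ndarray,
                         cells: np.ndarray, grid_shape: tuple[int, int],
                         slide_id: str = "slide",
                         patch_size: int = 150) -> tuple[TissueMap, ValueGrid]:
    """Argmax labels written into a TissueMap; cells not covered stay Blank.

    Returns the labeled map plus a ValueGrid of the winning probability.
    """
    labels = np.full(grid_shape, BLANK, dtype=object)
    conf = np.full(grid_shape, np.nan)
    features = np.asarray(features, dtype=float)
    if len(features):
        probs = model.predict_proba(features)
        winners = np.argmax(probs, axis=1)
        for (r, c), k, p in zip(np.asarray(cells, dtype=int), winners,
                                probs[np.arange(len(winners)), winners]):
            labels[r, c] = CATEGORIES[k]
            conf[r, c] = p
    return (TissueMap(slide_id, labels, patch_size),
            ValueGrid(slide_id, conf))


@dataclass
class ClassifierReport:
    per_class_auc: dict[str, float]     # NaN when the class is absent
    macro_auc: float
    confusion: np.ndarray               # rows = truth, cols = prediction

    def to_json(self) -> str:
        return json.dumps({
            "per_class_auc": {k: (None if np.isnan(v) else v)
                              for k, v in self.per_class_auc.items()},
            "macro_auc": self.macro_auc,
            "confusion": self.confusion.tolist(),
            "classes": list(CATEGORIES),
        }, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(CATEGORIES),
                            columns=list(CATEGORIES))


def evaluate_patch_classifier(model: PatchClassifier,
                              test: PatchDataset) -> ClassifierReport:
    """One-vs-rest AUC per class and the 6x6 confusion matrix."""
    if len(test.y) == 0:
        raise ValueError("test set is empty")
    probs = model.predict_proba(test.flat_x)
    pred = np.argmax(probs, axis=1)
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(test.y, pred):
        confusion[t, p] += 1
    aucs: dict[str, float] = {}
    for k, name in enumerate(CATEGORIES):
        truth = (test.y == k).astype(int)
        if truth.min() == truth.max():   # class absent (or only class)
            aucs[name] = float("nan")
            continue
        aucs[name] = float(roc_auc_score(truth, probs[:, k]))
    defined = [v for v in aucs.values() if not np.isnan(v)]
    macro = float(np.mean(defined)) if defined else float("nan")
    return ClassifierReport(aucs, macro, confusion)
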