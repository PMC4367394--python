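"""k-NN classification (k = 3, Euclidean) and evaluation measures.

The three labeling tasks — normal/abnormal beats, high/low signal quality,
static/non-static activity — all use the same instance-based classifier.
Positive/negative conventions: positive = abnormal beat, low quality,
non-static activity; negative = normal beat, high quality, static activity.

:class:`TieBreakKNN` is a scikit-learn-compatible estimator (fit/predict,
``get_params``/``set_params``), so it composes with sklearn pipelines and
model selection. Neighbour search is delegated to
:class:`sklearn.neighbors.NearestNeighbors`; the vote is implemented here
because the tie-breaking contract is part of this package's behaviour:
nearer-neighbour-first majority, with any residual tie resolved to the
negative (non-alarming) class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import ContextError, beat_feature_matrix
from .preprocess import TimeSeries
from .qrs import BeatAnnotation

UNCLASSIFIED = "unclassified"

#: MIT-BIH beat symbols regarded as normal (non-ectopic, supraventricular
#: ectopic, fusion, unknown AAMI classes) vs. abnormal (ventricular
#: ectopic: flutter/fibrillation, ventricular escape, PVC).
MITBIH_NORMAL_SYMBOLS = frozenset("NLRjeaSAJF/Qf")
MITBIH_ABNORMAL_SYMBOLS = frozenset("VE!")

#: paced records excluded from MIT-BIH-style evaluation
PACED_RECORDS = ("102", "104", "107", "217")

#: 22 + 22 record split used for beat-classifier training and testing
DS1_TRAIN_RECORDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
DS1_TEST_RECORDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)


def map_mitbih_symbol(symbol: str) -> str:
    """Map one MIT-BIH beat annotation symbol to 'normal' or 'abnormal'."""
    if symbol in MITBIH_ABNORMAL_SYMBOLS:
        return "abnormal"
    if symbol in MITBIH_NORMAL_SYMBOLS:
        return "normal"
    raise ValueError(f"unrecognized MIT-BIH beat symbol: {symbol!r}")


class TieBreakKNN(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbour classifier with deterministic tie-breaking.

    Parameters
    ----------
    k : int, default 3
        Number of neighbours (Euclidean distance).
    negative_label : object, optional
        Label returned when the vote among the k neighbours remains tied
        after the nearer-neighbour-first rule; defaults to the
        lexicographically smaller class. Set it to the task's non-alarming
        class for conservative alarm behaviour.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    n_features_in_ : int
    """

    def __init__(self, k: int = 3, negative_label=None):
        self.k = k
        self.negative_label = negative_label

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.k < 1 or self.k > X.shape[0]:
            raise ValueError(f"k={self.k} out of range for {X.shape[0]} samples")
        self.classes_ = np.unique(y)
        self._y = np.asarray(y)
        self._nn = NearestNeighbors(n_neighbors=self.k).fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _vote(self, dist: np.ndarray, labels: np.ndarray):
        """Majority vote; ties go to the nearer neighbour's label, then to
        the negative class."""
        uniq, counts = np.unique(labels, return_counts=True)
        winners = uniq[counts == counts.max()]
        if winners.size == 1:
            return winners[0]
        # nearer-neighbour-first: labels arrive sorted by distance; the
        # first tied label whose distance is strictly smallest wins
        order = np.argsort(dist, kind="stable")
        best = {}
        for j in order:
            if labels[j] in winners and labels[j] not in best:
                best[labels[j]] = dist[j]
        dmin = min(best.values())
        nearest = [lab for lab, d in best.items() if d == dmin]
        if len(nearest) == 1:
            return nearest[0]
        if self.negative_label is not None and self.negative_label in nearest:
            return self.negative_label
        return sorted(nearest)[0]

    def predict(self, X):
        check_is_fitted(self, "_nn")
        X = check_array(X)
        dist, ind = self._nn.kneighbors(X)
        return np.array([
            self._vote(dist[i], self._y[ind[i]]) for i in range(X.shape[0])
        ])


def knn_predict(train_X, train_y, query, k: int = 3, negative_label=None):
    """Label one query vector by k-NN majority over a training set."""
    query = np.atleast_2d(query)
    clf = TieBreakKNN(k=k, negative_label=negative_label).fit(train_X, train_y)
    out = clf.predict(query)
    return out[0] if out.shape[0] == 1 else out


def classify_beats(model: TieBreakKNN, x: TimeSeries,
                   beats: Sequence[BeatAnnotation]) -> list[str]:
    """Per-beat normal/abnormal labels.

    Beat ``i`` is classified from features spanning beats i-2 ... i+1;
    boundary beats without that context are marked ``'unclassified'`` and
    never alarm.
    """
    labels = [UNCLASSIFIED] * len(beats)
    try:
        F, idx = beat_feature_matrix(x, list(beats))
    except ContextError:
        return labels
    if F.shape[0] == 0:
        return labels
    pred = model.predict(F)
    for j, i in enumerate(idx):
        labels[i] = str(pred[j])
    return labels


def classify_segments(model: TieBreakKNN, features: np.ndarray) -> np.ndarray:
    """Per-5-s-segment labels (quality or activity task)."""
    features = np.atleast_2d(features)
    if features.shape[0] == 0:
        return np.empty(0, dtype=object)
    return model.predict(features)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with the task's positive/negative convention."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion_from_labels(pred, truth, positive) -> ConfusionMatrix:
    """Count TP/TN/FP/FN between aligned prediction and truth sequences."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth, strict=True):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, tn, fp, fn)


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy.

    A zero denominator yields ``None`` (reported as "N/A"); an all-zero
    matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sen = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    acc = (cm.tp + cm.tn) / cm.total
    return {"sen": sen, "spec": spec, "acc": acc}


def format_metrics(cm: ConfusionMatrix) -> dict[str, str]:
    """Metrics as 2-decimal percentage strings; undefined values as 'N/A'."""
    m = metrics(cm)
    return {
        key: ("N/A" if v is None else f"{100 * v:.2f}%")
        for key, v in m.items()
    }
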