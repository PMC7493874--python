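"""Evaluation statistics for binary virtual-screening classifiers.

Scalar metrics (balanced accuracy, sensitivity, specificity, F1, MCC) are
computed from a 2x2 confusion matrix; threshold-free metrics (AUC, binary
cross-entropy) and the enrichment factor work on raw scores.

The enrichment factor EF p% is the early-recognition metric of virtual
screening: rank the test set by predicted activity probability, take the
top p% window, and count how many truly active compounds it contains.  The
percentage reported alongside the count is the hit count divided by the
best achievable count in that window, min(window, P).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary classifier's outcomes (positive = active)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise MetricError(f"{name} must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class RankedScreen:
    """Compounds ordered by descending predicted activity probability.

    Built from unordered (id, score, label) triples; sorting is stable so
    ties keep the input order.  Labels: 1 = active, 0 = inactive.
    """

    ids: tuple[str, ...]
    scores: tuple[float, ...]
    labels: tuple[int, ...]

    @classmethod
    def from_predictions(
        cls,
        ids: Sequence[str],
        scores: Sequence[float],
        labels: Sequence[int],
    ) -> "RankedScreen":
        if not (len(ids) == len(scores) == len(labels)):
            raise MetricError("ids/scores/labels length mismatch")
        if len(ids) == 0:
            raise MetricError("empty screen")
        scores_arr = np.asarray(scores, dtype=float)
        order = np.argsort(-scores_arr, kind="stable")
        return cls(
            ids=tuple(str(ids[i]) for i in order),
            scores=tuple(float(scores_arr[i]) for i in order),
            labels=tuple(int(labels[i]) for i in order),
        )

    def __post_init__(self):
        if any(s2 > s1 for s1, s2 in zip(self.scores, self.scores[1:])):
            raise MetricError("scores must be non-increasing")
        if not set(self.labels) <= {0, 1}:
            raise MetricError("labels must be binary")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_active(self) -> int:
        return int(sum(self.labels))


@dataclass(frozen=True)
class EnrichmentResult:
    """EF p%: hits among the top-``window`` ranked compounds."""

    p_percent: float
    window: int
    hits: int
    percent: float


def confusion(labels_true: Sequence[int], labels_pred: Sequence[int]) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix (1 = active = positive)."""
    yt = np.asarray(labels_true)
    yp = np.asarray(labels_pred)
    if yt.shape != yp.shape:
        raise MetricError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (set(np.unique(yt)) | set(np.unique(yp))) <= {0, 1}:
        raise MetricError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """True positive rate TP/P."""
    if cm.p == 0:
        raise MetricError("sensitivity undefined: no positives")
    return cm.tp / cm.p


def specificity(cm: ConfusionMatrix) -> float:
    """True negative rate TN/N."""
    if cm.n == 0:
        raise MetricError("specificity undefined: no negatives")
    return cm.tn / cm.n


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """bACC = (TP/P + TN/N) / 2 — robust to class imbalance."""
    return (sensitivity(cm) + specificity(cm)) / 2


def f1(cm: ConfusionMatrix) -> float:
    """F1 = harmonic mean of precision and recall."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise MetricError("F1 undefined: no positives predicted or labeled")
    return 2 * cm.tp / denom


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1].

    For a 2x2 table |MCC| = sqrt(chi2 / n) with chi2 the Pearson statistic.
    A degenerate margin (all-one-class truths or predictions) makes MCC
    undefined; it is returned as 0 with a warning.
    """
    num = cm.tp * cm.tn - cm.fp * cm.fn
    den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if den == 0:
        warnings.warn("degenerate confusion-matrix margin; MCC set to 0")
        return 0.0
    return num / math.sqrt(den)


def bce_loss(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mean binary cross-entropy; probabilities clipped to [1e-7, 1-1e-7]."""
    p = np.clip(np.asarray(scores, dtype=float), 1e-7, 1 - 1e-7)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise MetricError("length mismatch")
    if p.size == 0:
        raise MetricError("empty input")
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random active outranks a random inactive (ties count 1/2).

    Computed from midranks (Mann-Whitney), equivalent to the area under the
    ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: only one class present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def enrichment_factor(screen: RankedScreen, p_percent: float) -> EnrichmentResult:
    """Hits among the top p% of the ranked screen.

    window = floor(p * n / 100); hits = actives in the window;
    percent = 100 * hits / min(window, P) where P is the total active count
    (so a window larger than P can still reach 100%).
    """
    if not 0 < p_percent <= 100:
        raise MetricError(f"p_percent must be in (0, 100], got {p_percent}")
    n = len(screen)
    window = math.floor(p_percent * n / 100)
    if window == 0:
        raise MetricError(
            f"EF window is empty at p={p_percent}% of n={n}; "
            "use a larger percentage or a larger screen"
        )
    hits = int(sum(screen.labels[:window]))
    denom = min(window, screen.n_active)
    if denom == 0:
        raise MetricError("screen contains no actives")
    return EnrichmentResult(
        p_percent=float(p_percent),
        window=window,
        hits=hits,
        percent=100.0 * hits / denom,
    )


def evaluation_report(
    labels_true: Sequence[int],
    scores: Sequence[float],
    *,
    threshold: float = 0.5,
) -> dict[str, float]:
    """All scalar metrics for one model on one test set."""
    preds = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    cm = confusion(labels_true, preds)
    return {
        "balanced_accuracy": balanced_accuracy(cm),
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "loss": bce_loss(scores, labels_true),
        "auc": auc(scores, labels_true),
        "f1": f1(cm),
        "mcc": mcc(cm),
    }
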