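"""Shallow reference models: RBF-kernel SVM and Random Forest.

Both consume the same signed {-1,+1} fingerprint representation the
convolutional classifiers use, and default to the FeatMorgan fingerprint,
the best-performing type for these models.  Scheme-specific
hyperparameters: scheme 1 uses SVM(C=5, gamma=1) and a 100-tree Gini
forest; scheme 2 uses SVM(C=1, gamma=0.1) and a 2-tree Gini forest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .fingerprints import FingerprintType


class BaselineError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineSpec:
    """Hyperparameters of one shallow baseline.

    SVM fields (C, gamma) are None for a forest and vice versa
    (n_estimators, criterion).
    """

    kind: str  # "svm_rbf" or "random_forest"
    fp_type: FingerprintType = FingerprintType.FEATMORGAN
    C: float | None = None
    gamma: float | None = None
    n_estimators: int | None = None
    criterion: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("svm_rbf", "random_forest"):
            raise BaselineError(f"unknown baseline kind {self.kind!r}")
        if self.kind == "svm_rbf":
            if self.C is None or self.gamma is None:
                raise BaselineError("svm_rbf needs C and gamma")
            if self.n_estimators is not None or self.criterion is not None:
                raise BaselineError("forest fields must be null for svm_rbf")
        else:
            if self.n_estimators is None:
                raise BaselineError("random_forest needs n_estimators")
            if self.C is not None or self.gamma is not None:
                raise BaselineError("SVM fields must be null for random_forest")

    @classmethod
    def for_scheme(cls, kind: str, scheme: int, *,
                   fp_type: FingerprintType = FingerprintType.FEATMORGAN,
                   seed: int = 0) -> "BaselineSpec":
        """The per-scheme defaults of each baseline."""
        if scheme not in (1, 2):
            raise BaselineError("scheme must be 1 or 2")
        if kind == "svm_rbf":
            C, gamma = (5.0, 1.0) if scheme == 1 else (1.0, 0.1)
            return cls(kind=kind, fp_type=fp_type, C=C, gamma=gamma, seed=seed)
        if kind == "random_forest":
            n = 100 if scheme == 1 else 2
            return cls(kind=kind, fp_type=fp_type, n_estimators=n,
                       criterion="gini", seed=seed)
        raise BaselineError(f"unknown baseline kind {kind!r}")


@dataclass
class TrainedBaseline:
    spec: BaselineSpec
    estimator: object


def train_baseline(
    spec: BaselineSpec,
    x_train: np.ndarray,
    y_train: Sequence[int],
) -> TrainedBaseline:
    """Fit the baseline on signed fingerprints of ``spec.fp_type``."""
    x = np.asarray(x_train, dtype=np.float32)
    y = np.asarray(y_train, dtype=int)
    if x.shape[0] != y.size:
        raise BaselineError("feature/label length mismatch")
    if np.unique(y).size < 2:
        raise BaselineError("training set contains a single class")
    if spec.kind == "svm_rbf":
        # probability=True gives Platt-calibrated scores for EF ranking
        est = SVC(
            kernel="rbf",
            C=spec.C,
            gamma=spec.gamma,
            probability=True,
            random_state=spec.seed,
        )
    else:
        est = RandomForestClassifier(
            n_estimators=spec.n_estimators,
            criterion=spec.criterion or "gini",
            random_state=spec.seed,
        )
    est.fit(x, y)
    return TrainedBaseline(spec=spec, estimator=est)


def predict_baseline(model: TrainedBaseline, x: np.ndarray) -> np.ndarray:
    """Activity probabilities in [0,1], order-preserving; empty in, empty out."""
    x = np.asarray(x, dtype=np.float32)
    if x.shape[0] == 0:
        return np.zeros(0)
    n_feat = getattr(model.estimator, "n_features_in_", None)
    if n_feat is not None and x.shape[1] != n_feat:
        raise BaselineError(f"expected {n_feat} features, got {x.shape[1]}")
    proba = model.estimator.predict_proba(x)
    classes = list(model.estimator.classes_)
    return proba[:, classes.index(1)]
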