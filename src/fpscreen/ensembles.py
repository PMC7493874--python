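"""Ensembles over the seven per-fingerprint 1D CNNs.

Two schemes.  *Voting* collects the hard 0/1 labels of the best 1D CNN
per fingerprint type and returns the majority label — membership is odd
(7), so a majority always exists.  *Tuned-MLP-Out* retrains seven
higher-capacity 1D CNNs (512/256/128/64 filters) from scratch, freezes
them, and feeds their seven output probabilities into a small one-hidden-
layer MLP head trained per task: 3 ReLU units / lr 1e-3 / Adam for
discrimination, 5 units / lr 1e-4 / Adamax for active-only selection.
Its sigmoid output gives the probabilities used for enrichment ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fingerprints import FingerprintType
from .models import (
    MEMBER_FILTERS,
    CnnSpec,
    TrainedModel,
    predict_scores,
    train,
)
from .nn import (
    Dense,
    EarlyStopConfig,
    Network,
    ReLU,
    TrainingHistory,
    fit_network,
    make_optimizer,
)


class EnsembleError(ValueError):
    pass


def majority_vote(member_labels: Sequence[int]) -> int:
    """Label held by at least 4 of exactly 7 binary member labels."""
    if len(member_labels) != 7:
        raise EnsembleError(f"expected 7 member labels, got {len(member_labels)}")
    votes = [int(l) for l in member_labels]
    if not set(votes) <= {0, 1}:
        raise EnsembleError("member labels must be binary 0/1")
    return int(sum(votes) >= 4)


@dataclass(frozen=True)
class TunedMlpOutConfig:
    """Per-task head settings for the stacked ensemble."""

    task: str
    hidden_units: int
    head_lr: float
    optimizer_name: str


TASKS = {
    "discrimination": TunedMlpOutConfig("discrimination", 3, 1e-3, "adam"),
    "active_only": TunedMlpOutConfig("active_only", 5, 1e-4, "adamax"),
}


def assemble_tuned_mlp_out(task: str) -> TunedMlpOutConfig:
    """Head configuration for DISCRIMINATION or ACTIVE_ONLY screening."""
    key = task.lower()
    if key not in TASKS:
        raise EnsembleError(f"unknown task {task!r}; known: {sorted(TASKS)}")
    return TASKS[key]


def _check_members(members: Mapping[FingerprintType, TrainedModel]) -> None:
    missing = set(FingerprintType) - set(members)
    if missing:
        raise EnsembleError(
            f"missing member fingerprint types: {sorted(t.value for t in missing)}"
        )


@dataclass
class VotingEnsemble:
    """Hard-majority vote over seven per-type 1D CNNs at threshold 0.5."""

    members: dict[FingerprintType, TrainedModel]
    decision_threshold: float = 0.5

    def __post_init__(self):
        _check_members(self.members)

    def predict_labels(self, x_by_type: Mapping[FingerprintType, np.ndarray]) -> np.ndarray:
        votes = _member_matrix(self.members, x_by_type) >= self.decision_threshold
        return (votes.sum(axis=1) >= 4).astype(int)


def _member_matrix(
    members: Mapping[FingerprintType, TrainedModel],
    x_by_type: Mapping[FingerprintType, np.ndarray],
) -> np.ndarray:
    """(n, 7) member probabilities, columns in canonical type order."""
    missing = set(members) - set(x_by_type)
    if missing:
        raise EnsembleError(
            f"missing fingerprints for types: {sorted(t.value for t in missing)}"
        )
    cols = [
        predict_scores(members[t], np.asarray(x_by_type[t]))
        for t in FingerprintType.canonical()
    ]
    return np.stack(cols, axis=1)


@dataclass
class TunedMlpOut:
    """Frozen member CNNs plus a trained one-hidden-layer probability head."""

    members: dict[FingerprintType, TrainedModel]
    head: Network
    config: TunedMlpOutConfig
    head_history: TrainingHistory | None = None

    def __post_init__(self):
        _check_members(self.members)

    def predict_proba(self, x_by_type: Mapping[FingerprintType, np.ndarray]) -> np.ndarray:
        probs = _member_matrix(self.members, x_by_type)
        return self.head.predict_proba(probs.astype(np.float32))


def member_spec(seed: int = 0, **overrides) -> CnnSpec:
    """Spec of one Tuned-MLP-Out member CNN (512/256/128/64 filters)."""
    kwargs = dict(
        dimensionality="1D",
        conv_filters=MEMBER_FILTERS,
        kernel=3,
        seed=seed,
    )
    kwargs.update(overrides)
    return CnnSpec(**kwargs)


def build_head(config: TunedMlpOutConfig, seed: int = 0) -> Network:
    """7 member probabilities -> hidden ReLU layer -> sigmoid output."""
    return Network(
        [Dense(7, config.hidden_units), ReLU(), Dense(config.hidden_units, 1)],
        seed=seed,
    )


def train_stacked(
    task: str,
    x_train_by_type: Mapping[FingerprintType, np.ndarray],
    y_train: Sequence[int],
    x_val_by_type: Mapping[FingerprintType, np.ndarray],
    y_val: Sequence[int],
    *,
    member_max_epochs: int = 100,
    member_patience: int = 10,
    head_max_epochs: int = 300,
    head_patience: int = 30,
    member_spec_overrides: dict | None = None,
    seed: int = 0,
) -> TunedMlpOut:
    """Two-phase training of the stacked ensemble.

    Phase 1: each member is trained from scratch on its own fingerprint
    type (early-stopped on the task's monitor).  Phase 2: members are
    frozen and the head is trained on their seven output probabilities,
    early-stopped on validation loss — the head is tiny and its
    thresholded metrics move only once the loss has dropped, so loss is
    the informative monitor.
    """
    config = assemble_tuned_mlp_out(task)
    monitor = "sensitivity" if config.task == "active_only" else "balanced_accuracy"
    _check_members_input(x_train_by_type)
    _check_members_input(x_val_by_type)

    members: dict[FingerprintType, TrainedModel] = {}
    for i, fp_type in enumerate(FingerprintType.canonical()):
        spec = member_spec(seed=seed + i, **(member_spec_overrides or {}))
        members[fp_type] = train(
            spec,
            np.asarray(x_train_by_type[fp_type]),
            y_train,
            np.asarray(x_val_by_type[fp_type]),
            y_val,
            max_epochs=member_max_epochs,
            patience=member_patience,
            monitor=monitor,
        )

    train_probs = _member_matrix(members, x_train_by_type).astype(np.float32)
    val_probs = _member_matrix(members, x_val_by_type).astype(np.float32)
    head = build_head(config, seed=seed + 100)
    optimizer = make_optimizer(config.optimizer_name, config.head_lr)
    head_history = fit_network(
        head,
        optimizer,
        train_probs,
        np.asarray(y_train),
        val_probs,
        np.asarray(y_val),
        max_epochs=head_max_epochs,
        batch_size=32,
        early_stop=EarlyStopConfig(monitor="loss", patience=head_patience),
        seed=seed + 100,
    )
    return TunedMlpOut(members=members, head=head, config=config,
                       head_history=head_history)


def _check_members_input(x_by_type: Mapping[FingerprintType, np.ndarray]) -> None:
    missing = set(FingerprintType) - set(x_by_type)
    if missing:
        raise EnsembleError(
            f"missing fingerprint type(s): {sorted(t.value for t in missing)}"
        )
    lengths = {np.asarray(v).shape[0] for v in x_by_type.values()}
    if len(lengths) > 1:
        raise EnsembleError(f"member feature sets differ in length: {sorted(lengths)}")


def predict_ensemble(
    model: VotingEnsemble | TunedMlpOut,
    x_by_type: Mapping[FingerprintType, np.ndarray],
) -> np.ndarray:
    """Voting emits hard labels; Tuned-MLP-Out emits probabilities."""
    if isinstance(model, VotingEnsemble):
        return model.predict_labels(x_by_type)
    if isinstance(model, TunedMlpOut):
        return model.predict_proba(x_by_type)
    raise EnsembleError(f"unknown ensemble type: {type(model).__name__}")


def write_manifest(
    path: str | Path,
    *,
    member_paths: Mapping[FingerprintType, str],
    config: TunedMlpOutConfig | None = None,
    task: str | None = None,
) -> None:
    """Ensemble manifest: member model paths, types, head config, task."""
    payload = {
        "members": {t.value: str(p) for t, p in member_paths.items()},
        "task": task if config is None else config.task,
        "head": None
        if config is None
        else {
            "hidden_units": config.hidden_units,
            "head_lr": config.head_lr,
            "optimizer": config.optimizer_name,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
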