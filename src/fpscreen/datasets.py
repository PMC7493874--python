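"""Training/validation/test splits, cross-validation folds, ratio resampling.

Two training schemes are supported.  Scheme 1 is the classic
discrimination setup: a stratified 80/10/10 split that preserves the
global active:inactive ratio (about 1:10 in a typical screening set) in
every partition.  Scheme 2 emulates early screening: the data are divided
into two nearly equal parts (48% training, 52% test), with the training
part enriched in actives (90% of them) while the test part is left scarce
(about 2% actives), and the training part further split 90/10 into train
and validation.  Both schemes use stratified 10-fold cross-validation
folds over the training ids.

Ratio stress sets (1:20, 1:50, 1:100) are built by subsampling actives
while keeping every inactive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


class SplitError(ValueError):
    pass


class Scheme(Enum):
    SCHEME1 = "scheme1"
    SCHEME2 = "scheme2"


# Scheme-2 quotas, expressed as class proportions so they transfer to data
# sets of any size: 90% of actives and 2720/6360 of inactives go to the
# training part, the rest to the test part.
SCHEME2_TRAIN_ACTIVE_FRAC = 720 / 800
SCHEME2_TRAIN_INACTIVE_FRAC = 2720 / 6360


@dataclass(frozen=True)
class SplitSpec:
    scheme: Scheme
    fractions: tuple[float, ...]
    seed: int
    active_ratio_test: float | None = None


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test id sets plus CV fold assignments."""

    train: list[str]
    validation: list[str]
    test: list[str]
    fold_assignments: dict[str, int]
    spec: SplitSpec | None = None
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise SplitError("partitions overlap")
        missing = set(self.train) - set(self.fold_assignments)
        if missing:
            raise SplitError(f"{len(missing)} train ids lack a fold assignment")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": self.train,
            "validation": self.validation,
            "test": self.test,
            "fold_assignments": self.fold_assignments,
            "class_counts": self.class_counts,
            "spec": None
            if self.spec is None
            else {
                "scheme": self.spec.scheme.value,
                "fractions": list(self.spec.fractions),
                "seed": self.spec.seed,
                "active_ratio_test": self.spec.active_ratio_test,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        spec = None
        if d.get("spec"):
            spec = SplitSpec(
                scheme=Scheme(d["spec"]["scheme"]),
                fractions=tuple(d["spec"]["fractions"]),
                seed=d["spec"]["seed"],
                active_ratio_test=d["spec"]["active_ratio_test"],
            )
        return cls(
            train=d["train"],
            validation=d["validation"],
            test=d["test"],
            fold_assignments={k: int(v) for k, v in d["fold_assignments"].items()},
            spec=spec,
            class_counts=d.get("class_counts", {}),
        )


def _check_ids_labels(ids: Sequence[str], labels: Sequence[int]):
    ids = [str(i) for i in ids]
    labels = np.asarray(labels, dtype=int)
    if len(ids) != labels.size:
        raise SplitError("ids/labels length mismatch")
    if len(set(ids)) != len(ids):
        raise SplitError("duplicate compound ids")
    if not set(np.unique(labels)) <= {0, 1}:
        raise SplitError("labels must be binary 0/1")
    return ids, labels


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n items to fractions, totals exact."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def _counts(ids: Sequence[str], label_of: Mapping[str, int]) -> dict[str, int]:
    act = sum(label_of[i] for i in ids)
    return {"active": act, "inactive": len(ids) - act, "total": len(ids)}


def scheme1_split(
    ids: Sequence[str],
    labels: Sequence[int],
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_folds: int = 10,
) -> DatasetSplit:
    """Stratified train/validation/test split preserving the class ratio.

    Every partition's active:inactive ratio stays within one sample of the
    global ratio.  Deterministic under a fixed seed.
    """
    ids, labels = _check_ids_labels(ids, labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], [], []]
    for cls in (1, 0):
        cls_ids = [i for i, l in zip(ids, labels) if l == cls]
        if len(cls_ids) < 10:
            raise SplitError(
                f"class {cls} has only {len(cls_ids)} members; "
                "need >= 10 for a stratified 80/10/10 split"
            )
        perm = rng.permutation(len(cls_ids))
        alloc = _largest_remainder(len(cls_ids), fractions)
        start = 0
        for part, count in zip(parts, alloc):
            part.extend(cls_ids[j] for j in perm[start : start + count])
            start += count
    train, validation, test = parts
    label_of = dict(zip(ids, labels.tolist()))
    folds = make_folds(train, [label_of[i] for i in train], k=n_folds, seed=seed)
    return DatasetSplit(
        train=train,
        validation=validation,
        test=test,
        fold_assignments=folds,
        spec=SplitSpec(Scheme.SCHEME1, tuple(fractions), seed),
        class_counts={
            "train": _counts(train, label_of),
            "validation": _counts(validation, label_of),
            "test": _counts(test, label_of),
        },
    )


def scheme2_split(
    ids: Sequence[str],
    labels: Sequence[int],
    seed: int,
    n_folds: int = 10,
) -> DatasetSplit:
    """Early-screening split: training enriched in actives, test left scarce.

    90% of actives and 2720/6360 of inactives form the training part
    (further split 90/10 into train and validation); the rest is the test
    part.  On an 800-active / 6360-inactive data set this reproduces the
    720-of-3440 training and 80-of-3720 test composition exactly.
    """
    ids, labels = _check_ids_labels(ids, labels)
    rng = np.random.default_rng(seed)
    train_part: list[str] = []
    test: list[str] = []
    for cls, frac in ((1, SCHEME2_TRAIN_ACTIVE_FRAC), (0, SCHEME2_TRAIN_INACTIVE_FRAC)):
        cls_ids = [i for i, l in zip(ids, labels) if l == cls]
        if len(cls_ids) < 10:
            raise SplitError(f"class {cls} has only {len(cls_ids)} members")
        perm = rng.permutation(len(cls_ids))
        n_train = round(len(cls_ids) * frac)
        train_part.extend(cls_ids[j] for j in perm[:n_train])
        test.extend(cls_ids[j] for j in perm[n_train:])
    label_of = dict(zip(ids, labels.tolist()))
    # 90/10 train/validation inside the training part, stratified.
    train: list[str] = []
    validation: list[str] = []
    for cls in (1, 0):
        cls_ids = [i for i in train_part if label_of[i] == cls]
        perm = rng.permutation(len(cls_ids))
        n_val = round(len(cls_ids) * 0.1)
        validation.extend(cls_ids[j] for j in perm[:n_val])
        train.extend(cls_ids[j] for j in perm[n_val:])
    folds = make_folds(train, [label_of[i] for i in train], k=n_folds, seed=seed)
    counts = {
        "train": _counts(train, label_of),
        "validation": _counts(validation, label_of),
        "test": _counts(test, label_of),
        "training_part": _counts(train_part, label_of),
    }
    return DatasetSplit(
        train=train,
        validation=validation,
        test=test,
        fold_assignments=folds,
        spec=SplitSpec(Scheme.SCHEME2, (0.48, 0.52), seed),
        class_counts=counts,
    )


def make_folds(
    train_ids: Sequence[str],
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
) -> dict[str, int]:
    """Stratified k-fold assignment; fold sizes differ by at most one.

    Ids are shuffled within each class and dealt round-robin across folds,
    which balances both the overall fold sizes and the per-class counts.
    Fold indices are 1-based (1..k).
    """
    ids, labels = _check_ids_labels(train_ids, labels)
    if k > len(ids):
        raise SplitError(f"k={k} exceeds number of train ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    dealt: list[str] = []
    for cls in (1, 0):
        cls_ids = [i for i, l in zip(ids, labels) if l == cls]
        perm = rng.permutation(len(cls_ids))
        dealt.extend(cls_ids[j] for j in perm)
    return {cid: (pos % k) + 1 for pos, cid in enumerate(dealt)}


def resample_ratio(
    ids: Sequence[str],
    labels: Sequence[int],
    ratio_r: int,
    seed: int,
) -> tuple[list[str], list[int]]:
    """Subsample to an active:inactive ratio of 1:ratio_r.

    All inactives are kept and actives are subsampled to round(N_inactive
    / r); if that would require more actives than exist, all actives are
    kept and inactives are subsampled to r * N_active instead.
    """
    ids, labels = _check_ids_labels(ids, labels)
    if ratio_r < 1:
        raise SplitError("ratio_r must be >= 1")
    rng = np.random.default_rng(seed)
    act = [i for i, l in zip(ids, labels) if l == 1]
    inact = [i for i, l in zip(ids, labels) if l == 0]
    n_act_target = round(len(inact) / ratio_r)
    if n_act_target == 0:
        raise SplitError(
            f"inactive class too small: {len(inact)} inactives cannot "
            f"support a 1:{ratio_r} ratio"
        )
    if n_act_target <= len(act):
        keep_act = [act[j] for j in rng.permutation(len(act))[:n_act_target]]
        keep_inact = inact
    else:
        keep_act = act
        n_inact_target = ratio_r * len(act)
        keep_inact = [inact[j] for j in rng.permutation(len(inact))[:n_inact_target]]
    out_ids = keep_act + keep_inact
    out_labels = [1] * len(keep_act) + [0] * len(keep_inact)
    return out_ids, out_labels


def deduplicate_by_smiles(
    ids: Sequence[str], smiles: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Drop duplicate compounds by canonical SMILES, keeping first occurrence."""
    from .fingerprints import canonical_smiles

    seen: set[str] = set()
    out_ids, out_smiles = [], []
    for cid, smi in zip(ids, smiles):
        can = canonical_smiles(smi)
        if can in seen:
            continue
        seen.add(can)
        out_ids.append(str(cid))
        out_smiles.append(smi)
    return out_ids, out_smiles
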