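"""IC50-based activity labeling via one-dimensional K-means.

There is no universally agreed IC50 cut-off between active and inactive
compounds (below 1 uM is clearly active, above 10 uM clearly inactive),
so the threshold is derived from the data: two-cluster K-means on the raw
IC50 values, with the threshold placed at the average of the two cluster
centroids.  An elbow (WCSS) curve supports the choice of two clusters.
The threshold is a data artifact and is persisted alongside the dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


class LabelingError(ValueError):
    pass


class Activity(Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


@dataclass
class ActivityRecord:
    """One compound's measured potency and (optionally) its binary label."""

    compound_id: str
    ic50: float | None
    label: Activity | None = None

    def __post_init__(self):
        if self.ic50 is not None:
            if not np.isfinite(self.ic50):
                self.ic50 = None
            elif self.ic50 <= 0:
                raise LabelingError(
                    f"ic50 must be positive, got {self.ic50} for {self.compound_id}"
                )


@dataclass(frozen=True)
class ElbowCurve:
    """WCSS (within-cluster sum of squares) as a function of cluster count."""

    k_values: tuple[int, ...]
    wcss: tuple[float, ...]


@dataclass(frozen=True)
class ThresholdModel:
    """Two-cluster activity threshold in uM.

    threshold = (centroid_active + centroid_inactive) / 2;
    upper_bound_active = largest IC50 in the active cluster;
    lower_bound_inactive = smallest IC50 in the inactive cluster.
    """

    centroid_active: float
    centroid_inactive: float
    threshold: float
    upper_bound_active: float
    lower_bound_inactive: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        return cls(**json.loads(Path(path).read_text()))


def _kmeans_1d(values: np.ndarray, k: int, seed: int, n_restarts: int = 10) -> KMeans:
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        tol=1e-6,
        random_state=seed,
        max_iter=500,
    )
    km.fit(values.reshape(-1, 1))
    return km


def wcss_curve(values: Sequence[float], k_max: int, seed: int = 0) -> ElbowCurve:
    """Best-of-restarts WCSS for k = 1..k_max (the elbow diagnostic)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise LabelingError("empty input")
    if k_max < 2:
        raise LabelingError("k_max must be >= 2")
    if arr.size < k_max:
        raise LabelingError(f"need at least k_max={k_max} values, got {arr.size}")
    ks, wcss = [], []
    for k in range(1, k_max + 1):
        if k == 1:
            inertia = float(((arr - arr.mean()) ** 2).sum())
        elif k >= np.unique(arr).size:
            inertia = 0.0
        else:
            inertia = float(_kmeans_1d(arr, k, seed).inertia_)
        ks.append(k)
        wcss.append(inertia)
    return ElbowCurve(k_values=tuple(ks), wcss=tuple(wcss))


def fit_threshold(values: Sequence[float], seed: int = 0) -> ThresholdModel:
    """Two-cluster K-means on raw IC50 values; threshold = centroid average.

    Lloyd's algorithm with 10 restarts and tolerance 1e-6.  In one
    dimension the optimal two-cluster partition is a contiguous split of
    the sorted values, which restarted K-means finds reliably.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise LabelingError("need at least 2 distinct values to fit a threshold")
    km = _kmeans_1d(arr, 2, seed)
    centers = km.cluster_centers_.ravel()
    lo_cluster = int(np.argmin(centers))
    active_vals = arr[km.labels_ == lo_cluster]
    inactive_vals = arr[km.labels_ != lo_cluster]
    c_act = float(centers[lo_cluster])
    c_inact = float(centers[1 - lo_cluster])
    return ThresholdModel(
        centroid_active=c_act,
        centroid_inactive=c_inact,
        threshold=(c_act + c_inact) / 2,
        upper_bound_active=float(active_vals.max()),
        lower_bound_inactive=float(inactive_vals.min()),
    )


def assign_labels(
    records: Sequence[ActivityRecord], threshold: float
) -> tuple[list[ActivityRecord], int]:
    """Label records ACTIVE iff ic50 <= threshold (boundary inclusive).

    Records with a missing IC50 are excluded; the count of dropped records
    is returned alongside the labeled ones.
    """
    if threshold <= 0:
        raise LabelingError("threshold must be positive")
    labeled: list[ActivityRecord] = []
    dropped = 0
    for rec in records:
        if rec.ic50 is None:
            dropped += 1
            continue
        labeled.append(
            ActivityRecord(
                compound_id=rec.compound_id,
                ic50=rec.ic50,
                label=Activity.ACTIVE if rec.ic50 <= threshold else Activity.INACTIVE,
            )
        )
    return labeled, dropped


def records_from_frame(df: pd.DataFrame) -> list[ActivityRecord]:
    """ActivityRecords from a DataFrame with ``id`` and ``ic50_um`` columns."""
    out = []
    for _, row in df.iterrows():
        ic50 = row.get("ic50_um")
        out.append(
            ActivityRecord(
                compound_id=str(row["id"]),
                ic50=None if pd.isna(ic50) else float(ic50),
            )
        )
    return out


def labeled_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """DataFrame with id, ic50_um, label (1 = active) columns."""
    return pd.DataFrame(
        {
            "id": [r.compound_id for r in records],
            "ic50_um": [r.ic50 for r in records],
            "label": [
                None if r.label is None else int(r.label is Activity.ACTIVE)
                for r in records
            ],
        }
    )
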