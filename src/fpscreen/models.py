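"""1D and 2D convolutional classifiers over signed fingerprints.

Both networks share one layout: four convolution+ReLU+max-pool blocks, a
flatten, a three-layer dense head of 1024/512/256 ReLU units (dropout
after each), and a single sigmoid output.  The 1D network consumes one
1024-long signed fingerprint; the 2D network consumes a k x 1024 stacked
fingerprint matrix and differs only in its kernel shape, where the second
kernel extent runs across the (small) fingerprint-type axis.

Direct classifiers default to 128/64/32/16 filters per layer; the
higher-capacity members of the stacked ensemble use 512/256/128/64.
Hyperparameters are explored with a grid search scored by k-fold
cross-validation of either balanced accuracy (discrimination) or
sensitivity (active-only early screening).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn import (
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    EarlyStopConfig,
    Flatten,
    MaxPool1D,
    MaxPool2D,
    Network,
    ReLU,
    ShapeError,
    TrainingHistory,
    fit_network,
    make_optimizer,
)
from .datasets import make_folds

DIRECT_FILTERS = (128, 64, 32, 16)
MEMBER_FILTERS = (512, 256, 128, 64)
HEAD_UNITS = (1024, 512, 256)
KERNELS_1D = (2, 3, 4)
KERNELS_2D = (
    (20, 2), (20, 1), (15, 2), (15, 1), (5, 2),
    (5, 1), (4, 2), (4, 1), (3, 2), (3, 1),
)


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class CnnSpec:
    """Full hyperparameter description of one convolutional classifier."""

    dimensionality: str = "1D"  # "1D" or "2D"
    conv_filters: tuple[int, int, int, int] = DIRECT_FILTERS
    kernel: int | tuple[int, int] = 3
    padding_mode: str = "same"
    dropout_p: float = 0.2
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    batch_size: int = 32
    seed: int = 0
    head_units: tuple[int, int, int] = HEAD_UNITS
    pool: int = 2

    def __post_init__(self):
        if self.dimensionality not in ("1D", "2D"):
            raise SpecError(f"dimensionality must be 1D or 2D, got {self.dimensionality!r}")
        if len(self.conv_filters) != 4:
            raise SpecError("exactly 4 convolutional layers are required")
        if self.dimensionality == "1D":
            if not isinstance(self.kernel, int) or self.kernel not in KERNELS_1D:
                raise SpecError(f"1D kernel must be one of {KERNELS_1D}")
        else:
            k = tuple(self.kernel) if not isinstance(self.kernel, int) else None
            if k not in KERNELS_2D:
                raise SpecError(f"2D kernel must be one of {KERNELS_2D}")
            object.__setattr__(self, "kernel", k)
        if self.padding_mode not in ("same", "valid"):
            raise SpecError("padding_mode must be 'same' or 'valid'")
        if not 0.2 <= self.dropout_p <= 0.9:
            raise SpecError("dropout_p must be in [0.2, 0.9]")
        if self.learning_rate <= 0:
            raise SpecError("learning_rate must be positive")
        if self.batch_size < 1:
            raise SpecError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        d["head_units"] = list(self.head_units)
        d["kernel"] = list(self.kernel) if isinstance(self.kernel, tuple) else self.kernel
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CnnSpec":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        d["head_units"] = tuple(d.get("head_units", HEAD_UNITS))
        if isinstance(d["kernel"], list):
            d["kernel"] = tuple(d["kernel"])
        return cls(**d)


@dataclass
class TrainedModel:
    """A trained classifier: spec, network with best-epoch weights, history."""

    spec: CnnSpec
    network: Network
    history: TrainingHistory
    k_rows: int | None = None

    @property
    def best_epoch(self) -> int:
        return self.history.best_epoch


def _head_layers(flat_dim: int, spec: CnnSpec) -> list:
    layers: list = [Flatten()]
    n_in = flat_dim
    for units in spec.head_units:
        layers += [Dense(n_in, units), ReLU(), Dropout(spec.dropout_p)]
        n_in = units
    layers.append(Dense(n_in, 1))
    return layers


def build_cnn1d(spec: CnnSpec, input_length: int = 1024) -> Network:
    """Four Conv1D+ReLU+MaxPool blocks, dense head, one sigmoid output.

    Parameter count and all intermediate shapes are pure functions of the
    spec; a kernel larger than the remaining spatial extent raises
    :class:`ShapeError` at build time.
    """
    if spec.dimensionality != "1D":
        raise SpecError("build_cnn1d needs a 1D spec")
    layers: list = []
    length = input_length
    c_in = 1
    for f in spec.conv_filters:
        conv = Conv1D(c_in, f, spec.kernel, spec.padding_mode)
        length = conv.out_length(length)
        layers += [conv, ReLU(), MaxPool1D(spec.pool)]
        length //= spec.pool
        if length < 1:
            raise ShapeError("spatial extent exhausted before the dense head")
        c_in = f
    layers += _head_layers(length * c_in, spec)
    return Network(layers, seed=spec.seed)


def build_cnn2d(spec: CnnSpec, k_rows: int, input_length: int = 1024) -> Network:
    """2D variant for a k_rows x 1024 fingerprint matrix (2 <= k_rows <= 7).

    Kernels are (bits-extent, rows-extent); 2x2 pooling stops acting on
    the row axis once only one row remains.
    """
    if spec.dimensionality != "2D":
        raise SpecError("build_cnn2d needs a 2D spec")
    if not 2 <= k_rows <= 7:
        raise SpecError(f"k_rows must be in 2..7, got {k_rows}")
    kw, kh = spec.kernel  # (along bits, across rows)
    layers: list = []
    h, w = k_rows, input_length
    c_in = 1
    for f in spec.conv_filters:
        if spec.padding_mode == "valid" and (kh > h or kw > w):
            raise ShapeError(
                f"kernel ({kw},{kh}) exceeds remaining extent ({w},{h})"
            )
        conv = Conv2D(c_in, f, (kh, kw), spec.padding_mode)
        h, w = conv.out_shape(h, w)
        layers += [conv, ReLU(), MaxPool2D((spec.pool, spec.pool))]
        h = max(h // spec.pool, 1) if h >= spec.pool else h
        w //= spec.pool
        if w < 1:
            raise ShapeError("spatial extent exhausted before the dense head")
        c_in = f
    layers += _head_layers(h * w * c_in, spec)
    return Network(layers, seed=spec.seed)


def build_network(spec: CnnSpec, k_rows: int | None = None) -> Network:
    if spec.dimensionality == "1D":
        return build_cnn1d(spec)
    if k_rows is None:
        raise SpecError("2D spec needs k_rows")
    return build_cnn2d(spec, k_rows)


def _as_input(x: np.ndarray, dimensionality: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if dimensionality == "1D":
        if x.ndim == 2:
            x = x[:, :, None]
        if x.ndim != 3 or x.shape[2] != 1:
            raise ShapeError(f"1D input must be (n, length[, 1]), got {x.shape}")
    else:
        if x.ndim == 3:
            x = x[:, :, :, None]
        if x.ndim != 4 or x.shape[3] != 1:
            raise ShapeError(f"2D input must be (n, k, length[, 1]), got {x.shape}")
    return x


def train(
    spec: CnnSpec,
    x_train: np.ndarray,
    y_train: Sequence[int],
    x_val: np.ndarray,
    y_val: Sequence[int],
    *,
    max_epochs: int = 100,
    patience: int = 10,
    monitor: str = "balanced_accuracy",
    k_rows: int | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """Build and train a classifier; returns the best-checkpoint model.

    ``monitor`` selects the early-stopping objective: balanced accuracy
    for discrimination, sensitivity for active-only screening.
    """
    seed = spec.seed if seed is None else seed
    x_train = _as_input(x_train, spec.dimensionality)
    x_val = _as_input(x_val, spec.dimensionality)
    if spec.dimensionality == "2D" and k_rows is None:
        k_rows = x_train.shape[1]
    network = build_network(replace(spec, seed=seed), k_rows)
    optimizer = make_optimizer(spec.optimizer_name, spec.learning_rate)
    history = fit_network(
        network,
        optimizer,
        x_train,
        np.asarray(y_train),
        x_val,
        np.asarray(y_val),
        max_epochs=max_epochs,
        batch_size=spec.batch_size,
        early_stop=EarlyStopConfig(monitor=monitor, patience=patience),
        seed=seed,
    )
    return TrainedModel(spec=spec, network=network, history=history, k_rows=k_rows)


def predict_scores(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Activity probabilities in [0,1], order-preserving; empty in, empty out."""
    x = _as_input(x, model.spec.dimensionality)
    if (
        model.spec.dimensionality == "2D"
        and x.shape[0]
        and x.shape[1] != model.k_rows
    ):
        raise ShapeError(f"expected {model.k_rows} fingerprint rows, got {x.shape[1]}")
    return model.network.predict_proba(x)


# ---------------------------------------------------------------------------
# Hyperparameter grid


def _decade_ladder(lo: float, hi: float) -> list[float]:
    out = []
    v = lo
    while v <= hi * (1 + 1e-9):
        out.append(v)
        v *= 10
    return out


@dataclass(frozen=True)
class GridSpace:
    """The hyperparameter grid, enumerable before launch.

    The first-layer filter count is drawn from ``filters`` with each
    following layer at half the previous one (the pattern of both stated
    architectures).
    """

    filters: tuple[int, ...] = (1024, 512, 256, 128, 64, 32, 16)
    learning_rates: tuple[float, ...] = tuple(
        sorted(set(_decade_ladder(1e-6, 1.0)) | set(_decade_ladder(2e-5, 0.2)))
    )
    dropouts: tuple[float, ...] = tuple(round(0.2 + 0.1 * i, 1) for i in range(8))
    kernels_1d: tuple[int, ...] = KERNELS_1D
    kernels_2d: tuple[tuple[int, int], ...] = KERNELS_2D
    batch_sizes: tuple[int, ...] = (8, 16, 32, 64, 128)
    optimizers: tuple[str, ...] = ("sgd", "rmsprop", "adagrad", "adam", "adamax")
    paddings: tuple[str, ...] = ("same",)

    def size(self, dimensionality: str = "1D") -> int:
        kernels = self.kernels_1d if dimensionality == "1D" else self.kernels_2d
        return (
            len(self.filters)
            * len(self.learning_rates)
            * len(self.dropouts)
            * len(kernels)
            * len(self.batch_sizes)
            * len(self.optimizers)
            * len(self.paddings)
        )

    def enumerate(self, dimensionality: str = "1D", seed: int = 0):
        """Yield CnnSpecs in deterministic lexicographic order."""
        kernels = self.kernels_1d if dimensionality == "1D" else self.kernels_2d
        for f0, lr, dp, k, bs, opt, pad in itertools.product(
            self.filters, self.learning_rates, self.dropouts,
            kernels, self.batch_sizes, self.optimizers, self.paddings,
        ):
            yield CnnSpec(
                dimensionality=dimensionality,
                conv_filters=(f0, max(f0 // 2, 1), max(f0 // 4, 1), max(f0 // 8, 1)),
                kernel=k,
                padding_mode=pad,
                dropout_p=dp,
                learning_rate=lr,
                optimizer_name=opt,
                batch_size=bs,
                seed=seed,
            )


@dataclass
class GridResult:
    spec: CnnSpec
    mean_objective: float
    fold_objectives: list[float]
    order_evaluated: int


def grid_search(
    specs,
    x: np.ndarray,
    y: Sequence[int],
    *,
    objective: str = "balanced_accuracy",
    budget: int | None = None,
    cv_folds: int = 10,
    max_epochs: int = 10,
    patience: int = 2,
    k_rows: int | None = None,
    seed: int = 0,
) -> list[GridResult]:
    """Evaluate specs by k-fold cross-validated mean of the objective.

    ``specs`` is any iterable of CnnSpec (e.g. ``GridSpace.enumerate()``);
    at most ``budget`` specs are evaluated, in iteration order, and the
    full leaderboard is returned sorted best-first.
    """
    if objective not in ("balanced_accuracy", "sensitivity"):
        raise SpecError(f"unknown objective {objective!r}")
    if budget is not None and budget < 1:
        raise SpecError("budget must be >= 1")
    y = np.asarray(y, dtype=int)
    ids = [str(i) for i in range(y.size)]
    folds = make_folds(ids, y, k=cv_folds, seed=seed)
    fold_of = np.array([folds[i] for i in ids])

    results: list[GridResult] = []
    for order, spec in enumerate(itertools.islice(specs, budget)):
        fold_scores = []
        for f in range(1, cv_folds + 1):
            val_mask = fold_of == f
            model = train(
                spec,
                x[~val_mask],
                y[~val_mask],
                x[val_mask],
                y[val_mask],
                max_epochs=max_epochs,
                patience=patience,
                monitor=objective,
                k_rows=k_rows,
                seed=seed + f,
            )
            fold_scores.append(model.history.val_metric[model.best_epoch - 1])
        results.append(
            GridResult(
                spec=spec,
                mean_objective=float(np.mean(fold_scores)),
                fold_objectives=fold_scores,
                order_evaluated=order,
            )
        )
    if not results:
        raise SpecError("empty grid: nothing to evaluate")
    results.sort(key=lambda r: (-r.mean_objective, r.order_evaluated))
    return results


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Weights as .npz with a JSON sidecar holding spec + history."""
    path = Path(path)
    weights = model.network.get_weights()
    np.savez(path, *weights)
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "spec": model.spec.to_dict(),
        "k_rows": model.k_rows,
        "history": model.history.as_dict(),
    }
    npz.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    meta = json.loads(npz.with_suffix(".json").read_text())
    spec = CnnSpec.from_dict(meta["spec"])
    network = build_network(spec, meta.get("k_rows"))
    with np.load(npz) as data:
        network.set_weights([data[k] for k in data.files])
    hist = TrainingHistory()
    for k, v in meta["history"].items():
        setattr(hist, k, v)
    return TrainedModel(spec=spec, network=network, history=hist,
                        k_rows=meta.get("k_rows"))
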