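"""A sequential network of layers with a sigmoid/BCE output head.

The final layer is expected to produce one logit per sample; the sigmoid
is folded into the loss gradient for numerical stability, and
:meth:`Network.predict_proba` applies it explicitly.
"""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Network:
    """Sequential container with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        self.seed = seed
        rng = np.random.default_rng(seed)
        for layer in layers:
            layer.initialize(rng)

    # -- passes -----------------------------------------------------------

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid probabilities, one per sample, computed in batches."""
        x = np.asarray(x, dtype=np.float32)
        if x.shape[0] == 0:
            return np.zeros(0)
        chunks = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], training=False)
            chunks.append(sigmoid(logits.reshape(-1)))
        for layer in self.layers:
            layer.release()
        return np.concatenate(chunks)

    # -- parameters -------------------------------------------------------

    def parameters(self):
        """Yield (layer, attribute-name) pairs for every trainable array."""
        for layer in self.layers:
            for name in layer.params():
                yield layer, name

    def param_count(self) -> int:
        return sum(getattr(layer, name).size for layer, name in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        pairs = list(self.parameters())
        if len(weights) != len(pairs):
            raise ValueError("weight list does not match network parameters")
        for (layer, name), w in zip(pairs, weights):
            current = getattr(layer, name)
            if current.shape != w.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {current.shape} vs {w.shape}"
                )
            setattr(layer, name, w.astype(np.float32).copy())

    def clone_weights(self) -> list[np.ndarray]:
        return copy.deepcopy(self.get_weights())
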