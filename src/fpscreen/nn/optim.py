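"""First-order optimizers operating on a network's (layer, name) parameters.

State (momenta, second moments) is keyed by parameter position, so an
optimizer instance is bound to one network for its lifetime.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.t = 0

    def step(self, network) -> None:
        self.t += 1
        for idx, (layer, name) in enumerate(network.parameters()):
            grad = getattr(layer, "d" + name)
            param = getattr(layer, name)
            setattr(layer, name, self._update(idx, param, grad))

    def _update(self, idx: int, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float, momentum: float = 0.0):
        super().__init__(lr)
        self.momentum = momentum
        self._v: dict[int, np.ndarray] = {}

    def _update(self, idx, param, grad):
        if self.momentum:
            v = self._v.get(idx)
            v = grad if v is None else self.momentum * v + grad
            self._v[idx] = v
            grad = v
        return param - self.lr * grad


class RMSprop(Optimizer):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps
        self._s: dict[int, np.ndarray] = {}

    def _update(self, idx, param, grad):
        s = self._s.get(idx, np.zeros_like(param))
        s = self.rho * s + (1 - self.rho) * grad * grad
        self._s[idx] = s
        return param - self.lr * grad / (np.sqrt(s) + self.eps)


class Adagrad(Optimizer):
    def __init__(self, lr: float, eps: float = 1e-7):
        super().__init__(lr)
        self.eps = eps
        self._s: dict[int, np.ndarray] = {}

    def _update(self, idx, param, grad):
        s = self._s.get(idx, np.zeros_like(param))
        s = s + grad * grad
        self._s[idx] = s
        return param - self.lr * grad / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def _update(self, idx, param, grad):
        if idx not in self._m:
            self._m[idx] = np.zeros_like(param)
            self._v[idx] = np.zeros_like(param)
        m, v = self._m[idx], self._v[idx]
        # in-place moment updates to avoid per-step reallocations
        m *= self.beta1
        m += (1 - self.beta1) * grad
        v *= self.beta2
        v += (1 - self.beta2) * (grad * grad)
        step = np.sqrt(v / (1 - self.beta2**self.t))
        step += self.eps
        np.divide(m, step, out=step)
        step *= self.lr / (1 - self.beta1**self.t)
        param -= step
        return param


class Adamax(Optimizer):
    """Adam variant using the infinity norm for the second moment."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._u: dict[int, np.ndarray] = {}

    def _update(self, idx, param, grad):
        if idx not in self._m:
            self._m[idx] = np.zeros_like(param)
            self._u[idx] = np.zeros_like(param)
        m, u = self._m[idx], self._u[idx]
        m *= self.beta1
        m += (1 - self.beta1) * grad
        np.maximum(self.beta2 * u, np.abs(grad), out=u)
        step = u + self.eps
        np.divide(m, step, out=step)
        step *= self.lr / (1 - self.beta1**self.t)
        param -= step
        return param


OPTIMIZERS = {
    "sgd": SGD,
    "rmsprop": RMSprop,
    "adagrad": Adagrad,
    "adam": Adam,
    "adamax": Adamax,
}


def make_optimizer(name: str, lr: float, **kwargs) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; known: {sorted(OPTIMIZERS)}"
        ) from None
    return cls(lr, **kwargs)
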