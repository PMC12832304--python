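"""Minimal dense neural-network engine (forward, backward, Adam).

The networks used by the relation classifier are tiny (a two-layer encoder
and two small set-function heads), so layers are implemented directly on
numpy arrays with explicit backward passes.  Shapes follow the convention
(batch, features); parameters are float64 throughout so that gradient
checks against central finite differences are meaningful to ~1e-8.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "ReLU", "Dropout", "MLP", "Adam"]


class Linear:
    """Affine layer ``y = x W + b`` with uniform fan-in initialisation.

    Weights are drawn from U(-1/sqrt(n_in), 1/sqrt(n_in)) using the supplied
    generator so a run is fully reproducible from its seed.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError(
                f"input has {x.shape[-1]} features, layer expects {self.W.shape[0]}"
            )
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    # parameter access for the optimizer; biases are exempt from weight decay
    def params(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask

    def params(self):
        return []


class MLP:
    """A sequence of layers with a shared forward/backward protocol."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g, _ in self.params():
            g[...] = 0.0

    def weight_arrays(self):
        """The parameter tensors in a stable order (for checkpoint/serialise)."""
        return [p for p, _, _ in self.params()]

    def get_state(self):
        return [p.copy() for p in self.weight_arrays()]

    def set_state(self, state) -> None:
        for p, s in zip(self.weight_arrays(), state, strict=True):
            p[...] = s


class Adam:
    """Adam with classical L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in self.params]
        self.v = [np.zeros_like(p) for p, _, _ in self.params]

    def step(self) -> None:
        self.t += 1
        for i, (p, g, decay) in enumerate(self.params):
            grad = g + self.weight_decay * p if (decay and self.weight_decay) else g
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
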