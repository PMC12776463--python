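"""Minimal feed-forward neural-network layers with hand-written backpropagation.

The package trains a small multilayer perceptron (encoder plus outcome heads)
whose loss mixes factual prediction terms with a distributional balance
penalty on the latent batch.  Everything here is plain numpy: each layer
caches what its backward pass needs, and :class:`Adam` updates a flat list of
parameter slots.  Gradient correctness is asserted against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Linear",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Sequential",
    "Adam",
    "global_grad_norm",
    "clip_gradients",
]


class Param:
    """A trainable array with its gradient accumulator.

    ``decay`` marks whether the optimizer applies weight decay to this slot
    (weight matrices yes; biases and batch-norm scales no).
    """

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Linear:
    """Affine map ``y = x W + b`` with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)), decay=True)
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if x.shape[1] != self.W.value.shape[0]:
            raise ValueError(
                f"input has {x.shape[1]} features, layer expects {self.W.value.shape[0]}"
            )
        self._x = x if train else None
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class BatchNorm:
    """Batch normalization with running statistics for evaluation mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv_std
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._cache = (xhat, inv_std)
            return self.gamma.value * xhat + self.beta.value
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = g.shape[0]
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        dxhat = g * self.gamma.value
        # standard batch-norm backward, folded form
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class ReLU:
    params: list[Param] = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Dropout:
    params: list[Param] = []

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask


class Sequential:
    """A chain of layers sharing one forward/backward interface."""

    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


def global_grad_norm(params: list[Param]) -> float:
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad * p.grad))
    return float(np.sqrt(total))


def clip_gradients(params: list[Param], max_norm: float) -> float:
    """Scale all gradients jointly so the global L2 norm is at most max_norm.

    Returns the post-clipping global norm.
    """
    norm = global_grad_norm(params)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params:
            p.grad *= scale
        return max_norm
    return norm


class Adam:
    """Adam with decoupled-from-layer L2 weight decay added to the gradient."""

    def __init__(self, params: list[Param], lr: float = 2e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def add_weight_decay(self) -> None:
        if self.weight_decay == 0.0:
            return
        for p in self.params:
            if p.decay:
                p.grad += self.weight_decay * p.value

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
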