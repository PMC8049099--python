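"""Minimal fully-connected network engine (numpy).

Implements exactly what the component-specific autoencoders need: forward
evaluation, reverse-mode gradients (for Adam training and vector-Jacobian
products), full Jacobians, and the Adam optimizer. Weights are float32; all
hidden layers carry the configured nonlinearity except the middle bottleneck
layer, which is linear, and the output layer, which is linear.

The ReLU subgradient at exactly 0 treats the unit as inactive (derivative 0);
this only matters on a measure-zero set of inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "AdamState"]


def _act(name: str, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(a, 0.0)
    if name == "tanh":
        return np.tanh(a)
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, a: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Derivative at pre-activation ``a`` (``z`` is the activation output)."""
    if name == "relu":
        return (a > 0.0).astype(a.dtype)
    if name == "tanh":
        return 1.0 - z * z
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class MLP:
    """Fully-connected network ``dims[0] -> ... -> dims[-1]``.

    ``nonlinear`` flags which layer outputs get the activation; by default all
    hidden layers except the (middle) bottleneck, and never the output layer.
    """

    dims: list[int]
    activation: str = "relu"
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    nonlinear: list[bool] = field(default_factory=list)

    @classmethod
    def create(cls, dims: list[int], activation: str = "relu",
               rng: np.random.Generator | None = None,
               bottleneck: int | None = None) -> "MLP":
        """Fan-in-scaled (He) random initialization from ``rng``."""
        if len(dims) < 3:
            raise ValueError("need at least one hidden layer")
        rng = rng or np.random.default_rng(0)
        n_layers = len(dims) - 1
        if bottleneck is None:
            bottleneck = n_layers // 2 - 1  # layer producing the middle dim
        weights, biases, nonlinear = [], [], []
        for i in range(n_layers):
            w = rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                           size=(dims[i], dims[i + 1])).astype(np.float32)
            weights.append(w)
            biases.append(np.zeros(dims[i + 1], dtype=np.float32))
            nonlinear.append(i != bottleneck and i != n_layers - 1)
        return cls(dims=list(dims), activation=activation, weights=weights,
                   biases=biases, nonlinear=nonlinear)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def dtype(self) -> np.dtype:
        return self.weights[0].dtype

    def astype(self, dtype) -> "MLP":
        """Copy of the network with parameters cast to ``dtype``.

        Training runs in float32; cast to float64 for high-accuracy Jacobian
        or gradient evaluation.
        """
        return MLP(dims=list(self.dims), activation=self.activation,
                   weights=[w.astype(dtype) for w in self.weights],
                   biases=[b.astype(dtype) for b in self.biases],
                   nonlinear=list(self.nonlinear))

    def forward(self, x: np.ndarray, cache: bool = False):
        """Batched forward pass; ``x`` is (..., dims[0]).

        With ``cache=True`` returns ``(y, caches)`` where caches hold the
        pre-activations needed by :meth:`vjp` and :meth:`backward`.
        """
        z = np.asarray(x, dtype=self.dtype)
        pre, post = [], [z]
        for i in range(self.n_layers):
            a = z @ self.weights[i] + self.biases[i]
            z = _act(self.activation, a) if self.nonlinear[i] else a
            if cache:
                pre.append(a)
                post.append(z)
        return (z, (pre, post)) if cache else z

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, caches, dy: np.ndarray):
        """Gradients of ``sum(dy * y)`` w.r.t. weights, biases and input.

        Returns ``(dweights, dbiases, dx)``.
        """
        pre, post = caches
        delta = np.asarray(dy, dtype=self.dtype)
        dws = [None] * self.n_layers
        dbs = [None] * self.n_layers
        for i in range(self.n_layers - 1, -1, -1):
            if self.nonlinear[i]:
                delta = delta * _act_deriv(self.activation, pre[i], post[i + 1])
            dws[i] = post[i].reshape(-1, post[i].shape[-1]).T @ \
                delta.reshape(-1, delta.shape[-1])
            dbs[i] = delta.reshape(-1, delta.shape[-1]).sum(axis=0)
            delta = delta @ self.weights[i].T
        return dws, dbs, delta

    def vjp(self, caches, v: np.ndarray) -> np.ndarray:
        """Vector-Jacobian product ``v @ J`` (i.e. J^T v per sample), batched."""
        pre, post = caches
        delta = np.asarray(v, dtype=self.dtype)
        for i in range(self.n_layers - 1, -1, -1):
            if self.nonlinear[i]:
                delta = delta * _act_deriv(self.activation, pre[i], post[i + 1])
            delta = delta @ self.weights[i].T
        return delta

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Full Jacobian dy/dx at a single input ``x`` (dims[-1] x dims[0])."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 1:
            raise ValueError("jacobian expects a single input vector")
        _, (pre, post) = self.forward(x[None], cache=True)
        j = np.eye(self.dims[0], dtype=self.dtype)
        for i in range(self.n_layers):
            j = j @ self.weights[i]
            if self.nonlinear[i]:
                j = j * _act_deriv(self.activation, pre[i][0], post[i + 1][0])[None, :]
        return j.T  # (out, in)


@dataclass
class AdamState:
    """Adam optimizer state over an MLP's parameters."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)

    def step(self, model: MLP, dws: list, dbs: list) -> None:
        params = model.weights + model.biases
        grads = dws + dbs
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
            self._scratch = [np.empty_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        scale = np.asarray(-self.lr / b1t, dtype=params[0].dtype)
        vs = np.asarray(1.0 / np.sqrt(b2t), dtype=params[0].dtype)
        for p, g, m, v, s in zip(params, grads, self.m, self.v, self._scratch):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.multiply(g, g, out=s)
            v *= self.beta2
            s *= (1.0 - self.beta2)
            v += s
            np.sqrt(v, out=s)
            s *= vs
            s += self.eps
            np.divide(m, s, out=s)
            s *= scale
            p += s
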