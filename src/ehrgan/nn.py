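"""Small fully connected building blocks and an Adam optimizer.

Built on :mod:`ehrgan.autodiff`; shapes follow the (batch, features)
convention throughout.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Linear:
    """Affine map with Kaiming-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / in_dim)
        self.W = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.b = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.W), self.b)

    def parameters(self):
        return [self.W, self.b]


class BatchNorm:
    """1-D batch normalization with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = ad.mean(x, axis=0, keepdims=True)
            var = ad.mean(ad.power(ad.add(x, -mu), 2.0), axis=0, keepdims=True)
            with ad.no_grad():
                self.running_mean = (
                    (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
                )
                self.running_var = (
                    (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
                )
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = ad.mul(ad.add(x, -mu), ad.power(ad.add(var, self.eps), -0.5))
        return ad.add(ad.mul(xhat, self.gamma), self.beta)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.running_mean = np.asarray(state["running_mean"], dtype=np.float64)
        self.running_var = np.asarray(state["running_var"], dtype=np.float64)


class MLP:
    """Fully connected stack: hidden Linear(+BN)(+activation), linear head.

    activation: 'relu' | 'leaky_relu' | 'tanh'.
    """

    def __init__(
        self,
        in_dim: int,
        hidden: list[int],
        out_dim: int,
        rng: np.random.Generator,
        activation: str = "relu",
        batchnorm: bool = False,
    ):
        self.hidden_layers: list[Linear] = []
        self.norms: list[BatchNorm | None] = []
        prev = in_dim
        for width in hidden:
            self.hidden_layers.append(Linear(prev, width, rng))
            self.norms.append(BatchNorm(width) if batchnorm else None)
            prev = width
        self.head = Linear(prev, out_dim, rng)
        self.activation = activation

    def _act(self, x: Tensor) -> Tensor:
        if self.activation == "relu":
            return ad.relu(x)
        if self.activation == "leaky_relu":
            return ad.leaky_relu(x, 0.2)
        if self.activation == "tanh":
            return ad.tanh(x)
        raise ValueError(f"unknown activation {self.activation!r}")

    def forward(self, x: Tensor, training: bool = True, return_hidden: bool = False):
        h = x
        for layer, norm in zip(self.hidden_layers, self.norms):
            h = layer(h)
            if norm is not None:
                h = norm(h, training)
            h = self._act(h)
        out = self.head(h)
        if return_hidden:
            return out, h
        return out

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        return self.forward(x, training=training)

    def parameters(self):
        params = []
        for layer, norm in zip(self.hidden_layers, self.norms):
            params.extend(layer.parameters())
            if norm is not None:
                params.extend(norm.parameters())
        params.extend(self.head.parameters())
        return params

    def state(self):
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, norm in enumerate(self.norms):
            if norm is not None:
                arrays[f"bn{i}_mean"] = norm.running_mean
                arrays[f"bn{i}_var"] = norm.running_var
        return arrays

    def load_state(self, arrays):
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"p{i}"], dtype=np.float64).reshape(p.shape)
        for i, norm in enumerate(self.norms):
            if norm is not None:
                norm.load_state(
                    {"running_mean": arrays[f"bn{i}_mean"], "running_var": arrays[f"bn{i}_var"]}
                )


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
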