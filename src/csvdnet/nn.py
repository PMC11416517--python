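"""Minimal reverse-mode sequential network runtime for the 3D CNN.

Channels-last layout throughout: activations are (N, D, H, W, C) tensors.
The 3D convolution forward pass is computed as a sum of 27 shifted
matrix products (one per kernel offset); the backward pass accumulates
the corresponding transposed products, which is exactly the adjoint of
the forward map.  Every layer's backward pass is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import itertools
import json
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .architecture import ArchitectureSpec, he_init, sigmoid


class Layer:
    """Base layer: parameter dict + cached forward state for backward."""

    name: str = ""
    l2_coeff: float = 0.0

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    #: parameter keys subject to the L2 penalty
    l2_keys: Tuple[str, ...] = ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    l2_keys = ("W",)

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, l2_coeff: float = 0.0,
                 seed: int = 0, name: str = "conv"):
        super().__init__()
        self.name = name
        self.kernel = kernel
        self.l2_coeff = l2_coeff
        fan_in = kernel ** 3 * c_in
        self.params["W"] = he_init((kernel, kernel, kernel, c_in, c_out), fan_in, seed)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k = self.kernel
        W, b = self.params["W"], self.params["b"]
        n, d, h, w, _ = x.shape
        do, ho, wo = d - k + 1, h - k + 1, w - k + 1
        if min(do, ho, wo) < 1:
            raise ValueError(f"{self.name}: input {x.shape} smaller than kernel {k}")
        y = np.zeros((n, do, ho, wo, W.shape[-1]), dtype=x.dtype)
        for m, q, p in itertools.product(range(k), repeat=3):
            y += x[:, m : m + do, q : q + ho, p : p + wo, :] @ W[m, q, p]
        y += b
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.kernel
        x, W = self._x, self.params["W"]
        do, ho, wo = dy.shape[1:4]
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for m, q, p in itertools.product(range(k), repeat=3):
            xs = x[:, m : m + do, q : q + ho, p : p + wo, :]
            dW[m, q, p] = np.tensordot(xs, dy, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            dx[:, m : m + do, q : q + ho, p : p + wo, :] += dy @ W[m, q, p].T
        self.grads["W"] = dW + 2.0 * self.l2_coeff * W
        self.grads["b"] = dy.sum(axis=(0, 1, 2, 3))
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0, name: str = "elu"):
        super().__init__()
        self.alpha = alpha
        self.name = name

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._x_pos = x > 0
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * np.where(self._x_pos, 1.0, self._y + self.alpha)


class BatchNorm(Layer):
    """Channel-wise batch normalization with running statistics.

    Training mode standardizes with mini-batch moments; inference mode
    uses the (non-trainable) running mean/variance.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn"):
        super().__init__()
        self.name = name
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        self._training = training
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv, self._axes = xhat, inv, axes
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        gamma = self.params["gamma"]
        xhat, inv, axes = self._xhat, self._inv, self._axes
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        if not self._training:
            return dy * gamma * inv
        m = dy.size // dy.shape[-1]
        dxhat = dy * gamma
        return (inv / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class MaxPool3D(Layer):
    """2x2x2 (or k^3) max pooling, stride = window; odd remainders dropped."""

    def __init__(self, k: int = 2, name: str = "pool"):
        super().__init__()
        self.k = k
        self.name = name

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k = self.k
        n, d, h, w, c = x.shape
        do, ho, wo = d // k, h // k, w // k
        xc = x[:, : do * k, : ho * k, : wo * k, :]
        xr = xc.reshape(n, do, k, ho, k, wo, k, c)
        y = xr.max(axis=(2, 4, 6))
        # tie-splitting mask (subgradient); ties vanish a.s. for continuous inputs
        mask = xr == y[:, :, None, :, None, :, None, :]
        self._mask = mask
        self._count = mask.sum(axis=(2, 4, 6), keepdims=True)
        self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        n, do, ho, wo, c = dy.shape
        g = self._mask * (dy[:, :, None, :, None, :, None, :] / self._count)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : do * k, : ho * k, : wo * k, :] = g.reshape(n, do * k, ho * k, wo * k, c)
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    l2_keys = ("W",)

    def __init__(self, n_in: int, n_out: int, l2_coeff: float = 0.0, seed: int = 0,
                 name: str = "dense"):
        super().__init__()
        self.name = name
        self.l2_coeff = l2_coeff
        self.params["W"] = he_init((n_in, n_out), n_in, seed)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy + 2.0 * self.l2_coeff * self.params["W"]
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.name = name
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Network:
    """Ordered layer stack producing a single pre-sigmoid logit."""

    def __init__(self, layers: List[Layer], spec: Optional[ArchitectureSpec] = None):
        self.layers = layers
        self.spec = spec

    # -- construction ---------------------------------------------------
    @classmethod
    def from_spec(cls, spec: ArchitectureSpec, seed: int = 0) -> "Network":
        ss = np.random.SeedSequence(seed)
        init_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(64))
        layers: List[Layer] = []
        for ls in spec.layers:
            if ls.kind == "input":
                continue
            if ls.kind == "conv3d":
                layers.append(
                    Conv3D(ls.input_shape[-1], ls.filters_or_units, ls.kernel[0],
                           l2_coeff=ls.l2_coeff, seed=next(init_seeds), name=ls.name)
                )
                layers.append(ELU(name=ls.name.replace("_conv", "_act")))
            elif ls.kind == "batchnorm":
                layers.append(BatchNorm(ls.filters_or_units, name=ls.name))
            elif ls.kind == "maxpool3d":
                layers.append(MaxPool3D(ls.kernel[0], name=ls.name))
            elif ls.kind == "flatten":
                layers.append(Flatten(name=ls.name))
            elif ls.kind == "dense":
                layers.append(
                    Dense(ls.input_shape[0], ls.filters_or_units, l2_coeff=ls.l2_coeff,
                          seed=next(init_seeds), name=ls.name)
                )
                if ls.activation == "elu":
                    layers.append(ELU(name=ls.name + "_act"))
            elif ls.kind == "dropout":
                layers.append(Dropout(ls.dropout_rate, name=ls.name))
            else:  # pragma: no cover
                raise ValueError(f"unknown layer kind {ls.kind!r}")
        return cls(layers, spec=spec)

    def reseed_dropout(self, seed: int) -> None:
        ss = np.random.SeedSequence([seed, 7919])
        for lyr, child in zip(
            [l for l in self.layers if isinstance(l, Dropout)],
            ss.spawn(sum(isinstance(l, Dropout) for l in self.layers)),
        ):
            lyr.rng = np.random.default_rng(child)

    # -- execution ------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Return pre-sigmoid logits of shape (N, 1)."""
        h = np.asarray(x, dtype=np.float64)
        for lyr in self.layers:
            h = lyr.forward(h, training)
        return h

    def backward(self, dlogit: np.ndarray, stop_at: Optional[int] = None) -> np.ndarray:
        """Propagate gradient from the logits back to ``stop_at`` (exclusive).

        Returns the gradient w.r.t. the output of layer ``stop_at - 1``
        (the network input when ``stop_at`` is None or 0).
        """
        g = dlogit
        stop = 0 if stop_at is None else stop_at
        for lyr in reversed(self.layers[stop:]):
            g = lyr.backward(g)
        return g

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode disease probabilities, shape (N,)."""
        return np.asarray(sigmoid(self.forward(x, training=False)[:, 0]))

    def layer_index(self, name: str) -> int:
        for i, lyr in enumerate(self.layers):
            if lyr.name == name:
                return i
        raise KeyError(
            f"no layer named {name!r}; available: {[l.name for l in self.layers]}"
        )

    # -- parameters -----------------------------------------------------
    def parameters(self) -> List[Tuple[Layer, str]]:
        return [(lyr, k) for lyr in self.layers for k in lyr.params]

    def l2_penalty(self) -> float:
        """Total L2 penalty: sum of l2 * sum(w^2) over conv/dense kernels."""
        return float(
            sum(
                lyr.l2_coeff * np.sum(lyr.params[k] ** 2)
                for lyr in self.layers
                for k in lyr.l2_keys
            )
        )

    def state_arrays(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for i, lyr in enumerate(self.layers):
            for k, v in lyr.params.items():
                out[f"{i}.{lyr.name}.{k}"] = v
            if isinstance(lyr, BatchNorm):
                out[f"{i}.{lyr.name}.running_mean"] = lyr.running_mean
                out[f"{i}.{lyr.name}.running_var"] = lyr.running_var
        return out

    def load_state_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        for i, lyr in enumerate(self.layers):
            for k in lyr.params:
                lyr.params[k] = np.array(arrays[f"{i}.{lyr.name}.{k}"])
            if isinstance(lyr, BatchNorm):
                lyr.running_mean = np.array(arrays[f"{i}.{lyr.name}.running_mean"])
                lyr.running_var = np.array(arrays[f"{i}.{lyr.name}.running_var"])


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits and its gradient w.r.t. logits.

    Uses the overflow-safe form max(z,0) - z*y + log(1 + exp(-|z|)).
    """
    z = logits[:, 0]
    y = np.asarray(y, dtype=float)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = np.asarray(sigmoid(z))
    grad = ((p - y) / y.size)[:, None]
    return loss, grad


class Adam:
    """Adam optimizer over a network's parameters."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(l) * 1000 + i: np.zeros_like(l.params[k])
                  for i, (l, k) in enumerate(net.parameters())}
        self.v = {key: np.zeros_like(val) for key, val in self.m.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (lyr, k) in enumerate(self.net.parameters()):
            key = id(lyr) * 1000 + i
            g = lyr.grads[k]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            lyr.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain stochastic gradient descent (alternative optimizer)."""

    def __init__(self, net: Network, lr: float = 1e-3):
        self.net = net
        self.lr = lr

    def step(self) -> None:
        for lyr, k in self.net.parameters():
            lyr.params[k] -= self.lr * lyr.grads[k]


def save_network(net: Network, path, builder_args: Optional[dict] = None) -> None:
    """Persist weights (npz) plus the builder arguments needed to rebuild."""
    arrays = net.state_arrays()
    meta = json.dumps(builder_args or {})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_network(path) -> Tuple[Network, dict]:
    from .architecture import build_architecture

    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    spec = build_architecture(
        tuple(meta["input_shape"]), tuple(meta["conv_filters"]),
        dense_units=tuple(meta.get("dense_units", (40, 10))),
        dropout_rate=meta.get("dropout_rate", 0.2),
        l2_coeff=meta.get("l2_coeff", 0.05),
    )
    net = Network.from_spec(spec, seed=0)
    net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta
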