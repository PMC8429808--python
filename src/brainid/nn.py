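"""Minimal 3D convolutional network primitives with exact backprop.

The layers here are exactly what the subject-identification encoder needs:
3D convolution (stride 1, zero padding that preserves spatial size), 2x2x2
average pooling, ReLU, flatten / global average pooling, a dense layer,
softmax cross-entropy and Adam. All gradients are exact (the test suite
checks them against central finite differences in float64).

Tensors are laid out channels-last — (N, D, H, W, C) — and a k^3 convolution
is evaluated as k^3 shifted-slice GEMMs: for each kernel offset the padded
input is sliced, flattened and multiplied against that offset's (C_in,
C_out) weight slab. On one CPU this is dominated by sequential copies plus
BLAS calls and is several times faster than an im2col patch matrix, whose
27-fold memory blowup is gather-bound. The input gradient reuses the same
trick with the roles of y and x swapped.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Conv3D",
    "ReLU",
    "AvgPool3D",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; invariant to per-row constant shifts."""
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dloss/dlogits)``; the gradient is ``(p - onehot) / N``.
    """
    n = logits.shape[0]
    z = logits - np.max(logits, axis=1, keepdims=True)
    logsumexp = np.log(np.sum(np.exp(z), axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(n), labels]))
    p = softmax(logits, axis=1)
    p[np.arange(n), labels] -= 1.0
    return loss, p / n


class Layer:
    """Base layer: forward caches what backward needs; params() lists weights."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv3D(Layer):
    """k x k x k convolution, stride 1, 'same' zero padding, channels-last.

    ``compute_dx=False`` skips the input gradient (for the first layer,
    where it is never used).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        compute_dx: bool = True,
    ) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for size-preserving padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.compute_dx = compute_dx
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel**3
        # weight[p, q, r] is the (C_in, C_out) slab for kernel offset (p, q, r)
        self.weight = (
            rng.standard_normal((kernel,) * 3 + (in_channels, out_channels))
            * np.sqrt(2.0 / fan_in)
        ).astype(dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._xp: np.ndarray | None = None

    def _offsets(self):
        k = self.kernel
        return itertools.product(range(k), range(k), range(k))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, _ = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3 + ((0, 0),))
        self._xp = xp
        acc = np.zeros((n * d * h * w, self.out_channels), dtype=x.dtype)
        for p, q, r in self._offsets():
            xs = np.ascontiguousarray(
                xp[:, p : p + d, q : q + h, r : r + w, :]
            ).reshape(-1, self.in_channels)
            acc += xs @ self.weight[p, q, r]
        acc += self.bias
        return acc.reshape(n, d, h, w, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        xp = self._xp
        n, d, h, w, _ = dout.shape
        pad = self.kernel // 2
        dflat = dout.reshape(-1, self.out_channels)
        self.dbias = dflat.sum(axis=0)
        self.dweight = np.empty_like(self.weight)
        dxp = np.zeros_like(xp) if self.compute_dx else None
        for p, q, r in self._offsets():
            xs = np.ascontiguousarray(
                xp[:, p : p + d, q : q + h, r : r + w, :]
            ).reshape(-1, self.in_channels)
            self.dweight[p, q, r] = xs.T @ dflat
            if dxp is not None:
                dxp[:, p : p + d, q : q + h, r : r + w, :] += (
                    dflat @ self.weight[p, q, r].T
                ).reshape(n, d, h, w, self.in_channels)
        self._xp = None
        if dxp is None:
            return None
        if pad:
            return dxp[:, pad:-pad, pad:-pad, pad:-pad, :]
        return dxp

    def params(self) -> list[dict]:
        return [
            {"name": "weight", "layer": self, "attr": "weight", "grad": "dweight"},
            {"name": "bias", "layer": self, "attr": "bias", "grad": "dbias"},
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool3D(Layer):
    """Non-overlapping k x k x k average pooling (kernel == stride)."""

    def __init__(self, kernel: int = 2) -> None:
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        n, d, h, w, c = x.shape
        if d % k or h % k or w % k:
            raise ValueError(f"spatial shape {(d, h, w)} not divisible by pool {k}")
        self._in_shape = x.shape
        return x.reshape(n, d // k, k, h // k, k, w // k, k, c).mean(axis=(2, 4, 6))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        g = dout * (1.0 / k**3)
        for axis in (1, 2, 3):
            g = np.repeat(g, k, axis=axis)
        return g.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Average each channel over all voxels: (N, D, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._shape
        g = dout / (d * h * w)
        return np.broadcast_to(g[:, None, None, None, :], self._shape).copy()


class Dense(Layer):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.weight = (rng.standard_normal((in_dim, out_dim))
                       * np.sqrt(2.0 / in_dim)).astype(dtype)
        self.bias = np.zeros(out_dim, dtype=dtype)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dweight = self._x.T @ dout
        self.dbias = dout.sum(axis=0)
        self._x = None
        return dout @ self.weight.T

    def params(self) -> list[dict]:
        return [
            {"name": "weight", "layer": self, "attr": "weight", "grad": "dweight"},
            {"name": "bias", "layer": self, "attr": "bias", "grad": "dbias"},
        ]


class Network:
    """A plain sequential stack."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[dict]:
        out: list[dict] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(getattr(p["layer"], p["attr"]).size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{p['name']}": getattr(p["layer"], p["attr"])
            for i, layer in enumerate(self.layers)
            for p in layer.params()
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for p in layer.params():
                key = f"{i}.{p['name']}"
                current = getattr(p["layer"], p["attr"])
                if key not in state:
                    raise KeyError(f"missing weight {key}")
                if state[key].shape != current.shape:
                    raise ValueError(
                        f"{key}: shape {state[key].shape} != {current.shape}"
                    )
                setattr(p["layer"], p["attr"], state[key].astype(current.dtype))


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(
        self,
        network: Network,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, p in enumerate(self.network.params()):
            w = getattr(p["layer"], p["attr"])
            g = getattr(p["layer"], p["grad"]).astype(np.float64)
            m = self._m.get(idx)
            v = self._v.get(idx)
            if m is None:
                m = np.zeros(w.shape)
                v = np.zeros(w.shape)
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._m[idx], self._v[idx] = m, v
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            update = self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            setattr(p["layer"], p["attr"], (w - update).astype(w.dtype))
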