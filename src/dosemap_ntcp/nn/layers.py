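"""Minimal NumPy layer engine: forward/backward passes and Adam.

Volumes are NCDHW arrays.  3D convolution is computed as a sum of
kernel-offset shifts, each a channel-mixing matrix product, which keeps the
whole engine inside BLAS-backed einsums.  Every layer caches what its
backward pass needs; ``backward`` must follow the matching ``forward``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: trainable parameters live in ``_params`` name -> array."""

    def __init__(self) -> None:
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}

    def params_and_grads(self):
        for name, p in self._params.items():
            yield self, name, p, self._grads.get(name)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self._params.values()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, odd kernel, stride 1, 'same' zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.ks = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size**3
        self._params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, *(kernel_size,) * 3)
        )
        self._params["b"] = np.zeros(out_channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        w, b = self._params["w"], self._params["b"]
        n, c, d, h, wd = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp_shape = xp.shape
        self._xp = xp
        y = np.zeros((n, w.shape[0], d, h, wd))
        for i in range(self.ks):
            for j in range(self.ks):
                for k in range(self.ks):
                    patch = xp[:, :, i : i + d, j : j + h, k : k + wd]
                    y += np.einsum(
                        "oc,ncxyz->noxyz", w[:, :, i, j, k], patch, optimize=True
                    )
        return y + b[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        w = self._params["w"]
        xp = self._xp
        n, _, d, h, wd = grad.shape
        dw = np.zeros_like(w)
        dxp = np.zeros(self._xp_shape)
        for i in range(self.ks):
            for j in range(self.ks):
                for k in range(self.ks):
                    patch = xp[:, :, i : i + d, j : j + h, k : k + wd]
                    dw[:, :, i, j, k] = np.einsum(
                        "noxyz,ncxyz->oc", grad, patch, optimize=True
                    )
                    dxp[:, :, i : i + d, j : j + h, k : k + wd] += np.einsum(
                        "oc,noxyz->ncxyz", w[:, :, i, j, k], grad, optimize=True
                    )
        self._grads["w"] = dw
        self._grads["b"] = grad.sum(axis=(0, 2, 3, 4))
        self._xp = None
        p = self.pad
        return dxp[:, :, p : p + d, p : p + h, p : p + wd] if p else dxp


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over (N, D, H, W) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self._params["gamma"] = np.ones(channels)
        self._params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) / std[None, :, None, None, None]
        if train:
            self._xhat, self._std = xhat, std
        return (
            self._params["gamma"][None, :, None, None, None] * xhat
            + self._params["beta"][None, :, None, None, None]
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, std = self._xhat, self._std
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self._grads["gamma"] = (grad * xhat).sum(axis=axes)
        self._grads["beta"] = grad.sum(axis=axes)
        g = self._params["gamma"][None, :, None, None, None]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) / std[None, :, None, None, None]
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class AvgPool3d(Layer):
    """Non-overlapping 2x2x2 average pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("AvgPool3d requires even spatial dimensions")
        self._in_shape = x.shape
        return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad[:, :, :, None, :, None, :, None] / 8.0
        g = np.broadcast_to(g, (*grad.shape[:2], grad.shape[2], 2, grad.shape[3], 2, grad.shape[4], 2))
        return g.reshape(self._in_shape)


class GlobalAvgPool3d(Layer):
    """Reduce each channel to its spatial mean: NCDHW -> NC."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        return np.broadcast_to(
            grad[:, :, None, None, None] / (d * h * w), self._in_shape
        ).copy()


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self._params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features)
        )
        self._params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self._params["w"].T + self._params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self._grads["w"] = grad.T @ self._x
        self._grads["b"] = grad.sum(axis=0)
        x = self._x
        self._x = None
        return grad @ self._params["w"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-15, None))))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with decoupled-from-nothing (coupled L2) weight decay, as in the
    classic Adam + weight_decay parameterisation."""

    def __init__(
        self,
        layers,
        learning_rate: float = 1e-3,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.layers = list(layers)
        self.lr = learning_rate
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        for layer in self.layers:
            for lay, name, p, g in layer.params_and_grads():
                if g is None:
                    continue
                if self.wd and name not in ("beta", "b"):
                    g = g + self.wd * p
                key = (id(lay), name)
                m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
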