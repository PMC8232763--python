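"""Primitive differentiable layers (single-item, channels-first).

Tensors are ``(C, *spatial)`` with spatial rank 2 or 3.  Each layer exposes
``forward(x, training) -> (y, cache)`` and ``backward(cache, dy) -> dx``;
parameter gradients are ACCUMULATED into ``layer.grads`` so that several
live caches (needed for backpropagation through time) can contribute to one
update.  Call ``zero_grad`` before a fresh accumulation round.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Conv", "BatchNorm",
    "relu_forward", "relu_backward", "sigmoid",
    "pool_forward", "pool_backward", "unpool_forward", "unpool_backward",
]

_LOGIT_CLIP = 36.0  # sigmoid(±36) is strictly inside (0,1) in float64


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv(Layer):
    """Same-padded convolution, kernel 1 or 3 per axis, stride 1.

    Implemented as a shift-and-stack im2col: the padded input is expanded to
    one row per kernel offset and contracted against the flattened weight
    matrix with a single matmul.
    """

    def __init__(self, in_channels: int, out_channels: int, rank: int,
                 kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.rank, self.k = in_channels, out_channels, rank, kernel
        fan_in = in_channels * kernel**rank
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels) + (kernel,) * rank)
        self.params = {"W": w, "b": np.zeros(out_channels)}
        self.zero_grad()
        self._offsets = list(itertools.product(range(kernel), repeat=rank))

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.k == 1:
            return x
        return np.pad(x, [(0, 0)] + [(1, 1)] * self.rank)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        spatial = x.shape[1:]
        xp = self._pad(x)
        cols = np.empty((self.cin, len(self._offsets)) + spatial, dtype=x.dtype)
        for m, off in enumerate(self._offsets):
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            cols[:, m] = xp[sl]
        return cols.reshape(self.cin * len(self._offsets), -1)

    def forward(self, x: np.ndarray, training: bool = True):
        spatial = x.shape[1:]
        cols = self._im2col(x)
        wf = self.params["W"].reshape(self.cout, -1)
        y = (wf @ cols + self.params["b"][:, None]).reshape((self.cout,) + spatial)
        return y, (cols, spatial)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        cols, spatial = cache
        dyf = dy.reshape(self.cout, -1)
        self.grads["W"] += (dyf @ cols.T).reshape(self.params["W"].shape)
        self.grads["b"] += dyf.sum(axis=1)
        dcols = (self.params["W"].reshape(self.cout, -1).T @ dyf)
        dcols = dcols.reshape((self.cin, len(self._offsets)) + spatial)
        if self.k == 1:
            return dcols[:, 0]
        pad_shape = (self.cin,) + tuple(s + 2 for s in spatial)
        dxp = np.zeros(pad_shape, dtype=dy.dtype)
        for m, off in enumerate(self._offsets):
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            dxp[sl] += dcols[:, m]
        core = (slice(None),) + (slice(1, -1),) * self.rank
        return dxp[core]


class BatchNorm(Layer):
    """Per-channel normalization over the spatial axes with running statistics.

    With single-item training batches this normalizes each channel over its
    spatial extent during training and uses the exponential running mean and
    variance at evaluation time (momentum 0.1, eps 1e-5).
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = channels, momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.buffers = {"running_mean": np.zeros(channels),
                        "running_var": np.ones(channels)}
        self.zero_grad()

    def _bc(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v.reshape((self.c,) + (1,) * (ndim - 1))

    def forward(self, x: np.ndarray, training: bool = True):
        axes = tuple(range(1, x.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            rm, rv = self.buffers["running_mean"], self.buffers["running_var"]
            rm += self.momentum * (mean - rm)
            rv += self.momentum * (var - rv)
        else:
            mean, var = self.buffers["running_mean"], self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean, x.ndim)) * self._bc(inv_std, x.ndim)
        y = self._bc(self.params["gamma"], x.ndim) * xhat + self._bc(self.params["beta"], x.ndim)
        return y, (xhat, inv_std)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = cache
        axes = tuple(range(1, dy.ndim))
        m = float(np.prod(dy.shape[1:]))
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        dxhat = dy * self._bc(self.params["gamma"], dy.ndim)
        s1 = self._bc(dxhat.sum(axis=axes), dy.ndim)
        s2 = self._bc((dxhat * xhat).sum(axis=axes), dy.ndim)
        return self._bc(inv_std, dy.ndim) / m * (m * dxhat - s1 - xhat * s2)


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(mask: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return dy * mask


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically clipped logistic; outputs strictly inside (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_LOGIT_CLIP, _LOGIT_CLIP)))


def _blocked(x: np.ndarray) -> np.ndarray:
    """(C, *S) -> (C, *S/2, 2**rank) gathering each 2x...x2 window last."""
    c = x.shape[0]
    spatial = x.shape[1:]
    rank = len(spatial)
    shape = (c,) + sum(((s // 2, 2) for s in spatial), ())
    xr = x.reshape(shape)
    # move the size-2 axes (2, 4, [6]) to the back, keeping order
    perm = (0,) + tuple(1 + 2 * i for i in range(rank)) + tuple(2 + 2 * i for i in range(rank))
    return xr.transpose(perm).reshape((c,) + tuple(s // 2 for s in spatial) + (2**rank,))


def _unblocked(xb: np.ndarray, spatial: tuple[int, ...]) -> np.ndarray:
    c = xb.shape[0]
    rank = len(spatial)
    half = tuple(s // 2 for s in spatial)
    xr = xb.reshape((c,) + half + (2,) * rank)
    inv = (0,) + sum(((1 + i, 1 + rank + i) for i in range(rank)), ())
    return xr.transpose(inv).reshape((c,) + spatial)


def pool_forward(x: np.ndarray):
    """2x max-pooling; returns the pooled map and the argmax index per window."""
    if any(s % 2 for s in x.shape[1:]):
        raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape[1:]}")
    xb = _blocked(x)
    idx = xb.argmax(axis=-1)
    y = np.take_along_axis(xb, idx[..., None], axis=-1)[..., 0]
    return y, idx


def pool_backward(idx: np.ndarray, dy: np.ndarray, spatial: tuple[int, ...]) -> np.ndarray:
    """Route pooled gradients back to the argmax positions."""
    return unpool_forward(dy, idx, spatial)


def unpool_forward(y: np.ndarray, idx: np.ndarray, spatial: tuple[int, ...]) -> np.ndarray:
    """Max-unpooling: place each value at its recorded argmax position,
    zeros elsewhere.  Exact inverse placement of :func:`pool_forward`."""
    rank = len(spatial)
    xb = np.zeros(y.shape + (2**rank,), dtype=y.dtype)
    np.put_along_axis(xb, idx[..., None], y[..., None], axis=-1)
    return _unblocked(xb, spatial)


def unpool_backward(idx: np.ndarray, dx_full: np.ndarray) -> np.ndarray:
    """Gather the gradient back from the placed positions."""
    xb = _blocked(dx_full)
    return np.take_along_axis(xb, idx[..., None], axis=-1)[..., 0]
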