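"""SegUNet: encoder-decoder with skip concatenation AND pooling-index transfer.

The architecture combines the two classic "cross connections": U-Net-style
channel concatenation of same-level encoder features into the decoder, and
SegNet-style max-unpooling driven by the argmax indices recorded by the
matching encoder max-pool.  Each convolutional block is
(conv 3^r -> batch norm -> ReLU) twice; encoder widths start at
``base_filters`` and double per level, decoder widths halve; the head is a
1x1(x1) convolution followed by a sigmoid, so outputs are probabilities
strictly inside (0, 1).  The same class serves as the 3D coarse network and,
with ``spatial_rank=2`` and three input channels, as the recurrent unit of
the slice-sequential fine network.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .layers import (BatchNorm, Conv, pool_backward, pool_forward, relu_backward,
                     relu_forward, sigmoid, unpool_backward, unpool_forward)

__all__ = ["NetworkConfig", "SegUNet", "build_segunet", "coarse_forward",
           "fine_step", "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Structural hyperparameters of a SegUNet.

    ``base_filters=32, depth=4`` is the full-scale configuration; desk-scale
    experiments use e.g. ``base_filters=4, depth=2``.
    """

    in_channels: int = 1
    base_filters: int = 32
    depth: int = 4
    spatial_rank: int = 3
    kernel: int = 3
    out_channels: int = 1

    def __post_init__(self):
        if self.base_filters < 1 or self.depth < 1:
            raise ValueError("base_filters and depth must be >= 1")
        if self.spatial_rank not in (2, 3):
            raise ValueError("spatial_rank must be 2 or 3")


class _ConvBlock:
    """(conv -> BN -> ReLU) x 2."""

    def __init__(self, cin: int, cout: int, rank: int, kernel: int,
                 rng: np.random.Generator):
        self.conv1 = Conv(cin, cout, rank, kernel, rng)
        self.bn1 = BatchNorm(cout)
        self.conv2 = Conv(cout, cout, rank, kernel, rng)
        self.bn2 = BatchNorm(cout)
        self.layers = [self.conv1, self.bn1, self.conv2, self.bn2]

    def forward(self, x, training):
        h1, c1 = self.conv1.forward(x, training)
        h2, c2 = self.bn1.forward(h1, training)
        h3, m1 = relu_forward(h2)
        h4, c3 = self.conv2.forward(h3, training)
        h5, c4 = self.bn2.forward(h4, training)
        y, m2 = relu_forward(h5)
        return y, (c1, c2, m1, c3, c4, m2)

    def backward(self, cache, dy):
        c1, c2, m1, c3, c4, m2 = cache
        d = relu_backward(m2, dy)
        d = self.bn2.backward(c4, d)
        d = self.conv2.backward(c3, d)
        d = relu_backward(m1, d)
        d = self.bn1.backward(c2, d)
        return self.conv1.backward(c1, d)


class SegUNet:
    """Encoder-decoder segmentation network over single items ``(C, *spatial)``.

    Spatial dimensions must be divisible by ``2**depth``.  ``forward`` keeps a
    cache so ``backward`` can run later (several caches may be alive at once
    during truncated backpropagation through time); ``predict`` is the
    cache-free evaluation-mode path.
    """

    def __init__(self, config: NetworkConfig, seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.config = config
        f, d, r, k = config.base_filters, config.depth, config.spatial_rank, config.kernel
        self.enc: list[_ConvBlock] = []
        cin = config.in_channels
        for i in range(d):
            self.enc.append(_ConvBlock(cin, f * 2**i, r, k, rng))
            cin = f * 2**i
        self.dec: list[_ConvBlock] = []
        for i in range(d):  # decoder block at level i
            cout = f * 2 ** (i - 1) if i > 0 else f
            self.dec.append(_ConvBlock(2 * f * 2**i, cout, r, k, rng))
        self.head = Conv(f, config.out_channels, r, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for i, b in enumerate(self.enc):
            for j, lay in enumerate(b.layers):
                yield f"enc{i}.{j}", lay
        for i, b in enumerate(self.dec):
            for j, lay in enumerate(b.layers):
                yield f"dec{i}.{j}", lay
        yield "head", self.head

    def named_parameters(self):
        for name, lay in self._layers():
            for key, val in lay.params.items():
                yield f"{name}.{key}", lay, key, val

    def n_parameters(self) -> int:
        return sum(v.size for _, _, _, v in self.named_parameters())

    def zero_grad(self) -> None:
        for _, lay in self._layers():
            lay.zero_grad()

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        cfg = self.config
        if x.ndim != cfg.spatial_rank + 1 or x.shape[0] != cfg.in_channels:
            raise ValueError(
                f"expected ({cfg.in_channels}, *spatial rank {cfg.spatial_rank}) input, "
                f"got shape {x.shape}")
        if any(s % 2**cfg.depth for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by 2**depth={2**cfg.depth}")

    def forward(self, x: np.ndarray, training: bool = True):
        self._check_input(x)
        d = self.config.depth
        skips, idxs, spatials, enc_caches = [], [], [], []
        h = np.asarray(x, dtype=np.float64)
        for i in range(d):
            h, c = self.enc[i].forward(h, training)
            enc_caches.append(c)
            skips.append(h)
            spatials.append(h.shape[1:])
            h, idx = pool_forward(h)
            idxs.append(idx)
        dec_caches = []
        for i in reversed(range(d)):
            up = unpool_forward(h, idxs[i], spatials[i])
            h = np.concatenate([skips[i], up], axis=0)
            h, c = self.dec[i].forward(h, training)
            dec_caches.append(c)
        logits, hc = self.head.forward(h, training)
        prob = sigmoid(logits)
        cache = (enc_caches, dec_caches, idxs, spatials, hc, prob)
        return prob, cache

    def backward(self, cache, dprob: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; returns the gradient wrt the input."""
        enc_caches, dec_caches, idxs, spatials, hc, prob = cache
        d = self.config.depth
        dlogits = dprob * prob * (1.0 - prob)
        dnext = self.head.backward(hc, dlogits)
        dskips: list[np.ndarray] = [None] * d  # type: ignore[list-item]
        # forward ran decoder levels d-1 .. 0, so backward visits 0 .. d-1;
        # dec_caches[d-1-i] belongs to level i
        for i in range(d):
            dcat = self.dec[i].backward(dec_caches[d - 1 - i], dnext)
            c_skip = dcat.shape[0] // 2  # concat was [skip, unpooled], equal widths
            dskips[i] = dcat[:c_skip]
            dnext = unpool_backward(idxs[i], dcat[c_skip:])
        dh = dnext
        for i in reversed(range(d)):
            dh = pool_backward(idxs[i], dh, spatials[i])
            dh = dh + dskips[i]
            dh = self.enc[i].backward(enc_caches[i], dh)
        return dh

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward pass (running BN statistics, no cache)."""
        prob, _ = self.forward(x, training=False)
        return prob

    __call__ = predict

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, lay in self._layers():
            for key, val in lay.params.items():
                out[f"{name}.{key}"] = val
            for key, val in lay.buffers.items():
                out[f"{name}.buf.{key}"] = val
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, lay in self._layers():
            for key in lay.params:
                lay.params[key] = np.array(state[f"{name}.{key}"])
            for key in lay.buffers:
                lay.buffers[key] = np.array(state[f"{name}.buf.{key}"])
        self.zero_grad()


def build_segunet(config: NetworkConfig, seed: int | np.random.Generator = 0) -> SegUNet:
    """Construct a SegUNet with Kaiming-initialized convolutions (seedable)."""
    return SegUNet(config, seed)


def coarse_forward(model: SegUNet, image_patch: np.ndarray) -> np.ndarray:
    """Evaluation-mode probability map for one normalized sub-volume.

    Accepts a bare 3D array (a channel axis is added) and returns the
    same-shape probability patch.
    """
    patch = np.asarray(image_patch, dtype=np.float64)
    squeeze = patch.ndim == model.config.spatial_rank
    if squeeze:
        patch = patch[None]
    prob = model.predict(patch)
    return prob[0] if squeeze else prob


def fine_step(model, slice_x: np.ndarray, coarse_slice: np.ndarray,
              prev_pred: np.ndarray) -> np.ndarray:
    """One recurrent refinement step on a single axial slice.

    The model input is the fixed 3-channel stack
    ``(image slice, coarse probability slice, previous slice's prediction)``;
    the return value is the refined probability slice.
    """
    if not (slice_x.shape == coarse_slice.shape == prev_pred.shape):
        raise ValueError("fine_step inputs must share one 2D shape")
    x = np.stack([slice_x, coarse_slice, prev_pred], axis=0)
    return np.asarray(model.predict(x))[0]


def save_checkpoint(model: SegUNet, path) -> None:
    """Single-file checkpoint: every array plus the JSON-encoded config."""
    cfg = json.dumps(dataclasses.asdict(model.config))
    np.savez(str(path), __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> SegUNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appends .npz
    with np.load(path) as data:
        cfg = NetworkConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = SegUNet(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
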