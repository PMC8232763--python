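"""Two-stage coarse-to-fine training and inference.

The method decomposes mandible segmentation into two curriculum steps:

1. **Coarse stage** — a 3D SegUNet trained on randomly sampled sub-volumes
   predicts a rough whole-volume probability map via sliding-window tiling
   and mean fusion.  Random sub-volume sampling doubles as hard negative
   mining: windows without foreground teach the network to suppress false
   positives.
2. **Fine stage** — a recurrent 2D SegUNet sweeps the axial slices in
   ascending order; each step sees the current image slice, the coarse
   probability slice, and its own previous-slice prediction, so it can
   exploit the anatomical continuity of the jaw across slices.  Training
   unrolls the recurrence and backpropagates through time, truncated to the
   last ``bptt_window`` steps; the previous-step input stays a soft
   probability during training so gradients can flow, and is binarized only
   at final inference.

Both stages are trained separately with the same compound BCE+Dice loss.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import MetricsReport, evaluate_case, summarize_reports
from .nn import Adam, NetworkConfig, SegUNet, build_segunet, fine_step
from .objective import LossWeights, combined_loss, loss_gradient
from .patchwork import crop, fuse_patches, sample_training_subvolume, tile_volume
from .volumes import ImageVolume, LabelVolume, ProbabilityVolume, normalize_intensity
from .volumes import read_label, read_volume

logger = logging.getLogger("c2fseg")

__all__ = [
    "TrainConfig", "CascadeModel", "load_manifest", "train_coarse",
    "run_coarse_inference", "train_fine", "predict",
    "postprocess_largest_component", "evaluate_directory",
]


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters shared by both training stages.

    ``patch_size`` (coarse stage sub-volume) defaults to the full-scale
    64x128x128; desk-scale runs override it.  ``bptt_window`` is the number
    of recurrent steps unrolled with gradient in the fine stage.
    """

    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 1
    patch_size: tuple[int, int, int] = (64, 128, 128)
    overlap: tuple[int, int, int] = (8, 16, 16)
    positive_fraction: float = 0.5
    loss: LossWeights = dataclasses.field(default_factory=LossWeights)
    bptt_window: int = 4
    teacher_forcing: bool = False
    clip_lo: float = -1000.0
    clip_hi: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.bptt_window < 1:
            raise ValueError("bptt_window must be >= 1")
        self.patch_size = tuple(self.patch_size)
        self.overlap = tuple(self.overlap)


@dataclasses.dataclass
class CascadeModel:
    """The full two-stage predictor: coarse 3D net, fine recurrent 2D net,
    preprocessing bounds and the binarization threshold."""

    coarse: SegUNet
    fine: SegUNet
    clip_lo: float = -1000.0
    clip_hi: float = 2000.0
    threshold: float = 0.5
    patch_size: tuple[int, int, int] = (64, 128, 128)
    overlap: tuple[int, int, int] = (8, 16, 16)
    init_prev: str = "zeros"  # or "coarse": start the recurrence from the coarse slice

    def __post_init__(self):
        if self.coarse is None or self.fine is None:
            raise ValueError("cascade requires both a coarse and a fine model")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.init_prev not in ("zeros", "coarse"):
            raise ValueError("init_prev must be 'zeros' or 'coarse'")


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"case_id", "image", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def _load_cases(manifest: pd.DataFrame, split: str | None,
                cfg: TrainConfig) -> list[tuple[ImageVolume, LabelVolume]]:
    rows = manifest if split is None or "split" not in manifest else manifest[manifest["split"] == split]
    cases = []
    for _, row in rows.iterrows():
        img = normalize_intensity(read_volume(row["image"]), cfg.clip_lo, cfg.clip_hi)
        cases.append((img, read_label(row["label"])))
    if not cases:
        raise ValueError("empty dataset")
    return cases


def train_coarse(manifest: pd.DataFrame, net_config: NetworkConfig,
                 train_config: TrainConfig, split: str | None = "train",
                 ) -> tuple[SegUNet, list[float]]:
    """Train the coarse 3D network on random sub-volumes.

    Returns the model and the per-epoch mean training loss history.
    Deterministic given ``train_config.seed`` (single-threaded).
    """
    cases = _load_cases(manifest, split, train_config)
    rng = np.random.default_rng(train_config.seed)
    model = build_segunet(net_config, rng)
    opt = Adam(model, lr=train_config.learning_rate)
    history: list[float] = []
    for epoch in range(train_config.epochs):
        losses = []
        for ci in rng.permutation(len(cases)):
            img, lbl = cases[ci]
            opt.zero_grad()
            batch_losses = []
            for _ in range(train_config.batch_size):
                ip, lp = sample_training_subvolume(
                    img, lbl, train_config.patch_size,
                    train_config.positive_fraction, rng)
                prob, fcache = model.forward(ip.data[None], training=True)
                batch_losses.append(combined_loss(prob[0], lp.data, train_config.loss))
                dprob = loss_gradient(prob[0], lp.data, train_config.loss)[None]
                model.backward(fcache, dprob / train_config.batch_size)
            opt.step()
            losses.append(float(np.mean(batch_losses)))
        history.append(float(np.mean(losses)))
        logger.info("coarse epoch %d/%d: loss %.5f", epoch + 1, train_config.epochs, history[-1])
    return model, history


def run_coarse_inference(image: ImageVolume, model: SegUNet,
                         patch_size: tuple[int, int, int],
                         overlap: tuple[int, int, int] = (8, 16, 16),
                         clip_lo: float = -1000.0, clip_hi: float = 2000.0,
                         assume_normalized: bool = False) -> ProbabilityVolume:
    """Whole-volume coarse probability map via tile -> forward -> mean fusion.

    The image is intensity-normalized internally unless ``assume_normalized``.
    Volumes smaller than the patch along any axis are symmetrically
    zero-padded for inference and un-padded afterwards.
    """
    vol = image if assume_normalized else normalize_intensity(image, clip_lo, clip_hi)
    shape = vol.shape
    pads = [(max(0, p - s) // 2, max(0, p - s) - max(0, p - s) // 2)
            for s, p in zip(shape, patch_size)]
    data = np.pad(vol.data, pads) if any(a + b for a, b in pads) else vol.data
    padded = ImageVolume(data=data, spacing=vol.spacing)
    specs = tile_volume(padded.shape, patch_size, overlap)
    patches = [model.predict(crop(padded, s).data[None])[0] for s in specs]
    fused = fuse_patches(specs, patches, padded.shape, vol.spacing)
    if any(a + b for a, b in pads):
        sl = tuple(slice(a, a + s) for (a, _), s in zip(pads, shape))
        fused = ProbabilityVolume(data=fused.data[sl], spacing=vol.spacing)
    return fused


def _fine_epoch(model: SegUNet, opt: Adam, img: ImageVolume,
                coarse_prob: ProbabilityVolume, lbl: LabelVolume,
                cfg: TrainConfig) -> list[float]:
    """One truncated-BPTT sweep over a case's axial slices; returns per-step losses.

    Each slice's loss L_t is backpropagated through the last ``bptt_window``
    recurrent steps: the window ``t-w+1 .. t`` is re-unrolled from the stored
    soft predictions (the entry state is treated as a constant, truncating
    the gradient there), the per-step loss gradient is chained backwards
    through the previous-prediction input channel, and one optimizer update
    is applied per slice.  With ``bptt_window=1`` this reduces to per-slice
    training with a detached previous mask.
    """
    n = img.shape[0]
    zeros = np.zeros(img.shape[1:], dtype=np.float64)
    prev_seq: list[np.ndarray] = []  # soft predictions, in slice order
    step_losses: list[float] = []
    for t in range(n):
        # teacher forcing feeds the ground-truth previous slice (a constant),
        # so the recurrence carries no gradient and the window collapses to 1
        w0 = t if cfg.teacher_forcing else max(0, t - cfg.bptt_window + 1)
        if cfg.teacher_forcing:
            prev = lbl.data[t - 1].astype(np.float64) if t > 0 else zeros
        else:
            prev = prev_seq[w0 - 1] if w0 > 0 else zeros
        caches = []
        for s in range(w0, t + 1):
            x = np.stack([img.data[s], coarse_prob.data[s], prev], axis=0)
            prob, cache = model.forward(x, training=True)
            caches.append(cache)
            prev = prob[0]  # soft probability keeps the recurrence differentiable
        y = lbl.data[t].astype(np.float64)
        step_losses.append(combined_loss(prob[0], y, cfg.loss))
        opt.zero_grad()
        dout = loss_gradient(prob[0], y, cfg.loss)[None]
        for cache in reversed(caches):
            dx = model.backward(cache, dout)
            dout = dx[2][None]  # gradient wrt the previous-prediction channel
        opt.step()
        prev_seq.append(prob[0])
    return step_losses


def train_fine(manifest: pd.DataFrame, coarse_model: SegUNet,
               net_config: NetworkConfig, train_config: TrainConfig,
               split: str | None = "train") -> tuple[SegUNet, list[float]]:
    """Train the recurrent fine network against precomputed coarse maps.

    The per-case coarse probability volumes are computed once up front (the
    coarse model is frozen).  History holds the per-epoch mean per-step loss.
    """
    if net_config.spatial_rank != 2 or net_config.in_channels != 3:
        raise ValueError("fine network needs spatial_rank=2 and in_channels=3")
    cases = _load_cases(manifest, split, train_config)
    rng = np.random.default_rng(train_config.seed + 1)
    coarse_maps = [
        run_coarse_inference(img, coarse_model, train_config.patch_size,
                             train_config.overlap, assume_normalized=True)
        for img, _ in cases
    ]
    model = build_segunet(net_config, rng)
    opt = Adam(model, lr=train_config.learning_rate)
    history: list[float] = []
    for epoch in range(train_config.epochs):
        losses: list[float] = []
        for ci in rng.permutation(len(cases)):
            img, lbl = cases[ci]
            losses.extend(_fine_epoch(model, opt, img, coarse_maps[ci], lbl, train_config))
        history.append(float(np.mean(losses)))
        logger.info("fine epoch %d/%d: loss %.5f", epoch + 1, train_config.epochs, history[-1])
    return model, history


def predict(image: ImageVolume, cascade: CascadeModel,
            postprocess: bool = False) -> LabelVolume:
    """Full cascaded inference on one raw scan volume.

    normalize -> coarse sliding-window map -> slice-sequential fine
    refinement (previous prediction initialized to zeros) -> threshold at
    ``cascade.threshold`` (ties map to foreground) -> optional
    largest-component post-processing.
    """
    norm = normalize_intensity(image, cascade.clip_lo, cascade.clip_hi)
    coarse_prob = run_coarse_inference(norm, cascade.coarse, cascade.patch_size,
                                       cascade.overlap, assume_normalized=True)
    n = norm.shape[0]
    if cascade.init_prev == "coarse":
        prev = np.asarray(coarse_prob.data[0], dtype=np.float64)
    else:
        prev = np.zeros(norm.shape[1:], dtype=np.float64)
    fine_prob = np.empty(norm.shape, dtype=np.float64)
    for t in range(n):
        prev = fine_step(cascade.fine, norm.data[t], coarse_prob.data[t], prev)
        fine_prob[t] = prev
    mask = LabelVolume(data=(fine_prob >= cascade.threshold).astype(np.uint8),
                       spacing=image.spacing, origin=image.origin)
    if postprocess:
        mask = postprocess_largest_component(mask)
    return mask


def postprocess_largest_component(mask: LabelVolume) -> LabelVolume:
    """Keep only the largest 26-connected foreground component.

    Size ties are broken in favour of the component whose first voxel comes
    earliest in z-major scan order.  An empty mask is returned unchanged.
    """
    labeled, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = np.bincount(labeled.ravel())[1:]  # skip background
    best_size = sizes.max()
    tied = np.flatnonzero(sizes == best_size) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        flat = labeled.ravel()
        keep = min(tied, key=lambda lab: int(np.argmax(flat == lab)))
    return LabelVolume(data=(labeled == keep).astype(np.uint8),
                       spacing=mask.spacing, origin=mask.origin)


def evaluate_directory(pred_paths: dict[str, Path], truth_paths: dict[str, Path],
                       ) -> tuple[dict[str, MetricsReport], pd.DataFrame]:
    """Score matching prediction/truth NIfTI pairs; returns per-case reports
    and the per-case + mean/std summary table."""
    reports = {}
    for cid in sorted(pred_paths):
        if cid not in truth_paths:
            raise ValueError(f"no ground truth for case {cid}")
        reports[cid] = evaluate_case(read_label(pred_paths[cid]),
                                     read_label(truth_paths[cid]))
    return reports, summarize_reports(reports)
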