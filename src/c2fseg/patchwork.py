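"""Sub-volume cropping, training patch sampling and sliding-window fusion.

Training 3D networks on whole scans is memory-prohibitive, so the coarse
stage trains on randomly sampled sub-volumes and predicts whole volumes by
tiling them with small overlaps and fusing the per-patch probabilities back
into place (Crop / UnCrop).  Sampling mixes patches forced to contain
foreground with fully random ones; the random ones act as hard negative
mining against false positives.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .volumes import ImageVolume, LabelVolume, ProbabilityVolume

__all__ = [
    "SubVolumeSpec",
    "crop",
    "sample_training_subvolume",
    "tile_volume",
    "fuse_patches",
]


@dataclasses.dataclass(frozen=True)
class SubVolumeSpec:
    """A crop window: start voxel indices (z0, y0, x0) and size (nc, wc, hc)."""

    start: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self):
        if any(s < 0 for s in self.start):
            raise ValueError(f"negative start index: {self.start}")
        if any(s < 1 for s in self.size):
            raise ValueError(f"non-positive size: {self.size}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, a + b) for a, b in zip(self.start, self.size))

    def within(self, shape: tuple[int, int, int]) -> bool:
        return all(a + b <= s for a, b, s in zip(self.start, self.size, shape))


def crop(vol: ImageVolume, spec: SubVolumeSpec) -> ImageVolume:
    """Copy the sub-volume defined by ``spec``; spacing is inherited."""
    if not spec.within(vol.shape):
        raise ValueError(f"crop window {spec} exceeds volume shape {vol.shape}")
    sub = vol.data[spec.slices].copy()
    return type(vol)(data=sub, spacing=vol.spacing, origin=vol.origin)


def sample_training_subvolume(image: ImageVolume, label: LabelVolume,
                              size: tuple[int, int, int],
                              positive_fraction: float,
                              rng: np.random.Generator,
                              ) -> tuple[ImageVolume, LabelVolume]:
    """Draw one training patch pair.

    With probability ``positive_fraction`` the patch window is positioned so
    that it covers a uniformly chosen foreground voxel (hence contains at
    least one positive); otherwise its start is uniform over all valid
    positions.  Seeded-deterministic through ``rng``.
    """
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    shape = image.shape
    if any(s < p for s, p in zip(shape, size)):
        raise ValueError(f"volume shape {shape} smaller than patch size {size}")
    max_start = [s - p for s, p in zip(shape, size)]

    want_positive = rng.uniform() < positive_fraction
    if want_positive:
        fg = np.argwhere(label.data > 0)
        if len(fg) == 0:
            warnings.warn("positive patch requested but label is empty; "
                          "falling back to uniform sampling")
            want_positive = False
    if want_positive:
        voxel = fg[rng.integers(len(fg))]
        start = tuple(
            int(rng.integers(max(0, v - p + 1), min(v, m) + 1))
            for v, p, m in zip(voxel, size, max_start)
        )
    else:
        start = tuple(int(rng.integers(0, m + 1)) for m in max_start)
    spec = SubVolumeSpec(start=start, size=tuple(size))
    return crop(image, spec), crop(label, spec)


def tile_volume(shape: tuple[int, int, int], patch_size: tuple[int, int, int],
                overlap: tuple[int, int, int] | int = 0) -> list[SubVolumeSpec]:
    """Cover ``shape`` with overlapping windows for sliding-window inference.

    Per axis the stride is ``patch - overlap``; windows start at multiples of
    the stride and the final window is clamped to end at the volume boundary,
    so every voxel is covered.  Windows are listed z-major.
    """
    if isinstance(overlap, int):
        overlap = (overlap,) * 3
    if any(o >= p for o, p in zip(overlap, patch_size)):
        raise ValueError(f"overlap {overlap} must be < patch size {patch_size}")
    if any(p > s for p, s in zip(patch_size, shape)):
        raise ValueError(f"patch size {patch_size} exceeds volume shape {shape}")

    axes_starts = []
    for s, p, o in zip(shape, patch_size, overlap):
        stride = p - o
        starts = list(range(0, s - p + 1, stride))
        if starts[-1] != s - p:
            starts.append(s - p)
        axes_starts.append(starts)
    return [
        SubVolumeSpec(start=(z, y, x), size=tuple(patch_size))
        for z in axes_starts[0] for y in axes_starts[1] for x in axes_starts[2]
    ]


def fuse_patches(specs: list[SubVolumeSpec], patch_probs: list[np.ndarray],
                 shape: tuple[int, int, int],
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 ) -> ProbabilityVolume:
    """UnCrop: place per-patch probabilities back and average overlaps.

    Every output voxel is the arithmetic mean of all patch predictions that
    cover it — a symmetric, order-independent fusion.  A voxel covered by no
    window is an error.
    """
    if len(specs) != len(patch_probs):
        raise ValueError("specs and patch_probs length mismatch")
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int64)
    for spec, patch in zip(specs, patch_probs):
        patch = np.asarray(patch.data if hasattr(patch, "data") else patch)
        if tuple(patch.shape) != tuple(spec.size):
            raise ValueError(f"patch shape {patch.shape} != spec size {spec.size}")
        acc[spec.slices] += patch
        cnt[spec.slices] += 1
    if (cnt == 0).any():
        raise ValueError("fusion left uncovered voxels; windows do not tile the volume")
    return ProbabilityVolume(data=acc / cnt, spacing=spacing)
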