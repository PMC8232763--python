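"""Synthetic mandible-like phantoms with metal streak artifacts.

The generator emulates the salient features of maxillofacial CBCT for
segmentation experiments: a bright horseshoe-shaped jaw (body arch, two
ascending rami, condylar knobs) on a darker soft-tissue background, a few
very-high-attenuation "metallic" voxels in the tooth region whose intensity
exceeds the preprocessing clip ceiling, in-plane streak artifacts radiating
from each metallic voxel, and additive Gaussian noise.  Artifacts corrupt
only the image; the paired ground-truth label is the clean anatomy (with the
metallic tooth voxels counted as foreground, as they belong to the jaw).

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import ImageVolume, LabelVolume, write_volume

__all__ = ["ArchParams", "PhantomConfig", "generate_phantom", "add_streak_artifacts", "make_dataset"]


@dataclasses.dataclass
class ArchParams:
    """Geometry of the horseshoe body, rami and condyles, as fractions of the
    volume shape (so one set of defaults scales across grid sizes).

    The body is a partial annulus in the axial plane spanning an angular range
    that leaves a posterior gap; the rami are vertical pillars rising from the
    two arch ends; the condyles are spheres capping the rami.
    """

    outer_radius_frac: float = 0.38   # of min(w, h)
    thickness_frac: float = 0.14      # annulus thickness, of min(w, h)
    opening_deg: float = 100.0        # posterior angular gap of the horseshoe
    body_z_frac: tuple[float, float] = (0.10, 0.55)  # axial extent of the body
    ramus_radius_frac: float = 0.07
    ramus_z_frac: tuple[float, float] = (0.55, 0.90)
    condyle_radius_frac: float = 0.09

    def __post_init__(self) -> None:
        if self.thickness_frac <= 0:
            raise ValueError("degenerate arch: thickness must be positive")
        if self.outer_radius_frac <= self.thickness_frac / 2:
            raise ValueError("degenerate arch: outer radius too small for thickness")


@dataclasses.dataclass
class PhantomConfig:
    """Full description of one synthetic case.

    Intensities are on a CT-like scale: soft tissue around 0, cortical bone
    around 1200, metal at 3000 (above the [-1000, 2000] clip ceiling so it
    saturates after normalization, as real fillings/braces do).
    """

    shape: tuple[int, int, int] = (32, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bone_intensity: float = 1200.0
    tissue_intensity: float = 0.0
    metal_intensity: float = 3000.0
    n_metal_seeds: int = 4
    streak_count: int = 8
    streak_amplitude: float = 600.0
    noise_sd: float = 80.0
    arch_params: ArchParams = dataclasses.field(default_factory=ArchParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError("phantom shape components must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.metal_intensity > self.bone_intensity > self.tissue_intensity):
            raise ValueError("need metal_intensity > bone_intensity > tissue_intensity")


def _mandible_mask(shape: tuple[int, int, int], ap: ArchParams) -> np.ndarray:
    n, w, h = shape
    scale = min(w, h)
    cy, cx = w / 2.0, h / 2.0
    r_out = ap.outer_radius_frac * scale
    r_in = r_out - ap.thickness_frac * scale

    yy, xx = np.mgrid[0:w, 0:h]
    dy, dx = yy - cy, xx - cx
    rad = np.hypot(dy, dx)
    # angle measured from the anterior (+y) direction; posterior gap excluded
    ang = np.degrees(np.arctan2(dx, dy))
    in_annulus = (rad >= r_in) & (rad <= r_out)
    in_arc = np.abs(ang) <= (360.0 - ap.opening_deg) / 2.0
    body_xy = in_annulus & in_arc

    mask = np.zeros(shape, dtype=bool)
    z0, z1 = (int(round(f * n)) for f in ap.body_z_frac)
    mask[z0:z1] = body_xy

    # the two arch-end columns where rami rise
    end_ang = (360.0 - ap.opening_deg) / 2.0
    r_mid = (r_in + r_out) / 2.0
    rz0, rz1 = (int(round(f * n)) for f in ap.ramus_z_frac)
    r_ram = ap.ramus_radius_frac * scale
    r_con = ap.condyle_radius_frac * scale
    zz = np.arange(n)
    for sgn in (-1.0, 1.0):
        ey = cy + r_mid * np.cos(np.radians(sgn * end_ang))
        ex = cx + r_mid * np.sin(np.radians(sgn * end_ang))
        pillar = np.hypot(yy - ey, xx - ex) <= r_ram
        mask[rz0:rz1] |= pillar
        # condylar knob: sphere (in voxel units) centred at the ramus top
        cz = rz1 - 1
        dz2 = (zz[:, None, None] - cz) ** 2
        sphere = dz2 + (yy - ey)[None] ** 2 + (xx - ex)[None] ** 2 <= r_con**2
        mask |= sphere
    return mask


def _place_metal_seeds(mask: np.ndarray, ap: ArchParams, n_seeds: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Pick metallic tooth voxels on the upper part of the arch body."""
    metal = np.zeros_like(mask)
    if n_seeds == 0:
        return metal
    n = mask.shape[0]
    z0, z1 = (int(round(f * n)) for f in ap.body_z_frac)
    zt0 = z0 + int(0.6 * (z1 - z0))  # tooth-bearing upper body slices
    cand = np.argwhere(mask[zt0:z1])
    if len(cand) == 0:
        cand = np.argwhere(mask)
        zt0 = 0
    idx = rng.choice(len(cand), size=min(n_seeds, len(cand)), replace=False)
    for z, y, x in cand[idx]:
        metal[z + zt0, y, x] = True
    return metal


def add_streak_artifacts(image: ImageVolume, metal_mask: LabelVolume,
                         streak_count: int, streak_amplitude: float,
                         rng: np.random.Generator) -> ImageVolume:
    """Superimpose in-plane streaks radiating from every metallic voxel.

    For each metal voxel, ``streak_count`` rays at random in-plane angles are
    rasterized through the voxel; successive rays carry alternating
    +/- ``streak_amplitude`` offsets that fall off linearly with distance from
    the source.  Voxels not on any ray are untouched, as is the label.
    """
    if image.shape != metal_mask.shape:
        raise ValueError("metal mask geometry does not match image")
    data = image.data.astype(np.float64).copy()
    _, w, h = image.shape
    reach = np.hypot(w, h) / 2.0
    for z, y, x in np.argwhere(metal_mask.data > 0):
        for j in range(streak_count):
            # angle measured from the +x (column) axis; theta=0 runs along a row
            theta = rng.uniform(0.0, np.pi)
            sign = 1.0 if j % 2 == 0 else -1.0
            cy, cx = np.sin(theta), np.cos(theta)
            steps = np.arange(1, int(np.ceil(reach)) + 1)
            for direction in (1.0, -1.0):
                ys = np.rint(y + direction * steps * cy).astype(int)
                xs = np.rint(x + direction * steps * cx).astype(int)
                falloff = 1.0 - steps / reach
                ok = (ys >= 0) & (ys < w) & (xs >= 0) & (xs < h) & (falloff > 0)
                data[z, ys[ok], xs[ok]] += sign * streak_amplitude * falloff[ok]
    return ImageVolume(data=data, spacing=image.spacing, origin=image.origin)


def generate_phantom(config: PhantomConfig) -> tuple[ImageVolume, LabelVolume]:
    """Generate one artifact-polluted phantom and its clean ground truth.

    Returns the image (tissue + bone + metal + streaks + noise) and the label
    (arch, rami, condyles; metallic tooth voxels included as foreground).
    Bit-identical for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    mask = _mandible_mask(config.shape, config.arch_params)
    metal = _place_metal_seeds(mask, config.arch_params, config.n_metal_seeds, rng)

    data = np.full(config.shape, config.tissue_intensity, dtype=np.float64)
    data[mask] = config.bone_intensity
    data[metal] = config.metal_intensity

    image = ImageVolume(data=data, spacing=config.spacing)
    label = LabelVolume(data=(mask | metal).astype(np.uint8), spacing=config.spacing)
    metal_lbl = LabelVolume(data=metal.astype(np.uint8), spacing=config.spacing)

    if config.streak_count > 0 and config.streak_amplitude != 0:
        image = add_streak_artifacts(image, metal_lbl, config.streak_count,
                                     config.streak_amplitude, rng)
    if config.noise_sd > 0:
        noisy = image.data + rng.normal(0.0, config.noise_sd, size=config.shape)
        image = ImageVolume(data=noisy, spacing=config.spacing)
    return image, label


def make_dataset(n_cases: int, config: PhantomConfig, out_dir,
                 split: str | list[str] = "train") -> pd.DataFrame:
    """Write ``n_cases`` image/label NIfTI pairs plus a CSV manifest.

    Case ``i`` uses seed ``config.seed + i``, so a dataset can be extended
    without changing earlier cases.  ``split`` is either one name for all
    cases or a per-case list.  Returns the manifest
    (columns ``case_id,image,label,split``), also saved as ``manifest.csv``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(split, str):
        split = [split] * n_cases
    rows = []
    for i in range(n_cases):
        cfg = dataclasses.replace(config, seed=config.seed + i)
        image, label = generate_phantom(cfg)
        img_path = out_dir / f"case_{i:03d}_image.nii.gz"
        lbl_path = out_dir / f"case_{i:03d}_label.nii.gz"
        write_volume(image, img_path)
        write_volume(label, lbl_path)
        rows.append({"case_id": f"case_{i:03d}", "image": str(img_path),
                     "label": str(lbl_path), "split": split[i]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
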