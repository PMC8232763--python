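"""Core volume containers and NIfTI I/O.

All in-memory grids are indexed ``(slice, row, col)`` — axial slice first,
because the fine segmentation stage iterates axial slices.  Spacing is the
matching ``(dz, dy, dx)`` triple in millimetres.  On disk the standard NIfTI
axis order (x, y, z fastest-first) is used, so arrays are transposed on
read/write.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "ProbabilityVolume",
    "read_volume",
    "read_label",
    "read_probability",
    "write_volume",
    "normalize_intensity",
]


@dataclasses.dataclass
class ImageVolume:
    """A 3D grayscale scan volume with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities, indexed ``(slice, row, col)``.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in mm; all components > 0.
    origin
        Physical offset in mm (informational only).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"not a 3D volume: got {self.data.ndim} dimensions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self._validate()

    def _validate(self) -> None:
        pass

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def same_geometry(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclasses.dataclass
class LabelVolume(ImageVolume):
    """Binary segmentation mask; voxel values exactly 0 or 1."""

    def _validate(self) -> None:
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("label volume must contain only 0 and 1")
        self.data = self.data.astype(np.uint8)


@dataclasses.dataclass
class ProbabilityVolume(ImageVolume):
    """Soft segmentation map; voxel values in [0, 1]."""

    def _validate(self) -> None:
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probability volume must lie within [0, 1]")


def _from_nifti(path: Path, cls):
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"not a 3D volume: {path} has {arr.ndim} dimensions")
    # NIfTI stores (x, y, z); transpose to (slice z, row y, col x).
    data = np.ascontiguousarray(arr.T)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    off = img.affine[:3, 3]
    origin = (float(off[2]), float(off[1]), float(off[0]))
    return cls(data=data, spacing=spacing, origin=origin)


def read_volume(path) -> ImageVolume:
    """Read a 3D NIfTI file as an :class:`ImageVolume`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the image is not 3-dimensional.
    nibabel.filebasedimages.ImageFileError
        If the file is not a readable NIfTI image.
    """
    return _from_nifti(Path(path), ImageVolume)


def read_label(path) -> LabelVolume:
    """Read a binary mask stored as NIfTI."""
    return _from_nifti(Path(path), LabelVolume)


def read_probability(path) -> ProbabilityVolume:
    """Read a soft probability map stored as NIfTI."""
    return _from_nifti(Path(path), ProbabilityVolume)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume to NIfTI (labels as uint8, everything else float32)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LabelVolume):
        payload = vol.data.astype(np.uint8)
    else:
        payload = vol.data.astype(np.float32)
    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    img = nib.Nifti1Image(payload.T, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))


def normalize_intensity(vol: ImageVolume, lo: float = -1000.0, hi: float = 2000.0) -> ImageVolume:
    """Clip raw intensities to ``[lo, hi]`` and rescale linearly to [0, 1].

    This is the standard CT preprocessing applied identically to every case:
    values below ``lo`` map to 0, above ``hi`` to 1, and the result is
    ``(clip(v, lo, hi) - lo) / (hi - lo)``.  Spacing and origin are unchanged.
    """
    if hi <= lo:
        raise ValueError(f"hi must exceed lo, got lo={lo}, hi={hi}")
    data = (np.clip(vol.data.astype(np.float64), lo, hi) - lo) / (hi - lo)
    return ImageVolume(data=data, spacing=vol.spacing, origin=vol.origin)
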