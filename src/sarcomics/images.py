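"""Gridded image containers used throughout the imaging pipeline.

An :class:`ImageVolume` is a 3-D scalar field on a regular grid with
physical voxel spacing in millimetres; a :class:`SegmentationMask` is a
binary field on the same grid delineating the tumor volume of interest.
NIfTI round-tripping is provided so cohorts can be written to disk and
re-read by the CLI stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "SegmentationMask", "load_nifti", "save_nifti"]


@dataclass
class ImageVolume:
    """A 3-D scalar image with physical spacing (mm) and origin."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ImageVolume requires a 3-D array")
        if self.values.size == 0:
            raise ValueError("ImageVolume must be non-empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageVolume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy_with(self, values: np.ndarray | None = None,
                  spacing: tuple[float, float, float] | None = None) -> "ImageVolume":
        return ImageVolume(
            values=self.values.copy() if values is None else np.asarray(values, float),
            spacing=self.spacing if spacing is None else spacing,
            origin=self.origin,
        )


@dataclass
class SegmentationMask:
    """Binary tumor mask on the same grid as its paired volume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("SegmentationMask requires a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self) -> None:
        if not self.values.any():
            raise ValueError("mask has no foreground voxel")


def save_nifti(path, vol: ImageVolume | SegmentationMask) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path, as_mask: bool = False):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj).astype(float)
    if as_mask:
        return SegmentationMask(data > 0.5, spacing)
    return ImageVolume(data, spacing)
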