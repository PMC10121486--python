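"""Core image containers and NIfTI input/output.

A :class:`Volume` is a 3-D scalar grid with axis order (sagittal, coronal,
axial) plus the physical voxel spacing in millimetres.  Values are Hounsfield
units on ingestion and unit-interval intensities after
:func:`asbestoscreen.preprocess.clip_scale`.  Binary masks (lung masks, lesion
masks) are plain boolean ``numpy`` arrays aligned voxel-for-voxel with their
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume", "read_mask", "write_mask"]


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing.

    Parameters
    ----------
    values
        Array of shape ``(sagittal, coronal, axial)``.
    spacing
        Voxel size per axis in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine built from the spacing."""
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), _affine(volume.spacing))
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.dataobj, dtype=np.float32), spacing)


def write_mask(mask: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0
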