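"""Data curation for volumetric CT: clipping, lung segmentation, masking.

The chain mirrors standard ILD pipelines: Hounsfield units are clipped to
[-1024, 3072] and scaled to [0, 1]; lungs are segmented by an air/parenchyma
threshold plus connected-component rules; the mask is dilated with a
13 x 13 x 5 voxel box so pleura and adjacent chest wall (plaques, thickening)
survive masking; non-lung voxels are zeroed; and the masked volume is cropped
to the mask bounding box and resampled to the working grid.

Segmentation here is threshold/morphology based: phantoms (and most chest
CTs) separate cleanly at an air/parenchyma threshold once the air connected
to the grid border is excluded, and it keeps the module free of pretrained
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .volumes import Volume

__all__ = [
    "SegmentationError",
    "clip_scale",
    "segment_lungs",
    "dilate_mask",
    "apply_mask_and_resize",
    "resize_mask",
    "preprocess_case",
]

HU_MIN = -1024.0
HU_MAX = 3072.0
LUNG_THRESHOLD_HU = -320.0
DILATION_KERNEL = (13, 13, 5)  # sagittal, coronal, axial
QC_MASK_FRACTION = (0.05, 0.6)


class SegmentationError(RuntimeError):
    """Raised when no plausible lung component can be found."""


def clip_scale(volume: Volume) -> Volume:
    """Clip HU to [-1024, 3072] and scale linearly onto [0, 1].

    ``v' = (clip(v, -1024, 3072) + 1024) / 4096``.  One-way transform; the
    input must be finite HU values.
    """
    values = np.asarray(volume.values, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("volume contains non-finite voxels")
    scaled = (np.clip(values, HU_MIN, HU_MAX) - HU_MIN) / (HU_MAX - HU_MIN)
    return Volume(scaled, volume.spacing)


def _touches_border(labels: np.ndarray, lab: int) -> bool:
    return any(
        (np.take(labels, 0, axis=ax) == lab).any() or (np.take(labels, -1, axis=ax) == lab).any()
        for ax in range(labels.ndim)
    )


def segment_lungs(volume: Volume, threshold_hu: float = LUNG_THRESHOLD_HU) -> np.ndarray:
    """Segment the lungs of an HU-scale volume.

    Voxels below the air/parenchyma threshold are connected-component
    labelled; components touching the grid border (outside air) are
    discarded; the up to two largest remaining components are kept and their
    holes filled.  A mask occupying an implausible fraction of the grid
    raises a quality-control warning.
    """
    values = np.asarray(volume.values)
    air = values < threshold_hu
    labels, n_labels = ndimage.label(air)
    if n_labels == 0:
        raise SegmentationError("no low-attenuation voxels below the lung threshold")

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
    internal = [lab for lab in range(1, n_labels + 1) if not _touches_border(labels, lab)]
    if not internal:
        raise SegmentationError("no internal low-attenuation component (lungs not found)")
    internal.sort(key=lambda lab: sizes[lab - 1], reverse=True)
    keep = internal[:2]

    mask = np.isin(labels, keep)
    mask = ndimage.binary_fill_holes(mask)

    frac = mask.mean()
    lo, hi = QC_MASK_FRACTION
    if not lo <= frac <= hi:
        warnings.warn(
            f"lung mask covers {frac:.1%} of the grid (QC band {lo:.0%}-{hi:.0%}); inspect the segmentation",
            stacklevel=2,
        )
    return mask


def dilate_mask(mask: np.ndarray, kernel: tuple[int, int, int] = DILATION_KERNEL) -> np.ndarray:
    """Morphological dilation with a rectangular box structuring element.

    The default 13 x 13 x 5 box (sagittal x coronal x axial) extends the lung
    mask over the pleural boundary.  The output is always a superset of the
    input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    out = ndimage.maximum_filter(mask.view(np.uint8), size=kernel, mode="constant", cval=0)
    return out.astype(bool)


def resize_mask(mask: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour resampling keeps masks binary."""
    out = resize(mask.astype(np.float32), target_shape, order=0, preserve_range=True, anti_aliasing=False)
    return out > 0.5


def apply_mask_and_resize(
    volume: Volume, mask: np.ndarray, target_shape: tuple[int, int, int]
) -> tuple[Volume, np.ndarray]:
    """Zero non-mask voxels, crop to the mask bounding box, resample.

    The volume is resampled trilinearly, the mask nearest-neighbour; the
    resampled mask is re-applied so that every voxel outside it is exactly
    zero.  Returns the resampled volume and mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {volume.shape}")
    if not mask.any():
        raise ValueError("empty mask")

    bbox = tuple(slice(idx.min(), idx.max() + 1) for idx in np.nonzero(mask))
    masked = np.where(mask, volume.values, 0.0)[bbox]
    cropped_mask = mask[bbox]

    out = resize(masked.astype(np.float64), target_shape, order=1, preserve_range=True, anti_aliasing=False)
    out_mask = resize_mask(cropped_mask, target_shape)
    out[~out_mask] = 0.0

    crop_shape = masked.shape
    spacing = tuple(
        sp * cs / ts for sp, cs, ts in zip(volume.spacing, crop_shape, target_shape)
    )
    return Volume(out, spacing), out_mask


def preprocess_case(
    volume_hu: Volume,
    target_shape: tuple[int, int, int] = (48, 48, 24),
    threshold_hu: float = LUNG_THRESHOLD_HU,
    kernel: tuple[int, int, int] = DILATION_KERNEL,
    extra_masks: tuple[np.ndarray, ...] = (),
):
    """Full curation chain for one HU volume.

    Order: clip/scale, segment on true HU, dilate, mask + crop + resize.
    ``extra_masks`` (e.g. a ground-truth lesion mask) are carried through the
    same crop/resize so they stay voxel-aligned with the output.

    Returns ``(volume, mask)`` or ``(volume, mask, resampled_extras)``.
    """
    scaled = clip_scale(volume_hu)
    lungs = segment_lungs(volume_hu, threshold_hu=threshold_hu)
    dilated = dilate_mask(lungs, kernel=kernel)
    prep, prep_mask = apply_mask_and_resize(scaled, dilated, target_shape)
    if not extra_masks:
        return prep, prep_mask
    bbox = tuple(slice(idx.min(), idx.max() + 1) for idx in np.nonzero(dilated))
    extras = tuple(resize_mask(np.asarray(m, dtype=bool)[bbox], target_shape) for m in extra_masks)
    return prep, prep_mask, extras
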