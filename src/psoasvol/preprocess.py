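"""Landmark cropping, intensity normalization and reflection.

A subject's water volume plus the two hip landmarks become two
fixed-shape crops, one per muscle.  The left crop is mirrored along the
left-right axis so both crops share the right-like chirality before any
model sees them.  Normalization maps the crop's 99th intensity
percentile to one and clips above it; it is applied per crop (cropping
precedes it in the processing order).

Crop placement: in-plane the box is centred on the landmark; along the
inferior-superior axis the landmark sits a configurable fraction
(default 25%) of the crop extent above the inferior face, since the
muscle extends mostly superiorly from the hip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import (
    DEFAULT_CROP_SHAPE,
    DixonVolume,
    LandmarkSet,
    MuscleCrop,
    MuscleMask,
)

NORMALIZE_PERCENTILE = 99.0
#: landmark position along the out-of-plane axis, as a fraction of the
#: crop extent measured from the inferior face
OUTPLANE_LANDMARK_FRAC = 0.25


class DegenerateInputError(ValueError):
    """Raised when the normalization percentile is not positive."""


def _crop_origin(landmark, crop_shape, outplane_frac) -> Tuple[int, int, int]:
    i = landmark[0] - crop_shape[0] // 2
    j = landmark[1] - crop_shape[1] // 2
    k = landmark[2] - int(round(outplane_frac * crop_shape[2]))
    return (i, j, k)


def extract_subvolume(data: np.ndarray, origin, shape, fill=0) -> np.ndarray:
    """Copy ``shape`` voxels starting at ``origin``; out-of-bounds
    regions are filled with ``fill``."""
    out = np.full(shape, fill, dtype=data.dtype)
    src, dst = [], []
    for o, s, n in zip(origin, shape, data.shape):
        lo, hi = max(o, 0), min(o + s, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = data[tuple(src)]
    return out


def embed_crop(crop_data: np.ndarray, source_offset, parent_shape,
               reflected: bool = False) -> np.ndarray:
    """Place crop-space data back into a parent-sized array (inverse of
    :func:`extract_subvolume`); a reflected crop is un-mirrored first."""
    if reflected:
        crop_data = crop_data[::-1]
    out = np.zeros(parent_shape, dtype=crop_data.dtype)
    src, dst = [], []
    for o, s, n in zip(source_offset, crop_data.shape, parent_shape):
        lo, hi = max(o, 0), min(o + s, n)
        if lo >= hi:
            return out
        dst.append(slice(lo, hi))
        src.append(slice(lo - o, hi - o))
    out[tuple(dst)] = crop_data[tuple(src)]
    return out


def crop_to_roi(
    volume: DixonVolume,
    landmark,
    crop_shape=DEFAULT_CROP_SHAPE,
    side: str = "right",
    mask: Optional[MuscleMask] = None,
    outplane_frac: float = OUTPLANE_LANDMARK_FRAC,
) -> MuscleCrop:
    """Cut a fixed-shape patch around one hip landmark.

    Returns raw (un-normalized) intensities; ``source_offset`` records
    the crop origin so the patch can be re-embedded losslessly.
    """
    landmark = tuple(int(c) for c in landmark)
    if any(c < 0 or c >= s for c, s in zip(landmark, volume.shape)):
        raise ValueError(f"landmark {landmark} outside volume {volume.shape}")
    origin = _crop_origin(landmark, crop_shape, outplane_frac)
    intensities = extract_subvolume(volume.data.astype(np.float32), origin, crop_shape)
    mask_data = None
    if mask is not None:
        if mask.shape != volume.shape:
            raise ValueError("mask grid does not match volume grid")
        mask_data = extract_subvolume(mask.data, origin, crop_shape)
    return MuscleCrop(
        intensities=intensities,
        side=side,
        reflected=False,
        source_offset=origin,
        mask=mask_data,
        voxel_mm=volume.voxel_mm,
    )


def normalize_intensity(intensities: np.ndarray) -> np.ndarray:
    """Scale so the 99th percentile maps to 1 and clip above it."""
    intensities = np.asarray(intensities, dtype=np.float32)
    if intensities.min() < 0:
        raise ValueError("intensities must be non-negative")
    p99 = float(np.percentile(intensities, NORMALIZE_PERCENTILE))
    if p99 <= 0:
        raise DegenerateInputError(
            "99th percentile is zero; cannot normalize an (almost) all-zero crop"
        )
    return np.minimum(intensities / p99, 1.0).astype(np.float32)


def normalize_crop(crop: MuscleCrop) -> MuscleCrop:
    return MuscleCrop(
        intensities=normalize_intensity(crop.intensities),
        side=crop.side,
        reflected=crop.reflected,
        source_offset=crop.source_offset,
        mask=crop.mask,
        voxel_mm=crop.voxel_mm,
    )


def reflect_crop(crop: MuscleCrop) -> MuscleCrop:
    """Mirror along the left-right axis; swaps the side label."""
    return MuscleCrop(
        intensities=crop.intensities[::-1].copy(),
        side="left" if crop.side == "right" else "right",
        reflected=not crop.reflected,
        source_offset=crop.source_offset,
        mask=None if crop.mask is None else crop.mask[::-1].copy(),
        voxel_mm=crop.voxel_mm,
    )


@dataclass
class SubjectCrops:
    """Both muscle crops of one subject, in right-like orientation."""

    subject_id: str
    left: MuscleCrop   # reflected
    right: MuscleCrop


def prepare_subject(
    volume: DixonVolume,
    landmarks: LandmarkSet,
    left_mask: Optional[MuscleMask] = None,
    right_mask: Optional[MuscleMask] = None,
    crop_shape=DEFAULT_CROP_SHAPE,
    subject_id: str = "subject",
    normalize: bool = True,
) -> SubjectCrops:
    """Crop both muscles, normalize each crop, reflect the left one.

    Masks (when given) undergo exactly the same geometric operations as
    the intensities.
    """
    landmarks.validate_inside(volume.shape)
    right = crop_to_roi(volume, landmarks.right_hip, crop_shape, "right", right_mask)
    left = crop_to_roi(volume, landmarks.left_hip, crop_shape, "left", left_mask)
    if normalize:
        right = normalize_crop(right)
        left = normalize_crop(left)
    left = reflect_crop(left)
    left.side = "left"  # reflected to right-like orientation, still the left muscle
    return SubjectCrops(subject_id=subject_id, left=left, right=right)
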