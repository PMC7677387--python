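"""Core volumetric data types.

Axis convention throughout the package: axis 0 runs left-right, axis 1
anterior-posterior (both in-plane), axis 2 inferior-superior
(out-of-plane / slice direction).  Voxel coordinates are 0-based integer
indices; extents are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

#: Acquisition grid spacing in mm (in-plane x2, slice thickness).
DEFAULT_VOXEL_MM: Tuple[float, float, float] = (2.232, 2.232, 3.0)

#: Fixed spatial shape of a single-muscle region of interest.
DEFAULT_CROP_SHAPE: Tuple[int, int, int] = (96, 96, 192)


def voxel_volume_ml(voxel_mm) -> float:
    """Volume of one voxel in millilitres."""
    vx, vy, vz = (float(v) for v in voxel_mm)
    return vx * vy * vz / 1000.0


@dataclass
class DixonVolume:
    """A 3D water-signal intensity field on a regular grid."""

    data: np.ndarray
    voxel_mm: Tuple[float, float, float] = DEFAULT_VOXEL_MM

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a non-empty 3D array")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class MuscleMask:
    """Binary 3D field marking muscle voxels."""

    data: np.ndarray
    voxel_mm: Tuple[float, float, float] = DEFAULT_VOXEL_MM

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)

    def volume_ml(self) -> float:
        return float(self.data.sum()) * voxel_volume_ml(self.voxel_mm)


@dataclass
class LandmarkSet:
    """Per-side hip landmark voxel coordinates (0-based ``(i, j, k)``).

    Under the radiological convention used here the subject's left side
    has the larger first-axis index.
    """

    left_hip: Tuple[int, int, int]
    right_hip: Tuple[int, int, int]

    def __post_init__(self):
        self.left_hip = tuple(int(c) for c in self.left_hip)
        self.right_hip = tuple(int(c) for c in self.right_hip)
        if len(self.left_hip) != 3 or len(self.right_hip) != 3:
            raise ValueError("landmarks must be (i, j, k) triples")

    def validate_inside(self, shape) -> None:
        for name, lm in (("left_hip", self.left_hip), ("right_hip", self.right_hip)):
            if any(c < 0 or c >= s for c, s in zip(lm, shape)):
                raise ValueError(f"{name} {lm} outside grid of shape {tuple(shape)}")


@dataclass
class MuscleCrop:
    """Fixed-shape single-muscle patch cut from a parent volume.

    ``source_offset`` is the crop origin in parent-volume voxel
    coordinates (possibly negative when zero-padding occurred), recorded
    so the crop can be re-embedded losslessly.
    """

    intensities: np.ndarray
    side: str
    reflected: bool = False
    source_offset: Tuple[int, int, int] = (0, 0, 0)
    mask: Optional[np.ndarray] = None
    voxel_mm: Tuple[float, float, float] = DEFAULT_VOXEL_MM

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValueError("crop intensities must be 3D")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.source_offset = tuple(int(c) for c in self.source_offset)
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.intensities.shape:
                raise ValueError("mask shape must match intensities")
            if not np.isin(np.unique(self.mask), (0, 1)).all():
                raise ValueError("crop mask must be binary")
            self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.intensities.shape)
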