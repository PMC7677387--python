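"""NIfTI and CSV input/output."""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DixonVolume, LandmarkSet, MuscleMask


class FormatError(ValueError):
    """Malformed input file."""


def _affine(voxel_mm) -> np.ndarray:
    return np.diag(list(voxel_mm) + [1.0])


def write_volume(volume: DixonVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_mm))
    nib.save(img, str(path))


def write_mask(mask: MuscleMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_mm))
    nib.save(img, str(path))


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types on bad input
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: invalid voxel sizes in header: {zooms}")
    return data, tuple(float(z) for z in zooms)


def read_volume(path) -> DixonVolume:
    data, voxel_mm = _load_nifti(path)
    return DixonVolume(np.clip(data.astype(np.float32), 0.0, None), voxel_mm)


def read_mask(path) -> MuscleMask:
    data, voxel_mm = _load_nifti(path)
    return MuscleMask((data > 0.5).astype(np.uint8), voxel_mm)


LANDMARK_COLUMNS = ["subject_id", "lx", "ly", "lz", "rx", "ry", "rz"]


def write_landmarks(landmarks: Dict[str, LandmarkSet], path) -> None:
    rows = []
    for sid, lm in landmarks.items():
        rows.append([sid, *lm.left_hip, *lm.right_hip])
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks(path) -> Dict[str, LandmarkSet]:
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing landmark columns {missing}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["subject_id"])] = LandmarkSet(
            left_hip=(row["lx"], row["ly"], row["lz"]),
            right_hip=(row["rx"], row["ry"], row["rz"]),
        )
    return out
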