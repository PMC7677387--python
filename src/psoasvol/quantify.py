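"""Per-subject volumetrics: left/right/total volume, asymmetry, muscle
index, and large-scale quality-control flags.

Sign convention: ``lr_diff_ml = left - right``, so negative values mean
the right muscle is larger.  The muscle index is total volume divided by
height squared, in ml/m^2; heights are accepted in cm (>3 is treated as
cm) or m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MuscleMask, voxel_volume_ml

#: fraction of either mask allowed to overlap the other before flagging
OVERLAP_TOLERANCE = 0.01


@dataclass
class QCConfig:
    min_ml: float = 100.0
    max_ml: float = 800.0
    max_asymmetry_fraction: float = 0.25
    outlier_z_threshold: float = 4.0

    def __post_init__(self):
        if self.min_ml >= self.max_ml:
            raise ValueError("min_ml must be below max_ml")
        if self.max_asymmetry_fraction <= 0 or self.outlier_z_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class VolumeRecord:
    subject_id: str
    left_ml: float
    right_ml: float
    total_ml: float
    lr_diff_ml: float
    imi: Optional[float] = None
    gender: Optional[str] = None
    age_years: Optional[float] = None
    height_cm: Optional[float] = None
    bmi: Optional[float] = None
    handedness: Optional[str] = None
    qc_flags: tuple = ()


def mask_to_volume_ml(mask, voxel_mm) -> float:
    """Voxel count times voxel volume, in ml."""
    if isinstance(mask, MuscleMask):
        data = mask.data
        voxel_mm = mask.voxel_mm
    else:
        data = np.asarray(mask)
        if not np.isin(np.unique(data), (0, 1)).all():
            raise ValueError("mask must be binary")
    return float(np.count_nonzero(data)) * voxel_volume_ml(voxel_mm)


def _height_to_m(height) -> float:
    height = float(height)
    if height <= 0:
        raise ValueError("height must be positive")
    return height / 100.0 if height > 3.0 else height


def compute_imi(total_ml: float, height) -> float:
    """Muscle index: total volume / height^2 (ml/m^2)."""
    h = _height_to_m(height)
    return total_ml / (h * h)


def quantify_subject(
    left_mask,
    right_mask,
    demographics: Optional[dict] = None,
    voxel_mm=None,
    subject_id: Optional[str] = None,
) -> VolumeRecord:
    """Build a :class:`VolumeRecord` from the two muscle masks.

    Overlapping masks are flagged (``overlap``), never a failure.
    """
    if isinstance(left_mask, MuscleMask) and isinstance(right_mask, MuscleMask):
        if left_mask.shape != right_mask.shape:
            raise ValueError("left/right masks must share a grid")
        overlap = int(np.count_nonzero(left_mask.data & right_mask.data))
        denom = max(1, min(left_mask.data.sum(), right_mask.data.sum()))
    else:
        l = np.asarray(left_mask)
        r = np.asarray(right_mask)
        if l.shape != r.shape:
            raise ValueError("left/right masks must share a grid")
        overlap = int(np.count_nonzero(l.astype(bool) & r.astype(bool)))
        denom = max(1, min(l.sum(), r.sum()))
    left_ml = mask_to_volume_ml(left_mask, voxel_mm)
    right_ml = mask_to_volume_ml(right_mask, voxel_mm)
    demographics = dict(demographics or {})
    flags = []
    if overlap / denom > OVERLAP_TOLERANCE:
        flags.append("overlap")
    total = left_ml + right_ml
    height = demographics.get("height_cm")
    return VolumeRecord(
        subject_id=subject_id or str(demographics.get("subject_id", "subject")),
        left_ml=left_ml,
        right_ml=right_ml,
        total_ml=total,
        lr_diff_ml=left_ml - right_ml,
        imi=None if height is None else compute_imi(total, height),
        gender=demographics.get("gender"),
        age_years=demographics.get("age_years"),
        height_cm=demographics.get("height_cm"),
        bmi=demographics.get("bmi"),
        handedness=demographics.get("handedness"),
        qc_flags=tuple(flags),
    )


def records_to_table(records: Sequence[VolumeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "gender": r.gender,
            "age_years": r.age_years,
            "height_cm": r.height_cm,
            "bmi": r.bmi,
            "handedness": r.handedness,
            "left_ml": r.left_ml,
            "right_ml": r.right_ml,
            "total_ml": r.total_ml,
            "lr_diff_ml": r.lr_diff_ml,
            "imi": r.imi,
            "qc_flags": ";".join(r.qc_flags),
        })
    return pd.DataFrame(rows)


def qc_screen(records: pd.DataFrame, config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Append QC flags; no record is ever dropped.

    Flags: ``volume_bounds`` (either muscle outside the plausibility
    bounds), ``asymmetric`` (|L-R| / pairwise mean above the configured
    fraction), ``outlier`` (total volume z-score within gender beyond
    the threshold).
    """
    df = records.copy()
    flags = [list(filter(None, f.split(";"))) if isinstance(f, str) else []
             for f in df.get("qc_flags", [""] * len(df))]
    oob = (
        (df["left_ml"] < config.min_ml) | (df["left_ml"] > config.max_ml)
        | (df["right_ml"] < config.min_ml) | (df["right_ml"] > config.max_ml)
    )
    mean_sides = (df["left_ml"] + df["right_ml"]) / 2.0
    asym = (df["lr_diff_ml"].abs() / mean_sides) > config.max_asymmetry_fraction
    z = pd.Series(0.0, index=df.index)
    for _, idx in df.groupby(df.get("gender", "all")).groups.items():
        sub = df.loc[idx, "total_ml"]
        sd = sub.std(ddof=1)
        if sd and sd > 0:
            z.loc[idx] = (sub - sub.mean()) / sd
    outlier = z.abs() > config.outlier_z_threshold
    for i, (o, a, u) in enumerate(zip(oob, asym, outlier)):
        if o:
            flags[i].append("volume_bounds")
        if a:
            flags[i].append("asymmetric")
        if u:
            flags[i].append("outlier")
    df["qc_flags"] = [";".join(dict.fromkeys(f)) for f in flags]
    df["qc_pass"] = [f == "" for f in df["qc_flags"]]
    return df
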