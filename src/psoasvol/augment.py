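"""Training-set expansion: reflection plus random translation/scaling.

Per subject and muscle, the builder emits the original crop and its
reflection, each accompanied by ``n_random_transforms`` randomly
translated/scaled versions: ``2 muscles x 2 reflection states x
(1 + n)`` samples, i.e. 32 per subject at the defaults and 2880 from 90
subjects.

Translations are integer voxel shifts, up to 6 in-plane and 24
out-of-plane; scaling is uniform within +/-25% in-plane (one factor
shared by both in-plane axes) and +/-50% out-of-plane, applied about
the crop centre.  Intensities are resampled trilinearly, masks with
nearest-neighbour, both through the same geometric map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import affine_transform

from .core import MuscleCrop
from .preprocess import SubjectCrops, reflect_crop


@dataclass
class AugmentationSpec:
    n_random_transforms: int = 7
    max_shift_inplane: int = 6
    max_shift_outplane: int = 24
    scale_range_inplane: Tuple[float, float] = (-0.25, 0.25)
    scale_range_outplane: Tuple[float, float] = (-0.50, 0.50)
    include_reflections: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_random_transforms < 0:
            raise ValueError("n_random_transforms must be >= 0")
        if self.max_shift_inplane < 0 or self.max_shift_outplane < 0:
            raise ValueError("shift bounds must be >= 0")
        for lo, hi in (self.scale_range_inplane, self.scale_range_outplane):
            if lo > hi or lo <= -1.0:
                raise ValueError("scale ranges must satisfy -1 < lo <= hi")

    @property
    def samples_per_subject(self) -> int:
        states = 2 if self.include_reflections else 1
        return 2 * states * (1 + self.n_random_transforms)


@dataclass
class TransformParams:
    """One random transform: per-axis integer shift and scale factors
    (the two in-plane axes share one factor)."""

    shift: Tuple[int, int, int] = (0, 0, 0)
    scale: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def is_identity(self) -> bool:
        return all(s == 0 for s in self.shift) and all(s == 1.0 for s in self.scale)


def sample_transform(spec: AugmentationSpec, rng: np.random.Generator) -> TransformParams:
    """Draw shifts (uniform integers) and scales (uniform) within bounds."""
    si = spec.max_shift_inplane
    so = spec.max_shift_outplane
    shift = (
        int(rng.integers(-si, si + 1)),
        int(rng.integers(-si, si + 1)),
        int(rng.integers(-so, so + 1)),
    )
    lo_i, hi_i = spec.scale_range_inplane
    lo_o, hi_o = spec.scale_range_outplane
    s_in = 1.0 + rng.uniform(lo_i, hi_i)
    s_out = 1.0 + rng.uniform(lo_o, hi_o)
    return TransformParams(shift=shift, scale=(s_in, s_in, s_out))


def _resample(data, params: TransformParams, order: int):
    scale = np.asarray(params.scale, dtype=float)
    shift = np.asarray(params.shift, dtype=float)
    centre = (np.asarray(data.shape, dtype=float) - 1.0) / 2.0
    # output(x) = input((x - centre - shift) / scale + centre)
    matrix = np.diag(1.0 / scale)
    offset = centre - (centre + shift) / scale
    return affine_transform(
        data.astype(np.float32),
        matrix=matrix,
        offset=offset,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )


def apply_transform(crop: MuscleCrop, params: TransformParams) -> MuscleCrop:
    """Shift/scale a crop about its centre; shape is unchanged and
    out-of-field voxels are zero."""
    if params.is_identity():
        return MuscleCrop(
            intensities=crop.intensities.copy(),
            side=crop.side,
            reflected=crop.reflected,
            source_offset=crop.source_offset,
            mask=None if crop.mask is None else crop.mask.copy(),
            voxel_mm=crop.voxel_mm,
        )
    intensities = _resample(crop.intensities, params, order=1)
    mask = None
    if crop.mask is not None:
        mask = _resample(crop.mask, params, order=0).astype(np.uint8)
    return MuscleCrop(
        intensities=np.clip(intensities, 0.0, 1.0).astype(np.float32),
        side=crop.side,
        reflected=crop.reflected,
        source_offset=crop.source_offset,
        mask=mask,
        voxel_mm=crop.voxel_mm,
    )


@dataclass
class TrainingSample:
    subject_id: str
    side: str
    reflected_variant: bool
    transform_index: int  # 0 = untransformed original
    crop: MuscleCrop


def iter_training_samples(
    subjects: Sequence[SubjectCrops], spec: AugmentationSpec
) -> Iterable[TrainingSample]:
    """Lazily yield augmented samples (see module docstring for the
    count bookkeeping)."""
    rng = np.random.default_rng(spec.seed)
    for subj in subjects:
        for crop in (subj.left, subj.right):
            if crop.mask is None:
                raise ValueError(
                    f"subject {subj.subject_id}: crop '{crop.side}' has no mask; "
                    "training requires annotated crops"
                )
            variants = [(False, crop)]
            if spec.include_reflections:
                variants.append((True, reflect_crop(crop)))
            for refl, base in variants:
                yield TrainingSample(subj.subject_id, crop.side, refl, 0, base)
                for t in range(spec.n_random_transforms):
                    params = sample_transform(spec, rng)
                    yield TrainingSample(
                        subj.subject_id, crop.side, refl, t + 1,
                        apply_transform(base, params),
                    )


def build_training_set(
    subjects: Sequence[SubjectCrops], spec: AugmentationSpec
) -> List[TrainingSample]:
    """Materialize the full augmented training set."""
    return list(iter_training_samples(subjects, spec))
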