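"""Dixon-like phantom volumes and synthetic cohorts with known truth.

Two generators live here:

* :func:`generate_phantom` builds a water-image-like 3D volume holding a
  bilateral pair of curved, tapering tubular "muscles" with ground-truth
  masks, hip landmarks at the inferior muscle ends, and exact target
  volumes.
* :func:`generate_cohort` draws per-subject demographics and target
  left/right muscle volumes whose joint distribution matches the
  published population summaries (gender-specific volume means/SDs,
  height, BMI, age range, left-right asymmetry, muscle-index
  correlations with BMI and age, and the male post-changepoint
  acceleration of age-related decline).

The cohort model is structural: a muscle index (volume / height^2) is
drawn with additive age and BMI components plus noise, and total volume
is the index times height squared.  With the published marginals this
reproduces the reported volume mean/SD and the volume-height rank
correlation without further tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter

from .core import DEFAULT_VOXEL_MM, DixonVolume, LandmarkSet, MuscleMask, voxel_volume_ml


class PhantomSizingError(ValueError):
    """Raised when a target muscle volume cannot fit in the grid."""


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and appearance of a bilateral muscle phantom."""

    grid_shape: Tuple[int, int, int] = (144, 112, 200)
    voxel_mm: Tuple[float, float, float] = DEFAULT_VOXEL_MM
    muscle_length_mm: float = 280.0
    lateral_offset_mm: float = 55.0
    taper_exponent: float = 0.5
    curvature_mm: float = 20.0
    lr_volume_ratio: float = 1.0
    noise_sd: float = 0.03
    blur_mm: float = 2.0
    background_structures: bool = True
    inferior_margin_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be positive")
        if self.muscle_length_mm <= 0:
            raise ValueError("muscle_length_mm must be positive")

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """Small grid sized for CPU tests (muscles of ~40-80 ml)."""
        base = dict(
            grid_shape=(64, 48, 80),
            muscle_length_mm=100.0,
            lateral_offset_mm=32.0,
            curvature_mm=8.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PhantomSubject:
    """One simulated subject: volume, truth masks, landmarks, truth volumes."""

    subject_id: str
    volume: Optional[DixonVolume]
    left_mask: MuscleMask
    right_mask: MuscleMask
    landmarks: LandmarkSet
    true_left_ml: float
    true_right_ml: float
    demographics: Optional[dict] = None


def _taper(t: np.ndarray, exponent: float) -> np.ndarray:
    return np.sin(np.pi * t) ** exponent


def _tube_geometry(spec: PhantomSpec):
    """Per-slice parameters shared by both sides (index/mm mixed units)."""
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_mm
    n_slices = int(round(spec.muscle_length_mm / vz))
    k0 = int(round(spec.inferior_margin_frac * nz))
    if k0 + n_slices > nz - 1:
        raise PhantomSizingError(
            f"muscle of {n_slices} slices does not fit in grid of {nz} slices"
        )
    t = (np.arange(n_slices) + 0.5) / n_slices
    shape = _taper(t, spec.taper_exponent)
    # lateral distance of the centerline from the mid-sagittal plane (mm),
    # bowing outward mid-length
    lateral_mm = spec.lateral_offset_mm + spec.curvature_mm * 4.0 * t * (1.0 - t)
    return k0, t, shape, lateral_mm


def _solve_radius(spec: PhantomSpec, target_ml: float, shape: np.ndarray) -> float:
    """Peak tube radius (mm) whose analytic volume hits the target."""
    vz = spec.voxel_mm[2]
    denom = np.pi * vz * float(np.sum(shape ** 2))
    return float(np.sqrt(target_ml * 1000.0 / denom))


def _check_fit(spec: PhantomSpec, r_max: float, lateral_mm: np.ndarray) -> None:
    nx = spec.grid_shape[0]
    vx = spec.voxel_mm[0]
    half_fov = (nx - 1) * vx / 2.0
    margin = 2.0 * vx
    if r_max + lateral_mm.max() > half_fov - margin:
        raise PhantomSizingError(
            f"tube (radius {r_max:.1f} mm) exceeds the lateral field of view"
        )
    if r_max + margin > lateral_mm.min():
        raise PhantomSizingError(
            f"tube (radius {r_max:.1f} mm) would cross the mid-sagittal plane"
        )


def _voxelize_tube(
    spec: PhantomSpec, side: str, radius_mm: float, shape: np.ndarray,
    lateral_mm: np.ndarray, k0: int,
) -> np.ndarray:
    """Rasterize one tube.  Centre coordinates are expressed in exact
    index arithmetic so that mirrored sides voxelize to exact mirror
    images when their radii agree."""
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_mm
    mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    ii = np.arange(nx, dtype=np.float64)[:, None]
    jj = np.arange(ny, dtype=np.float64)[None, :]
    cj = (ny - 1) / 2.0
    dy2 = ((jj - cj) * vy) ** 2
    mid = (nx - 1) / 2.0
    for s in range(shape.size):
        # centre index along x; left side mirrors right about the grid centre
        ci = mid + lateral_mm[s] / vx
        if side == "right":
            ci = (nx - 1) - ci
        r = radius_mm * shape[s]
        inside = ((ii - ci) * vx) ** 2 + dy2 <= r * r
        mask[:, :, k0 + s] |= inside.astype(np.uint8)
    return mask


def _make_side_mask(spec: PhantomSpec, side: str, target_ml: float):
    """Build one tube mask, refining the radius so the voxelized volume
    matches the target closely (two fixed-point iterations)."""
    k0, t, shape, lateral_mm = _tube_geometry(spec)
    radius = _solve_radius(spec, target_ml, shape)
    _check_fit(spec, radius, lateral_mm)
    vox_ml = voxel_volume_ml(spec.voxel_mm)
    mask = _voxelize_tube(spec, side, radius, shape, lateral_mm, k0)
    for _ in range(2):
        achieved = mask.sum() * vox_ml
        if achieved <= 0:
            raise PhantomSizingError(
                f"target volume {target_ml} ml rasterizes to an empty mask"
            )
        radius *= np.sqrt(target_ml / achieved)
        _check_fit(spec, radius, lateral_mm)
        mask = _voxelize_tube(spec, side, radius, shape, lateral_mm, k0)
    # landmark: centreline voxel at the inferior end of the muscle
    nx = spec.grid_shape[0]
    vx = spec.voxel_mm[0]
    mid = (nx - 1) / 2.0
    ci = mid + lateral_mm[0] / vx
    if side == "right":
        ci = (nx - 1) - ci
    landmark = (int(round(ci)), int(round((spec.grid_shape[1] - 1) / 2.0)), k0)
    return mask, landmark


def _render_intensities(spec: PhantomSpec, muscle: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Water-image-like contrast: muscle 0.7, fat rind 1.0, body 0.1."""
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_mm
    img = np.zeros(spec.grid_shape, dtype=np.float32)
    ii = np.arange(nx)[:, None]
    jj = np.arange(ny)[None, :]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = 0.95 * cx, 0.95 * cy
    e = ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2
    body = e <= 1.0
    img[:] = np.where(body, 0.1, 0.0)[:, :, None]
    if spec.background_structures:
        rind = body & (e > 0.8)
        img[:] = np.where(rind, 1.0, img[..., 0])[:, :, None]
        # spine-like bright cylinder, posterior of centre
        sy = cy + 0.55 * cy
        r_spine = 15.0
        spine = ((ii - cx) * vx) ** 2 + ((jj - sy) * vy) ** 2 <= r_spine ** 2
        img[:] = np.where(spine & body, 0.5, img[..., 0])[:, :, None]
    img[muscle > 0] = 0.7
    if spec.blur_mm > 0:
        sigma = [spec.blur_mm / v for v in spec.voxel_mm]
        img = gaussian_filter(img, sigma=sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape).astype(np.float32)
    return np.clip(img, 0.0, None).astype(np.float32)


def generate_phantom(
    spec: PhantomSpec,
    target_left_ml: float,
    target_right_ml: float,
    subject_id: str = "phantom",
    demographics: Optional[dict] = None,
    with_intensities: bool = True,
) -> PhantomSubject:
    """Simulate one subject with mask volumes within 3% of the targets.

    ``with_intensities=False`` skips image synthesis (masks and
    landmarks only), which is much faster for volumetry-only studies.
    """
    if target_left_ml <= 0 or target_right_ml <= 0:
        raise PhantomSizingError("target volumes must be positive")
    left_mask, left_lm = _make_side_mask(spec, "left", target_left_ml)
    right_mask, right_lm = _make_side_mask(spec, "right", target_right_ml)
    if (left_mask & right_mask).any():
        raise PhantomSizingError("left and right tubes overlap")
    vox_ml = voxel_volume_ml(spec.voxel_mm)
    true_left = float(left_mask.sum()) * vox_ml
    true_right = float(right_mask.sum()) * vox_ml
    for name, true, target in (
        ("left", true_left, target_left_ml),
        ("right", true_right, target_right_ml),
    ):
        if abs(true - target) > 0.03 * target:
            raise PhantomSizingError(
                f"{name} mask volume {true:.1f} ml misses target {target:.1f} ml"
            )
    volume = None
    if with_intensities:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, _stable_id_hash(subject_id)])
        )
        img = _render_intensities(spec, left_mask | right_mask, rng)
        volume = DixonVolume(img, spec.voxel_mm)
    return PhantomSubject(
        subject_id=subject_id,
        volume=volume,
        left_mask=MuscleMask(left_mask, spec.voxel_mm),
        right_mask=MuscleMask(right_mask, spec.voxel_mm),
        landmarks=LandmarkSet(left_hip=left_lm, right_hip=right_lm),
        true_left_ml=true_left,
        true_right_ml=true_right,
        demographics=demographics,
    )


def _stable_id_hash(subject_id: str) -> int:
    import zlib

    return zlib.crc32(subject_id.encode())


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GenderParams:
    """Marginals and dependence targets for one gender."""

    total_volume_mean: float
    total_volume_sd: float
    total_volume_range: Tuple[float, float]
    imi_mean: float
    imi_sd: float
    height_mean_cm: float
    height_sd_cm: float
    bmi_mean: float
    bmi_sd: float
    bmi_range: Tuple[float, float]
    age_mean: float
    age_sd: float
    age_range: Tuple[float, float] = (44.0, 82.0)
    lr_diff_mean: float = -6.5
    lr_diff_sd: float = 16.0
    lr_diff_range: Tuple[float, float] = (-100.0, 100.0)
    imi_bmi_rho: float = 0.47
    imi_age_rho: float = -0.11
    #: age at which the decline steepens; None = single linear slope
    age_changepoint: Optional[float] = None
    #: post-changepoint slope as a multiple of the pre-changepoint slope
    accel_factor: float = 4.0

    def __post_init__(self):
        for sd in (self.total_volume_sd, self.imi_sd, self.height_sd_cm,
                   self.bmi_sd, self.age_sd, self.lr_diff_sd):
            if sd <= 0:
                raise ValueError("all SDs must be positive")
        if not (44.0 <= self.age_range[0] < self.age_range[1] <= 82.0):
            raise ValueError("age range must lie within [44, 82]")
        for rho in (self.imi_bmi_rho, self.imi_age_rho):
            if not -1.0 < rho < 1.0:
                raise ValueError("correlation targets must be in (-1, 1)")


@dataclass
class CohortParams:
    """Cohort-level simulation parameters (both genders + handedness)."""

    female: GenderParams
    male: GenderParams
    handedness_proportions: Dict[str, float] = field(
        default_factory=lambda: {"right": 0.9, "left": 0.1}
    )
    seed: int = 0

    @classmethod
    def from_study(cls, seed: int = 0) -> "CohortParams":
        """Parameters matching the published population summaries."""
        female = GenderParams(
            total_volume_mean=542.3, total_volume_sd=72.1,
            total_volume_range=(307.5, 904.2),
            imi_mean=205.1, imi_sd=22.6,
            height_mean_cm=162.5, height_sd_cm=6.1,
            bmi_mean=26.2, bmi_sd=4.7, bmi_range=(16.1, 55.2),
            age_mean=63.3, age_sd=8.3,
            lr_diff_mean=-6.5, lr_diff_sd=16.1, lr_diff_range=(-96.9, 62.5),
            imi_bmi_rho=0.47, imi_age_rho=-0.11, age_changepoint=None,
        )
        male = GenderParams(
            total_volume_mean=814.5, total_volume_sd=125.4,
            total_volume_range=(467.3, 1311.5),
            imi_mean=261.8, imi_sd=34.2,
            height_mean_cm=176.2, height_sd_cm=6.8,
            bmi_mean=27.0, bmi_sd=3.9, bmi_range=(17.6, 50.9),
            age_mean=63.3, age_sd=8.4,
            lr_diff_mean=-7.3, lr_diff_sd=22.8, lr_diff_range=(-95.6, 184.4),
            imi_bmi_rho=0.48, imi_age_rho=-0.31,
            age_changepoint=62.0, accel_factor=4.0,
        )
        return cls(female=female, male=male, seed=seed)


from functools import lru_cache


@lru_cache(maxsize=256)
def _truncnorm_underlying(target_mean, target_sd, lo, hi):
    """Solve for the underlying (mu, sigma) so the truncated normal has
    the requested mean and SD."""

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [d.mean() - target_mean, d.std() - target_sd]

    sol = optimize.fsolve(moments, [target_mean, np.log(target_sd)], full_output=False)
    mu, sigma = sol[0], float(np.exp(sol[1]))
    return mu, sigma


def _stratified_uniform(rng, n):
    """One draw per probability stratum, in shuffled order: keeps the
    marginal essentially exact (sample-mean error O(1/n) instead of
    O(1/sqrt(n))) while leaving the joint structure random."""
    return (rng.permutation(n) + rng.uniform(size=n)) / n


def _stratified_normal(rng, n):
    return stats.norm.ppf(_stratified_uniform(rng, n))


def _sample_truncnorm(rng, target_mean, target_sd, lo, hi, n):
    mu, sigma = _truncnorm_underlying(target_mean, target_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma).ppf(
        _stratified_uniform(rng, n))


def _age_shape(age: np.ndarray, gp: GenderParams) -> np.ndarray:
    """Unit-slope piecewise-linear decline profile (before centring)."""
    if gp.age_changepoint is None:
        return age.astype(float)
    cp, k = gp.age_changepoint, gp.accel_factor
    return age + (k - 1.0) * np.maximum(0.0, age - cp)


def _simulate_gender(rng, gp: GenderParams, n: int, gender: str,
                     prefix: str) -> pd.DataFrame:
    # age at recruitment is reported in whole years
    age = np.round(_sample_truncnorm(rng, gp.age_mean, gp.age_sd,
                                     *gp.age_range, n))
    height = gp.height_mean_cm + gp.height_sd_cm * _stratified_normal(rng, n)
    bmi = _sample_truncnorm(rng, gp.bmi_mean, gp.bmi_sd, *gp.bmi_range, n)

    # additive muscle-index model: imi = mean + age component + BMI
    # component + noise, with loadings calibrated on the drawn sample so
    # the rank-correlation targets are met
    u = _age_shape(age, gp)
    sd_u = u.std()
    sd_b = bmi.std()
    if n < 2 or sd_u == 0 or sd_b == 0:
        # degenerate cohort: no covariate structure to calibrate against
        alpha = beta = 0.0
        sd_eps = gp.imi_sd
    else:
        c_age = np.corrcoef(u, age)[0, 1]
        alpha = abs(gp.imi_age_rho) * gp.imi_sd / (sd_u * c_age)
        beta = gp.imi_bmi_rho * gp.imi_sd / sd_b
        var_eps = gp.imi_sd ** 2 - (alpha * sd_u) ** 2 - (beta * sd_b) ** 2
        if var_eps <= 0:
            raise ValueError("correlation targets leave no residual variance")
        sd_eps = np.sqrt(var_eps)

    h2 = (height / 100.0) ** 2
    # centre the index so E[total] = E[imi] * E[height^2] hits the
    # configured total-volume mean exactly (stays within rounding of the
    # configured index mean)
    e_h2 = (gp.height_mean_cm ** 2 + gp.height_sd_cm ** 2) / 1e4
    base_imi = gp.total_volume_mean / e_h2
    lo, hi = gp.total_volume_range
    comp = (base_imi - alpha * (u - u.mean()) + beta * (bmi - bmi.mean()))
    imi = comp + sd_eps * _stratified_normal(rng, n)
    total = imi * h2
    redraw = (total < lo) | (total > hi)
    for _ in range(100):
        m = int(redraw.sum())
        if m == 0:
            break
        imi[redraw] = comp[redraw] + rng.normal(0.0, sd_eps, m)
        total[redraw] = imi[redraw] * h2[redraw]
        redraw = (total < lo) | (total > hi)
    total = np.clip(total, lo, hi)
    imi = total / h2

    lr = _sample_truncnorm(rng, gp.lr_diff_mean, gp.lr_diff_sd,
                           *gp.lr_diff_range, n)
    left = (total + lr) / 2.0
    right = (total - lr) / 2.0
    return pd.DataFrame({
        "subject_id": [f"{prefix}{i:05d}" for i in range(n)],
        "gender": gender,
        "age_years": age,
        "height_cm": height,
        "weight_kg": bmi * (height / 100.0) ** 2,
        "bmi": bmi,
        "target_left_ml": left,
        "target_right_ml": right,
        "target_total_ml": total,
        "target_imi": imi,
    })


def generate_cohort(params: CohortParams, n_female: int, n_male: int) -> pd.DataFrame:
    """Draw a cohort table; fully determined by ``params.seed``."""
    if n_female < 0 or n_male < 0 or n_female + n_male < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(params.seed)
    frames = []
    if n_female:
        frames.append(_simulate_gender(rng, params.female, n_female, "female", "F"))
    if n_male:
        frames.append(_simulate_gender(rng, params.male, n_male, "male", "M"))
    df = pd.concat(frames, ignore_index=True)
    hands = list(params.handedness_proportions)
    probs = np.array([params.handedness_proportions[h] for h in hands], dtype=float)
    probs = probs / probs.sum()
    df["handedness"] = rng.choice(hands, size=len(df), p=probs)
    return df
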