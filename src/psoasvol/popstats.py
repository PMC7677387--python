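"""Population statistics: normality gating, rank-based tests,
correlations and the spline age-trend of the muscle index.

Conventions: all tests are two-sided; the significance threshold is
0.05; no multiple-testing correction (exploratory analysis).  The
Wilcoxon tests use their exact null distribution for small samples
(combined n <= 12 for the rank-sum test, n <= 12 non-zero differences
for the signed-rank test) and the tie/continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import interpolate, stats

EXACT_N_LIMIT = 12


@dataclass
class StatTestResult:
    test_name: str
    statistic: float
    p_value: float
    effect: Dict[str, float] = field(default_factory=dict)
    n: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")


def normality_gate(sample, name: str = "sample") -> StatTestResult:
    """Shapiro-Wilk test; p < 0.05 routes downstream analysis to
    rank-based tests."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    w, p = stats.shapiro(x)
    return StatTestResult(
        test_name="shapiro_wilk",
        statistic=float(w),
        p_value=float(p),
        effect={"variable": 0.0, "normal": float(p >= 0.05)},
        n={name: int(x.size)},
    )


def spearman_rho(x, y) -> StatTestResult:
    """Rank correlation with mid-ranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ranks")
    res = stats.spearmanr(x, y)
    return StatTestResult(
        test_name="spearman",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect={"rho": float(res.statistic)},
        n={"pairs": int(x.size)},
    )


def rank_sum_test(group_a, group_b) -> StatTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    method = "exact" if a.size + b.size <= EXACT_N_LIMIT else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatTestResult(
        test_name=f"wilcoxon_rank_sum[{method}]",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect={
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
        },
        n={"a": int(a.size), "b": int(b.size)},
    )


def signed_rank_test(paired_left, paired_right) -> StatTestResult:
    """Two-sided Wilcoxon signed-rank test on left - right differences.

    Zero differences are dropped; reports the mean difference ``d``.
    """
    l = np.asarray(paired_left, dtype=float)
    r = np.asarray(paired_right, dtype=float)
    if l.shape != r.shape or l.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    diff = l - r
    nz = diff[diff != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if nz.size <= EXACT_N_LIMIT else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return StatTestResult(
        test_name=f"wilcoxon_signed_rank[{method}]",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect={"d": float(diff.mean())},
        n={"pairs": int(l.size), "nonzero": int(nz.size)},
    )


@dataclass
class TrendFit:
    """Penalized cubic smoothing-spline fit of one gender's
    index-versus-age trend, with numerical first derivative."""

    gender: str
    age_grid: np.ndarray
    fitted: np.ndarray
    derivative: np.ndarray
    lam: Optional[float] = None

    def mean_derivative(self, lo: float, hi: float) -> float:
        sel = (self.age_grid >= lo) & (self.age_grid <= hi)
        if not sel.any():
            raise ValueError("empty derivative window")
        return float(self.derivative[sel].mean())


def _bspline_basis(x, lo, hi, n_basis):
    """Cubic B-spline design matrix with quantile-free uniform interior
    knots on [lo, hi]."""
    degree = 3
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    design = interpolate.BSpline.design_matrix(
        np.clip(x, lo, hi), t, degree).toarray()
    return design, t


def _second_derivative_penalty(knots, n_basis):
    """Exact integral penalty ``P_ij = int B_i'' B_j''`` for cubic
    B-splines (two-point Gauss per interval integrates the piecewise-
    quadratic products exactly).  Its null space holds all linear
    functions, so an unpenalized straight line stays a straight line."""
    spans = np.unique(knots)
    pen = np.zeros((n_basis, n_basis))
    gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    all_basis = interpolate.BSpline(knots, np.eye(n_basis), 3,
                                    extrapolate=False)
    for a, b in zip(spans[:-1], spans[1:]):
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gauss_x
        d2 = np.nan_to_num(all_basis(pts, nu=2))  # (n_pts, n_basis)
        pen += half * (d2.T @ d2)
    return pen


def fit_age_trend(age, imi, gender: str = "all", n_grid: int = 200,
                  n_basis: int = 10) -> TrendFit:
    """Penalized cubic regression spline of index on age.

    Ten cubic B-spline basis functions with a second-difference penalty
    on the coefficients; the penalty weight is chosen by generalized
    cross-validation over a log-spaced grid.  Replicate ages are
    aggregated to weighted means (an equivalent formulation for a linear
    smoother).
    """
    age = np.asarray(age, dtype=float)
    imi = np.asarray(imi, dtype=float)
    if age.size != imi.size or age.size < 20:
        raise ValueError("need at least 20 (age, index) pairs")
    ux, inv, counts = np.unique(age, return_inverse=True, return_counts=True)
    if ux.size < 5:
        raise ValueError("too few distinct ages for a spline fit")
    ymean = np.bincount(inv, weights=imi) / counts
    w = counts.astype(float)
    lo, hi = float(ux.min()), float(ux.max())
    basis, knots = _bspline_basis(ux, lo, hi, n_basis)
    pen = _second_derivative_penalty(knots, n_basis)
    bw = basis * w[:, None]
    btb = basis.T @ bw
    bty = bw.T @ ymean
    n_eff = float(w.sum())
    best = (np.inf, None, None)
    for lam in np.logspace(-3, 7, 41):
        a = btb + lam * pen
        coef = np.linalg.solve(a, bty)
        fitted = basis @ coef
        rss = float(w @ (ymean - fitted) ** 2)
        # tr(H) of the weighted linear smoother
        edf = float(np.trace(np.linalg.solve(a, btb)))
        gcv = n_eff * rss / (n_eff - edf) ** 2
        if gcv < best[0]:
            best = (gcv, coef, lam)
    _, coef, lam = best
    spl = interpolate.BSpline(knots, coef, 3)
    grid = np.linspace(lo, hi, n_grid)
    return TrendFit(
        gender=gender,
        age_grid=grid,
        fitted=spl(grid),
        derivative=spl.derivative()(grid),
        lam=float(lam),
    )


def handedness_association(records: pd.DataFrame) -> StatTestResult:
    """Rank-sum test of the left-right volume difference between right-
    and left-handed subjects (the study reports only that no association
    was found; the test choice is ours)."""
    groups = records.groupby("handedness")["lr_diff_ml"]
    keys = [k for k, g in groups if len(g) > 0]
    if len(keys) < 2:
        raise ValueError("need at least two handedness groups")
    a = groups.get_group("right") if "right" in keys else groups.get_group(keys[0])
    b = groups.get_group("left") if "left" in keys else groups.get_group(keys[1])
    res = rank_sum_test(a.to_numpy(), b.to_numpy())
    res.test_name = "handedness_" + res.test_name
    return res


def analyze_cohort(records: pd.DataFrame) -> dict:
    """Full population analysis of a quantified cohort table.

    Returns a JSON-serializable report: per-variable normality gates,
    gender comparison of total volume, the paired left-right asymmetry
    test per gender, the volume-height / index-BMI / index-age rank
    correlations per gender, handedness association, and per-gender age
    trends of the muscle index.
    """
    report: dict = {"n": int(len(records)), "tests": {}, "trends": {}}

    def put(name, fn, *args, **kwargs):
        # a test that cannot run on this cohort (too small, degenerate)
        # is recorded, never fatal
        try:
            res = fn(*args, **kwargs)
        except ValueError as exc:
            report["tests"][name] = {"error": str(exc)}
            return
        report["tests"][name] = {
            "test": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "effect": res.effect,
            "n": res.n,
        }

    for var in ("total_ml", "lr_diff_ml", "imi"):
        put(f"normality_{var}", normality_gate, records[var].dropna(), var)
    genders = [g for g in ("female", "male") if (records["gender"] == g).any()]
    if len(genders) == 2:
        f = records[records["gender"] == "female"]
        m = records[records["gender"] == "male"]
        put("total_volume_by_gender", rank_sum_test,
            m["total_ml"], f["total_ml"])
    for g in genders:
        sub = records[records["gender"] == g]
        put(f"lr_asymmetry_{g}", signed_rank_test,
            sub["left_ml"], sub["right_ml"])
        put(f"volume_vs_height_{g}", spearman_rho,
            sub["total_ml"], sub["height_cm"])
        if sub["imi"].notna().all():
            put(f"imi_vs_bmi_{g}", spearman_rho, sub["imi"], sub["bmi"])
            put(f"imi_vs_age_{g}", spearman_rho, sub["imi"], sub["age_years"])
            try:
                trend = fit_age_trend(sub["age_years"], sub["imi"], gender=g)
            except ValueError as exc:
                report["trends"][g] = {"error": str(exc)}
            else:
                report["trends"][g] = {
                    "age_grid": trend.age_grid.tolist(),
                    "fitted": trend.fitted.tolist(),
                    "mean_slope_45_60": trend.mean_derivative(45, 60),
                    "mean_slope_65_80": trend.mean_derivative(65, 80),
                }
    if "handedness" in records and records["handedness"].nunique() > 1:
        put("handedness", handedness_association, records)
    return report
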