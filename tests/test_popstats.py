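"""Statistical tests against independent enumeration/brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psoasvol.popstats import (
    analyze_cohort,
    fit_age_trend,
    handedness_association,
    normality_gate,
    rank_sum_test,
    signed_rank_test,
    spearman_rho,
)
from psoasvol.synthetic import CohortParams, generate_cohort


# -- independent oracles ----------------------------------------------------

def exact_rank_sum_p(a, b):
    """Two-sided p by enumerating all C(n_a+n_b, n_a) rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    all_sums = [sum(c) for c in itertools.combinations(ranks, n_a)]
    mean = np.mean(all_sums)
    extreme = sum(1 for s in all_sums if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(all_sums)


def exact_signed_rank_p(diff):
    """Two-sided p by enumerating all 2^n sign patterns."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    ranks = stats.rankdata(np.abs(diff))
    obs = ranks[diff > 0].sum()
    n = len(diff)
    total = ranks.sum()
    wplus = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([0, 1], repeat=n)]
    mean = total / 2.0
    extreme = sum(1 for w in wplus if abs(w - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(wplus)


def brute_spearman(x, y):
    """Rank with mid-ranks, then plain product-moment correlation."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


# -- tests ------------------------------------------------------------------

class TestNormalityGate:
    def test_lognormal_rejected(self):
        x = np.random.default_rng(0).lognormal(0, 1, 500)
        res = normality_gate(x)
        assert res.p_value < 0.05
        assert res.effect["normal"] == 0.0

    def test_gaussian_usually_passes(self):
        x = np.random.default_rng(1).normal(0, 1, 200)
        assert normality_gate(x).p_value > 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normality_gate(np.ones(10))

    def test_too_small(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x ** 3).statistic == pytest.approx(1.0)
        assert spearman_rho(x, -x).statistic == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 5.0])
        assert spearman_rho(x, y).statistic == pytest.approx(
            brute_spearman(x, y), abs=1e-12)

    def test_exhaustive_n5_permutations(self):
        x = np.arange(5.0)
        for perm in itertools.permutations(range(5)):
            y = np.array(perm, dtype=float)
            assert spearman_rho(x, y).statistic == pytest.approx(
                brute_spearman(x, y), abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(5), np.arange(5.0))


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert "exact" in res.test_name

    def test_most_extreme_small_sample(self):
        # A={1,2,3} vs B={10,11,12}: 2 of the 20 rank assignments are as
        # extreme, exact two-sided p = 0.1
        res = rank_sum_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.p_value == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.8, 1, 6)
            res = rank_sum_test(a, b)
            assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=1e-9)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(3)
        res = rank_sum_test(rng.normal(0, 1, 300), rng.normal(3, 1, 300))
        assert res.p_value < 1e-6
        assert "asymptotic" in res.test_name

    def test_exact_vs_asymptotic_agree_at_crossover(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        p_exact = stats.mannwhitneyu(a, b, method="exact").pvalue
        p_asym = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.02

    def test_empty_group(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSignedRank:
    def test_all_zero_differences(self):
        with pytest.raises(ValueError, match="zero"):
            signed_rank_test([1.0, 2.0], [1.0, 2.0])

    def test_most_extreme_three_pairs(self):
        # differences {1,2,3}: W+ = 6; 2 of 8 sign patterns as extreme
        res = signed_rank_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(0.25)
        assert res.effect["d"] == pytest.approx(2.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.normal(0.5, 1, 8)
            d = d[d != 0]
            res = signed_rank_test(d, np.zeros_like(d))
            assert res.p_value == pytest.approx(exact_signed_rank_p(d), abs=1e-9)

    def test_exact_vs_approx_agree_at_crossover(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.7, 1, 12)
        p_exact = stats.wilcoxon(d, method="exact").pvalue
        p_approx = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert abs(p_exact - p_approx) < 0.02

    def test_cohort_asymmetry_recovery(self):
        # synthetic female cohort at the configured L-R offset
        df = generate_cohort(CohortParams.from_study(seed=21), 2496, 0)
        res = signed_rank_test(df["target_left_ml"], df["target_right_ml"])
        se = 16.1 / np.sqrt(2496)
        assert res.effect["d"] == pytest.approx(-6.5, abs=2 * se)
        assert res.p_value < 1e-15


class TestAgeTrend:
    def test_noiseless_linear_data_reproduced(self):
        age = np.linspace(45, 80, 100)
        imi = 260.0 - 0.8 * age
        fit = fit_age_trend(age, imi)
        assert np.allclose(fit.fitted, 260.0 - 0.8 * fit.age_grid, atol=1e-6)
        assert np.allclose(fit.derivative, -0.8, atol=1e-6)

    def test_male_changepoint_acceleration(self):
        df = generate_cohort(CohortParams.from_study(seed=8), 0, 2500)
        fit = fit_age_trend(df["age_years"], df["target_imi"], gender="male")
        early = fit.mean_derivative(45, 60)
        late = fit.mean_derivative(65, 80)
        assert late < early < 0

    def test_female_roughly_constant_slope(self):
        # seeded: the female decline is shallow relative to the noise,
        # so the derivative ratio is only loosely pinned
        df = generate_cohort(CohortParams.from_study(seed=1), 2500, 0)
        fit = fit_age_trend(df["age_years"], df["target_imi"], gender="female")
        early = fit.mean_derivative(45, 60)
        late = fit.mean_derivative(65, 80)
        assert early < 0 and late < 0
        assert 0.5 < late / early < 2.0

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            fit_age_trend(np.arange(5.0), np.arange(5.0))


def _handed_records(df):
    return pd.DataFrame({
        "handedness": df["handedness"],
        "lr_diff_ml": df["target_left_ml"] - df["target_right_ml"],
    })


class TestHandedness:
    def test_null_p_uniform_over_seeds(self):
        # handedness is simulated independent of asymmetry: p-values
        # should be uniform across repeated generator seeds
        ps = []
        params = CohortParams.from_study()
        for seed in range(200):
            params.seed = seed
            df = generate_cohort(params, 150, 150)
            ps.append(handedness_association(_handed_records(df)).p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_planted_shift(self):
        df = generate_cohort(CohortParams.from_study(seed=17), 1000, 1000)
        rec = _handed_records(df)
        rec.loc[rec["handedness"] == "left", "lr_diff_ml"] += 20.0
        assert handedness_association(rec).p_value < 0.01

    def test_single_group_rejected(self):
        rec = pd.DataFrame({"handedness": ["right"] * 5,
                            "lr_diff_ml": np.arange(5.0)})
        with pytest.raises(ValueError):
            handedness_association(rec)


@pytest.fixture(scope="module")
def report():
    df = generate_cohort(CohortParams.from_study(seed=30), 800, 800)
    records = pd.DataFrame({
        "subject_id": df["subject_id"], "gender": df["gender"],
        "age_years": df["age_years"], "height_cm": df["height_cm"],
        "bmi": df["bmi"], "handedness": df["handedness"],
        "left_ml": df["target_left_ml"], "right_ml": df["target_right_ml"],
        "total_ml": df["target_total_ml"],
        "lr_diff_ml": df["target_left_ml"] - df["target_right_ml"],
        "imi": df["target_imi"],
    })
    return analyze_cohort(records)


class TestAnalyzeCohort:
    def test_report_structure(self, report):
        assert report["n"] == 1600
        for key in ("total_volume_by_gender", "lr_asymmetry_female",
                    "imi_vs_age_male", "handedness"):
            assert key in report["tests"]

    def test_directional_findings(self, report):
        t = report["tests"]
        assert t["total_volume_by_gender"]["effect"]["median_a"] > \
            t["total_volume_by_gender"]["effect"]["median_b"]
        for g in ("female", "male"):
            assert t[f"lr_asymmetry_{g}"]["effect"]["d"] < 0
            assert t[f"volume_vs_height_{g}"]["effect"]["rho"] > 0.3
            assert t[f"imi_vs_bmi_{g}"]["effect"]["rho"] > 0.3
            assert t[f"imi_vs_age_{g}"]["effect"]["rho"] < 0
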