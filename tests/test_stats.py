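import numpy as np
import pytest
from scipy import stats as sps

from dynmodnet.stats import (
    PairedSample,
    StatsError,
    cohens_dz,
    compare_conditions,
    experience_correlation,
    fdr_bh,
    normality_ad,
    paired_t,
    power_paired_t,
    significance_stars,
)


class TestPairedT:
    def test_antisymmetric_differences_give_t_zero_p_one(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = paired_t(PairedSample(x1, x1[::-1].copy()))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        # diffs [1,2,3]: t = 2 / (1/sqrt(3)), df = 2
        t, p = paired_t(PairedSample(np.array([1.0, 2.0, 3.0]), np.zeros(3)))
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_constant_shift_rejected_as_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(StatsError, match="degenerate"):
            paired_t(PairedSample(x + 2.0, x))

    def test_type_one_error_calibrated(self):
        # seeded normal null, n=30, 5000 replicates
        rng = np.random.default_rng(99)
        d = rng.standard_normal((5000, 30))
        t = d.mean(axis=1) / (d.std(ddof=1, axis=1) / np.sqrt(30))
        p = 2 * sps.t.sf(np.abs(t), df=29)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert abs(rate - 0.05) < 3 * se
        # spot check the vectorized null against the implementation
        ti, pi = paired_t(PairedSample(d[0], np.zeros(30)))
        assert ti == pytest.approx(t[0])
        assert pi == pytest.approx(p[0])


class TestCohensDz:
    def test_worked_value(self):
        assert cohens_dz(PairedSample(np.array([1.0, 2.0, 3.0]), np.zeros(3))) == pytest.approx(2.0)

    def test_equal_differences_rejected(self):
        with pytest.raises(StatsError):
            cohens_dz(PairedSample(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0])))

    def test_matches_brute_force(self, rng):
        x1 = rng.standard_normal(30)
        x2 = rng.standard_normal(30)
        d = x1 - x2
        assert cohens_dz(PairedSample(x1, x2)) == pytest.approx(d.mean() / d.std(ddof=1))


class TestFdrBh:
    def test_step_up_worked_vector(self):
        # largest k with p_(k) <= k * alpha / 4 is k = 4: all rejected
        q, reject = fdr_bh([0.01, 0.02, 0.04, 0.05], alpha=0.05)
        assert reject.all()

    def test_all_ones_nothing_rejected(self):
        q, reject = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.all(q == 1.0)

    def test_single_p_unchanged(self):
        q, _ = fdr_bh([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=20)
        q, _ = fdr_bh(p)
        assert np.all(q >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            fdr_bh([0.1, 1.5])


class TestNormalityAd:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        n_reps = 200
        rejections = sum(
            normality_ad(rng.standard_normal(100))[1] < 0.05 for _ in range(n_reps)
        )
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rejections / n_reps - 0.05) < 3 * se

    def test_uniform_samples_rejected(self):
        rng = np.random.default_rng(8)
        rejections = sum(normality_ad(rng.uniform(size=100))[1] < 0.05 for _ in range(50))
        assert rejections >= 45

    def test_constant_vector_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            normality_ad(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(StatsError, match="n >= 8"):
            normality_ad(np.arange(5.0))


class TestExperienceCorrelation:
    def test_perfect_monotone_decrease(self):
        codes = [1, 1, 2, 2, 3, 3]
        y = [30.0, 30.0, 20.0, 20.0, 10.0, 10.0]
        r, p, ci = experience_correlation(y, codes)
        assert r == pytest.approx(-1.0)

    def test_independent_data_mean_r_near_zero(self):
        rng = np.random.default_rng(21)
        rs = []
        codes = np.repeat([1, 2, 3], 10)
        for _ in range(500):
            r, _, _ = experience_correlation(rng.standard_normal(30), codes)
            rs.append(r)
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 1e-3

    def test_matches_covariance_formula(self):
        codes = np.array([1, 1, 2, 2, 3, 3], dtype=float)
        y = np.array([25.0, 28.0, 14.0, 17.0, 9.0, 12.0])
        r, _, ci = experience_correlation(y, codes)
        brute = np.cov(codes, y)[0, 1] / (codes.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(brute)
        assert ci[0] < r < ci[1]

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            experience_correlation([1.0, 1.0, 1.0], [1, 2, 3])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert power_paired_t(0.0, 30) == pytest.approx(0.05, abs=1e-9)

    def test_large_effect_saturates(self):
        assert power_paired_t(3.0, 30) > 0.999

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(17)
        dz, n = 0.5, 30
        d = rng.standard_normal((100_000, n)) + dz
        t = d.mean(axis=1) / (d.std(ddof=1, axis=1) / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), df=n - 1)
        mc_power = (p < 0.05).mean()
        assert power_paired_t(dz, n) == pytest.approx(mc_power, abs=0.01)

    def test_monotone_in_effect_and_sample_size(self):
        powers_dz = [power_paired_t(dz, 20) for dz in (0.1, 0.3, 0.5, 1.0)]
        assert powers_dz == sorted(powers_dz)
        powers_n = [power_paired_t(0.4, n) for n in (5, 10, 30, 100)]
        assert powers_n == sorted(powers_n)


class TestReporting:
    def test_star_convention(self):
        assert significance_stars(0.004) == "***"
        assert significance_stars(0.006) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""

    def test_compare_conditions_table(self, rng):
        import pandas as pd

        records = []
        for cond, shift in [("a", 0.0), ("b", 0.3)]:
            for trial in range(20):
                for unit in ("SMN", "DMN"):
                    records.append(
                        dict(condition=cond, trial=trial, unit=unit, metric="flexibility",
                             value=rng.standard_normal() + (shift if unit == "DMN" else 0.0))
                    )
        frame = pd.DataFrame.from_records(records)
        out = compare_conditions(
            frame[frame["condition"] == "a"],
            frame[frame["condition"] == "b"],
            metric="flexibility",
            contrast="a vs b",
        )
        assert set(out["unit"]) == {"SMN", "DMN"}
        assert np.all(out["q"] >= out["p"] - 1e-15)
        assert np.all((out["power"] >= 0) & (out["power"] <= 1))
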