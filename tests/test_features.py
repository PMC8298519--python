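"""The 37-feature engine: worked examples, independent oracles, invariances."""

import numpy as np
import pytest
from scipy import stats

from surgforce.catalog import FEATURE_CATALOG
from surgforce.features import (
    FeatureConfig,
    acf_stats,
    basic_stats,
    decomposition_stats,
    distribution_stats,
    extract_all,
    extract_features,
    flat_spots,
    kpss_statistic,
    loo_variances,
    peak_stats,
    spectral_stats,
    terasvirta_statistic,
    window_stats,
)
from surgforce.segment_io import SegmentTable

from conftest import make_segment, make_table

FS = 100.0


# ---------------------------------------------------------------------------
# Independent oracles (deliberately brute-force / from first principles)


def peaks_oracle(x, prominence):
    """Scan every interior sample against the topographic prominence rule."""
    n = len(x)
    peaks = []
    for i in range(1, n - 1):
        if not (x[i] > x[i - 1] and x[i] > x[i + 1]):
            continue
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        if x[i] - max(left_min, right_min) >= prominence:
            peaks.append(i)
    return peaks


def flat_spots_oracle(x):
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return len(x)
    bins = np.minimum((10 * (x - lo) / (hi - lo)).astype(int), 9)
    best = 1
    for start in range(len(x)):
        run = 1
        for j in range(start + 1, len(x)):
            if bins[j] != bins[start]:
                break
            run += 1
        best = max(best, run)
    return best


def spikiness_oracle(r):
    n = len(r)
    loo = []
    for i in range(n):
        rest = np.delete(r, i)
        loo.append(np.var(rest, ddof=1))
    return np.var(loo, ddof=1)


def window_shift_oracle(x, width, eps=1e-8):
    best_mean, best_var, best_kl = 0.0, 0.0, -np.inf
    for lo in range(0, len(x) - 2 * width + 1):
        w1 = x[lo : lo + width]
        w2 = x[lo + width : lo + 2 * width]
        m1, m2 = np.mean(w1), np.mean(w2)
        v1 = max(np.var(w1, ddof=1), eps)
        v2 = max(np.var(w2, ddof=1), eps)
        best_mean = max(best_mean, abs(m1 - m2))
        best_var = max(best_var, abs(np.var(w1, ddof=1) - np.var(w2, ddof=1)))
        kl = 0.5 * (np.log(v2 / v1) + (v1 + (m1 - m2) ** 2) / v2 - 1.0)
        best_kl = max(best_kl, kl)
    return best_mean, best_var, best_kl


def kpss_oracle(x, nlags=1):
    """Stationarity statistic around a linear trend from first principles."""
    n = len(x)
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    e = x - X @ beta
    s_t = np.cumsum(e)
    eta = np.sum(s_t**2) / n**2
    s2 = np.sum(e * e) / n
    for j in range(1, nlags + 1):
        gamma = np.sum(e[j:] * e[:-j]) / n
        s2 += 2.0 * (1.0 - j / (nlags + 1.0)) * gamma
    return eta / s2


# ---------------------------------------------------------------------------


class TestBasicStats:
    def test_worked_example(self):
        out = basic_stats(np.array([1.0, 2, 3, 4, 5]), fs=5.0)
        assert out["duration"] == pytest.approx(1.0)
        assert out["mean"] == 3
        assert out["max"] == 5 and out["min"] == 1 and out["range"] == 4
        assert out["median"] == 3
        assert out["sd"] == pytest.approx(1.5811, abs=1e-4)
        assert out["cv"] == pytest.approx(0.5270, abs=1e-4)

    def test_ci_halfwidth_uses_t_quantile(self):
        out = basic_stats(np.array([1.0, 2.0, 3.0]), fs=1.0)
        # t(0.975, 2) = 4.30265, sd = 1, so halfwidth = 4.30265 / sqrt(3)
        assert out["mean_ci95_halfwidth"] == pytest.approx(2.48414, abs=1e-4)

    def test_zero_mean_gives_na_cv(self):
        out = basic_stats(np.array([-1.0, 1.0]), fs=1.0)
        assert np.isnan(out["cv"])


class TestDistributionStats:
    def test_symmetric_values_have_zero_skew(self):
        out = distribution_stats(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), fs=1.0)
        assert abs(out["skewness"]) < 1e-12

    def test_skew_standard_error_closed_form(self):
        x = np.random.default_rng(0).normal(size=10)
        out = distribution_stats(x, fs=1.0)
        se = np.sqrt(540.0 / (8 * 11 * 13))
        assert se == pytest.approx(0.6870, abs=1e-4)
        assert out["skewness_2se"] == pytest.approx(out["skewness"] / (2 * se))

    def test_shapiro_null_rarely_rejects(self):
        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(100):
            out = distribution_stats(rng.normal(size=500), fs=1.0)
            hits += out["shapiro_p"] > 0.01
        assert hits >= 95

    def test_short_series_degrades_to_na(self):
        out = distribution_stats(np.array([1.0, 2.0]), fs=1.0)
        assert np.isnan(out["skewness"]) and np.isnan(out["shapiro_w"])


class TestPeakStats:
    def test_alternating_series(self):
        out = peak_stats(np.array([0.0, 1, 0, 1, 0]), fs=1.0, prominence_fraction=0.05)
        assert out["peak_count"] == 2
        assert out["cycle_length"] == pytest.approx(2.0)
        assert out["peak_value"] == 1

    def test_monotone_ramp_has_no_peaks(self):
        out = peak_stats(np.linspace(0, 1, 50), fs=1.0)
        assert out["peak_count"] == 0
        assert np.isnan(out["cycle_length"])

    def test_d1_sd_is_rate_sd(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        out = peak_stats(x, fs=10.0)
        assert out["d1_sd"] == pytest.approx(np.std(np.diff(x), ddof=1) * 10.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_peak_count_matches_prominence_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=150)
        rngx = float(np.max(x) - np.min(x))
        out = peak_stats(x, fs=1.0, prominence_fraction=0.1)
        assert out["peak_count"] == len(peaks_oracle(x, 0.1 * rngx))


class TestFlatSpots:
    def test_constant_series_returns_length(self):
        assert flat_spots(np.full(50, 3.3)) == 50

    def test_linear_ramp_of_100_gives_10(self):
        assert flat_spots(np.linspace(0, 1, 100)) == 10

    def test_alternating_extremes_gives_1(self):
        x = np.tile([0.0, 1.0], 25)
        assert flat_spots(x) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_run_length_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=80)
        assert flat_spots(x) == flat_spots_oracle(x)


class TestSpectralStats:
    def test_sinusoid_dominant_frequency(self):
        t = np.arange(1000) / FS
        out = spectral_stats(np.sin(2 * np.pi * 1.0 * t), fs=FS)
        assert out["dominant_freq"] == pytest.approx(1.0, abs=0.1)
        assert out["spectral_entropy"] < 0.2

    def test_white_noise_entropy_near_one(self):
        x = np.random.default_rng(5).normal(size=1024)
        out = spectral_stats(x, fs=FS)
        assert out["spectral_entropy"] > 0.9

    def test_zero_variance_is_na(self):
        out = spectral_stats(np.full(100, 2.0), fs=FS)
        assert np.isnan(out["dominant_freq"]) and np.isnan(out["spectral_entropy"])


class TestDecompositionStats:
    def test_linear_ramp_has_strong_trend_small_curvature(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 300) + rng.normal(scale=1e-3, size=300)
        out = decomposition_stats(x, fs=FS)
        assert out["trend"] > 0.99
        assert abs(out["curvature"]) < 0.1

    def test_quadratic_curvature_sign(self):
        t = np.linspace(-1, 1, 200)
        up = decomposition_stats(t**2, fs=FS)
        down = decomposition_stats(-(t**2), fs=FS)
        assert up["curvature"] > 0 > down["curvature"]

    def test_fluctuation_is_mean_crossing_rate(self):
        x = np.tile([0.0, 1.0], 50)  # crosses the mean between every sample
        out = decomposition_stats(x, fs=FS)
        assert out["fluctuation"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_loo_variances_match_double_loop(self, seed):
        r = np.random.default_rng(seed).normal(size=60)
        direct = np.array([np.var(np.delete(r, i), ddof=1) for i in range(len(r))])
        assert np.allclose(loo_variances(r), direct, rtol=1e-10)
        assert np.var(loo_variances(r), ddof=1) == pytest.approx(
            spikiness_oracle(r), rel=1e-9
        )

    def test_terasvirta_detects_nonlinearity(self):
        rng = np.random.default_rng(3)
        n = 400
        lin = np.empty(n)
        nonlin = np.empty(n)
        lin[0] = nonlin[0] = 0.0
        e = rng.normal(scale=0.5, size=n)
        for t in range(1, n):
            lin[t] = 0.6 * lin[t - 1] + e[t]
            # threshold AR: conditional mean is piecewise-linear in the lag
            coef = 0.9 if nonlin[t - 1] > 0 else -0.6
            nonlin[t] = coef * nonlin[t - 1] + e[t]
        assert terasvirta_statistic(nonlin) > terasvirta_statistic(lin)
        # linear AR(1) should not exceed the chi2(2) 0.1% critical value
        assert terasvirta_statistic(lin) < stats.chi2.ppf(0.999, 2)


class TestWindowStats:
    def test_constant_series_all_zero(self):
        out = window_stats(np.full(100, 1.0), fs=FS, width=10)
        for key in ("stability", "lumpiness", "max_mean_shift", "max_var_shift", "max_kl_shift"):
            assert out[key] == pytest.approx(0.0, abs=1e-12)

    def test_step_series_mean_shift_is_one(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        out = window_stats(x, fs=FS, width=10)
        assert out["max_mean_shift"] == pytest.approx(1.0)

    def test_too_short_series_is_na(self):
        out = window_stats(np.arange(15.0), fs=FS, width=10)
        assert all(np.isnan(v) for v in out.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_shifts_match_sliding_pair_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=120)
        out = window_stats(x, fs=FS, width=10)
        m, v, kl = window_shift_oracle(x, 10)
        assert out["max_mean_shift"] == pytest.approx(m, rel=1e-9)
        assert out["max_var_shift"] == pytest.approx(v, rel=1e-9)
        assert out["max_kl_shift"] == pytest.approx(kl, rel=1e-9)


class TestKpss:
    def test_trend_stationary_series_below_10pct_critical_value(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            x = 0.01 * np.arange(500) + rng.normal(size=500)
            hits += kpss_statistic(x) < 0.119
        assert hits >= 90

    def test_random_walk_above_1pct_critical_value(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(100):
            x = np.cumsum(rng.normal(size=500))
            hits += kpss_statistic(x) > 0.216
        assert hits >= 90

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_from_scratch_formula(self, seed):
        x = np.random.default_rng(seed).normal(size=200).cumsum()
        assert kpss_statistic(x) == pytest.approx(kpss_oracle(x), rel=1e-6)


class TestAcfStats:
    def test_ramp_has_near_unit_lag1(self):
        out = acf_stats(np.arange(1000.0), fs=FS)
        assert out["acf_e1"] > 0.99

    def test_white_noise_acf_small(self):
        x = np.random.default_rng(8).normal(size=1000)
        out = acf_stats(x, fs=FS)
        assert abs(out["acf_e1"]) < 0.1
        assert out["acf_e10"] < 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_e10_bounds_e1_squared(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        out = acf_stats(x, fs=FS)
        assert out["acf_e10"] >= out["acf_e1"] ** 2 - 1e-12

    def test_oscillation_zero_crossing_time(self):
        t = np.arange(400) / FS
        out = acf_stats(np.sin(2 * np.pi * 1.0 * t), fs=FS)
        # ACF of a 1 Hz sinusoid first crosses zero near a quarter period
        assert out["acf_first_zero_time"] == pytest.approx(0.25, abs=0.03)


class TestExtractAll:
    def test_catalogue_closure_and_order(self, tiny_dataset):
        seg = tiny_dataset.table[0]
        vals = extract_features(seg.right_force, seg.sampling_rate)
        assert list(vals) == list(FEATURE_CATALOG)
        assert len(vals) == 37

    def test_identical_segments_identical_vectors(self):
        x = np.random.default_rng(0).normal(size=300)
        table = make_table([x, x.copy()])
        df = extract_all(table)
        a, b = df.iloc[0][list(FEATURE_CATALOG)], df.iloc[1][list(FEATURE_CATALOG)]
        assert np.array_equal(a.to_numpy(dtype=float), b.to_numpy(dtype=float), equal_nan=True)

    def test_five_sample_segment_degrades_gracefully(self):
        df = extract_all(make_table([np.array([1.0, 2, 1, 3, 2])]))
        row = df.iloc[0]
        assert len([c for c in FEATURE_CATALOG]) == 37
        assert np.isfinite(row["mean"]) and np.isfinite(row["sd"])
        for col in ("trend", "stability", "kpss_stat", "acf_e1"):
            assert np.isnan(row[col])

    def test_both_channels_mode_suffixes_names(self):
        x = np.random.default_rng(1).normal(size=200)
        table = make_table([x], left=0.5 * x)
        df = extract_all(table, FeatureConfig(both_channels=True))
        assert "mean_left" in df.columns and "mean_right" in df.columns
        assert df.loc[0, "mean_left"] == pytest.approx(0.5 * df.loc[0, "mean_right"])

    @pytest.mark.parametrize("seed", range(3))
    def test_scale_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(loc=1.0, size=400)
        c = 3.7
        a = extract_features(x, FS)
        b = extract_features(c * x, FS)
        for name in ("mean", "max", "min", "range", "median", "sd", "peak_value", "max_mean_shift"):
            assert b[name] == pytest.approx(c * a[name], rel=1e-6)
        for name in ("cv", "skewness", "kurtosis", "spectral_entropy", "trend", "fluctuation"):
            assert b[name] == pytest.approx(a[name], rel=1e-5, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_time_reversal_invariance_of_distributional_features(self, seed):
        x = np.random.default_rng(seed).normal(size=300)
        a = extract_features(x, FS)
        b = extract_features(x[::-1].copy(), FS)
        for name in ("mean", "sd", "skewness", "kurtosis", "shapiro_w", "flat_spots", "spectral_entropy"):
            assert b[name] == pytest.approx(a[name], rel=1e-8)
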