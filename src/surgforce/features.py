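"""The 37-feature engine for force segments.

Each annotated force segment is condensed into a fixed, ordered catalogue of
37 hand-crafted time-series features (see :data:`surgforce.catalog.FEATURE_CATALOG`):
basic moments, distribution shape and normality, peak structure, flat spots,
spectral content, trend/remainder decomposition statistics, windowed
stability/lumpiness/shift statistics, a stationarity statistic, spectral
entropy (forecastability), and autocorrelation timing/energy features.

Features are computed on a single designated analysis channel (default the
right prong).  A value that cannot be computed for a given segment — too few
samples, zero variance — is reported as the not-available sentinel (NaN) and
never silently dropped: every feature vector has exactly 37 keys.

Notes on conventions:

* ``sd`` and all variances are sample (n-1) statistics.
* ``skewness``/``kurtosis`` are bias-adjusted sample statistics; kurtosis is
  excess kurtosis.  Their ``*_2se`` companions divide by twice the standard
  error (|value| > 1 reads as significant at ~0.05).
* ``fluctuation`` is the mean-crossing rate: sign changes of the mean-centred
  series divided by (n - 1), bounded in [0, 1].
* ``spikiness`` is the variance of leave-one-out variances of the remainder
  after subtracting a loess trend.
* ``linearity`` is the chi-squared statistic of a neural-network-type
  nonlinearity test (Teräsvirta), lag 1.
* ``kpss_stat`` is the stationarity statistic around a linear trend with a
  lag-1 Bartlett long-run variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .catalog import FEATURE_CATALOG, METADATA_COLUMNS
from .segment_io import ForceSegment, SegmentTable

NA = float("nan")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature engine.

    ``prominence_fraction``: a local maximum counts as a peak when its
    prominence is at least this fraction of the segment's force range.
    ``window_width``: samples per window for stability/lumpiness/shift
    features.  ``loess_span``: fraction of the segment used by the local
    trend regression.  ``acf_lag_cap``: autocorrelation is computed to
    ``min(n - 1, acf_lag_cap)`` lags.
    """

    channel: str = "right"
    prominence_fraction: float = 0.05
    loess_span: float = 0.75
    window_width: int = 10
    acf_lag_cap: int = 100
    kl_epsilon: float = 1e-8
    both_channels: bool = False


# ---------------------------------------------------------------------------
# Basic moments


def basic_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    """Duration, location and dispersion summaries of one segment."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = dict.fromkeys(
        ("duration", "mean", "max", "min", "range", "median", "sd", "cv", "mean_ci95_halfwidth"),
        NA,
    )
    if n < 2:
        return out
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    out.update(
        duration=n / fs,
        mean=mean,
        max=float(np.max(x)),
        min=float(np.min(x)),
        range=float(np.max(x) - np.min(x)),
        median=float(np.median(x)),
        sd=sd,
        cv=sd / mean if mean != 0 else NA,
        mean_ci95_halfwidth=float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)),
    )
    return out


# ---------------------------------------------------------------------------
# Distribution shape and normality


def _se_skew(n: int) -> float:
    return float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))


def _se_kurt(n: int) -> float:
    return float(2.0 * _se_skew(n) * np.sqrt((n * n - 1.0) / ((n - 3) * (n + 5))))


def distribution_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    """Adjusted skewness/excess kurtosis, their 2-SE ratios, Shapiro-Wilk."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = dict.fromkeys(
        ("skewness", "skewness_2se", "kurtosis", "kurtosis_2se", "shapiro_w", "shapiro_p"),
        NA,
    )
    if n >= 3 and np.std(x) > 0:
        sk = float(stats.skew(x, bias=False))
        out["skewness"] = sk
        out["skewness_2se"] = sk / (2.0 * _se_skew(n))
    if n >= 4 and np.std(x) > 0:
        ku = float(stats.kurtosis(x, fisher=True, bias=False))
        out["kurtosis"] = ku
        out["kurtosis_2se"] = ku / (2.0 * _se_kurt(n))
    if 3 <= n <= 5000 and np.std(x) > 0:
        try:
            w, p = stats.shapiro(x)
            out["shapiro_w"] = float(w)
            out["shapiro_p"] = float(p)
        except Exception:
            pass
    return out


# ---------------------------------------------------------------------------
# Peaks and first derivative


def peak_stats(x: np.ndarray, fs: float, prominence_fraction: float = 0.05) -> dict[str, float]:
    """Peak value/count, mean force-cycle length, first-derivative SD.

    Peaks are strict local maxima whose topographic prominence is at least
    ``prominence_fraction`` of the segment range.  ``cycle_length`` is the
    mean inter-peak interval in seconds (needs >= 2 peaks).  ``d1_sd`` is the
    sample SD of the first difference divided by the sample period, i.e. the
    SD of the finite-difference force rate in N/s.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = dict.fromkeys(("peak_value", "peak_count", "cycle_length", "d1_sd"), NA)
    if n < 2:
        return out
    out["peak_value"] = float(np.max(x))
    out["d1_sd"] = float(np.std(np.diff(x), ddof=1) * fs) if n >= 3 else NA
    if n < 3:
        return out
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        out["peak_count"] = 0.0
        return out
    peaks, _ = signal.find_peaks(x, prominence=prominence_fraction * rng)
    out["peak_count"] = float(len(peaks))
    if len(peaks) >= 2:
        out["cycle_length"] = float(np.mean(np.diff(peaks)) / fs)
    return out


# ---------------------------------------------------------------------------
# Flat spots


def flat_spots(x: np.ndarray, fs: float | None = None) -> float:
    """Maximum run length within one of ten equal-width value bins.

    The value range [min, max] is split into 10 equal-width bins; the
    statistic is the longest run of consecutive samples staying in a single
    bin.  A constant series (range 0) returns n.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return NA
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return float(n)
    bins = np.minimum((10 * (x - lo) / (hi - lo)).astype(int), 9)
    best = run = 1
    for i in range(1, n):
        run = run + 1 if bins[i] == bins[i - 1] else 1
        best = max(best, run)
    return float(best)


# ---------------------------------------------------------------------------
# Spectrum


def spectral_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    """Dominant frequency and normalized spectral (Shannon) entropy.

    The periodogram of the mean-removed series is normalized to a discrete
    distribution over the non-zero frequencies; entropy is divided by
    log(#ordinates) so it lies in [0, 1].  Low entropy = concentrated
    spectrum = predictable signal; white noise approaches 1.
    """
    x = np.asarray(x, dtype=float)
    out = {"dominant_freq": NA, "spectral_entropy": NA}
    if len(x) < 8 or float(np.std(x)) == 0.0:
        return out
    freqs, pxx = signal.periodogram(x, fs=fs, detrend="constant")
    freqs, pxx = freqs[1:], pxx[1:]  # drop the DC ordinate
    total = float(np.sum(pxx))
    if total <= 0 or len(pxx) < 2:
        return out
    out["dominant_freq"] = float(freqs[int(np.argmax(pxx))])
    p = pxx / total
    nz = p[p > 0]
    out["spectral_entropy"] = float(-np.sum(nz * np.log(nz)) / np.log(len(p)))
    return out


# ---------------------------------------------------------------------------
# Trend decomposition, spikiness, curvature, linearity, fluctuation


def _loess_trend(x: np.ndarray, span: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    idx = np.arange(len(x), dtype=float)
    return lowess(
        x, idx, frac=span, it=2, delta=0.01 * len(x), return_sorted=False
    )


def loo_variances(r: np.ndarray) -> np.ndarray:
    """Sample variance of ``r`` with each element left out in turn (vectorized)."""
    r = np.asarray(r, dtype=float)
    n = len(r)
    s, ss = float(np.sum(r)), float(np.sum(r * r))
    mean_loo = (s - r) / (n - 1)
    return (ss - r * r - (n - 1) * mean_loo**2) / (n - 2)


def terasvirta_statistic(x: np.ndarray, lag: int = 1) -> float:
    """Chi-squared statistic of the Teräsvirta neural-network nonlinearity test.

    The series (standardized for conditioning) is regressed on its first
    ``lag`` lags; the auxiliary regression adds all quadratic and cubic
    products of the lags, and the statistic is n * (SSR0 - SSR1) / SSR0.
    Large values indicate nonlinear dependence on the lags.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        return NA
    sd = np.std(x)
    if sd == 0:
        return NA
    x = (x - np.mean(x)) / sd
    n_eff = len(x) - lag
    if n_eff < 3 * lag + 5:
        return NA
    y = x[lag:]
    lags = np.column_stack([x[lag - j - 1 : len(x) - j - 1] for j in range(lag)])
    X0 = np.column_stack([np.ones(n_eff), lags])
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    u = y - X0 @ beta0
    ssr0 = float(u @ u)
    if ssr0 <= 0:
        return NA
    quad = [lags[:, i] * lags[:, j] for i in range(lag) for j in range(i, lag)]
    cubic = [
        lags[:, i] * lags[:, j] * lags[:, k]
        for i in range(lag)
        for j in range(i, lag)
        for k in range(j, lag)
    ]
    X1 = np.column_stack([X0] + quad + cubic)
    beta1, *_ = np.linalg.lstsq(X1, u, rcond=None)
    v = u - X1 @ beta1
    ssr1 = float(v @ v)
    return float(n_eff * (ssr0 - ssr1) / ssr0)


def decomposition_stats(x: np.ndarray, fs: float, span: float = 0.75) -> dict[str, float]:
    """Trend strength, fluctuation, spikiness, curvature and nonlinearity.

    A loess trend on the sample index defines remainder r = x - trend;
    ``trend`` = max(0, 1 - var(r)/var(x)).  ``spikiness`` is the variance of
    the leave-one-out variances of r.  ``curvature`` is the second-degree
    coefficient of an orthonormal-polynomial quadratic regression of force on
    time (sign follows the quadratic term).  ``fluctuation`` is the
    mean-crossing rate in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = dict.fromkeys(("trend", "fluctuation", "spikiness", "curvature", "linearity"), NA)
    if n < 12:
        return out
    var_x = float(np.var(x, ddof=1))
    # fluctuation: sign changes of the mean-centred series, zeros dropped
    centred = x - np.mean(x)
    s = np.sign(centred)
    s = s[s != 0]
    if len(s) >= 2:
        out["fluctuation"] = float(np.sum(s[1:] != s[:-1]) / (n - 1))
    elif var_x == 0:
        out["fluctuation"] = 0.0
    if var_x == 0:
        out["trend"] = 0.0
        out["spikiness"] = 0.0
        out["curvature"] = 0.0
        return out
    trend_fit = _loess_trend(x, span)
    r = x - trend_fit
    out["trend"] = float(max(0.0, 1.0 - np.var(r, ddof=1) / var_x))
    out["spikiness"] = float(np.var(loo_variances(r), ddof=1))
    # orthonormal quadratic regression on the time index
    t = np.arange(n, dtype=float)
    V = np.column_stack([np.ones(n), t, t * t])
    Q, _ = np.linalg.qr(V)
    # fix sign so each basis column correlates positively with its monomial
    for j in range(3):
        if Q[:, j] @ V[:, j] < 0:
            Q[:, j] = -Q[:, j]
    coeffs = Q.T @ x
    out["curvature"] = float(coeffs[2])
    out["linearity"] = terasvirta_statistic(x, lag=1)
    return out


# ---------------------------------------------------------------------------
# Windowed statistics


def gaussian_kl(m1: float, v1: float, m2: float, v2: float) -> float:
    """KL divergence between two univariate Gaussians N(m1,v1) || N(m2,v2)."""
    return 0.5 * (np.log(v2 / v1) + (v1 + (m1 - m2) ** 2) / v2 - 1.0)


def window_stats(
    x: np.ndarray, fs: float, width: int = 10, kl_epsilon: float = 1e-8
) -> dict[str, float]:
    """Stability, lumpiness and the largest adjacent-window shifts.

    The series is tiled into non-overlapping windows of ``width`` samples
    (remainder dropped): ``stability`` is the variance of the window means,
    ``lumpiness`` the variance of the window variances.  Shift statistics
    slide a pair of adjacent ``width``-sample windows along the series and
    report the largest |mean difference|, |variance difference| and Gaussian
    KL divergence (variances floored at ``kl_epsilon``).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = dict.fromkeys(
        ("stability", "lumpiness", "max_mean_shift", "max_var_shift", "max_kl_shift"), NA
    )
    if width < 2 or n < 2 * width:
        return out
    n_tiles = n // width
    tiles = x[: n_tiles * width].reshape(n_tiles, width)
    out["stability"] = float(np.var(tiles.mean(axis=1), ddof=1))
    out["lumpiness"] = float(np.var(tiles.var(axis=1, ddof=1), ddof=1))
    # sliding adjacent pair: windows [i-width, i) and [i, i+width)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    starts = np.arange(0, n - 2 * width + 1)
    def win_moments(lo):
        s = c1[lo + width] - c1[lo]
        ss = c2[lo + width] - c2[lo]
        m = s / width
        v = (ss - width * m * m) / (width - 1)
        return m, np.maximum(v, 0.0)
    m1, v1 = win_moments(starts)
    m2, v2 = win_moments(starts + width)
    out["max_mean_shift"] = float(np.max(np.abs(m1 - m2)))
    out["max_var_shift"] = float(np.max(np.abs(v1 - v2)))
    v1c = np.maximum(v1, kl_epsilon)
    v2c = np.maximum(v2, kl_epsilon)
    kl = 0.5 * (np.log(v2c / v1c) + (v1c + (m1 - m2) ** 2) / v2c - 1.0)
    out["max_kl_shift"] = float(np.max(kl))
    return out


# ---------------------------------------------------------------------------
# Stationarity


def kpss_statistic(x: np.ndarray, fs: float | None = None) -> float:
    """Stationarity statistic around a linear trend, lag-1 Bartlett window.

    Small values are consistent with trend-stationarity; a random walk drives
    the statistic above its upper critical values.
    """
    from statsmodels.tsa.stattools import kpss

    x = np.asarray(x, dtype=float)
    if len(x) < 12:
        return NA
    t = np.arange(len(x), dtype=float)
    resid_var = np.var(x - np.polyval(np.polyfit(t, x, 1), t))
    if resid_var == 0:
        return NA
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, *_ = kpss(x, regression="ct", nlags=1)
    return float(stat)


# ---------------------------------------------------------------------------
# Autocorrelation


def acf_stats(x: np.ndarray, fs: float, lag_cap: int = 100) -> dict[str, float]:
    """Autocorrelation timing and energy features.

    ``acf_first_min_time``: lag (seconds) of the first local minimum of the
    ACF; ``acf_first_zero_time``: first zero crossing (linear interpolation
    between lags, seconds); ``acf_e1``: lag-1 coefficient; ``acf_e10``: sum
    of the first ten squared coefficients.
    """
    from statsmodels.tsa.stattools import acf as sm_acf

    x = np.asarray(x, dtype=float)
    n = len(x)
    out = dict.fromkeys(("acf_first_min_time", "acf_first_zero_time", "acf_e1", "acf_e10"), NA)
    if n < 12 or float(np.std(x)) == 0.0:
        return out
    nlags = min(n - 1, lag_cap)
    rho = sm_acf(x, nlags=nlags, fft=True)
    out["acf_e1"] = float(rho[1])
    if nlags >= 10:
        out["acf_e10"] = float(np.sum(rho[1:11] ** 2))
    for k in range(1, len(rho) - 1):
        if rho[k] < rho[k - 1] and rho[k] < rho[k + 1]:
            out["acf_first_min_time"] = k / fs
            break
    for k in range(1, len(rho)):
        if rho[k] < 0 <= rho[k - 1]:
            frac = rho[k - 1] / (rho[k - 1] - rho[k])
            out["acf_first_zero_time"] = (k - 1 + frac) / fs
            break
        if rho[k] == 0:
            out["acf_first_zero_time"] = k / fs
            break
    return out


# ---------------------------------------------------------------------------
# Assembly


def extract_features(
    x: np.ndarray, fs: float, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Compute the full 37-feature catalogue for one channel of one segment.

    A failing sub-computation degrades to NaN for its entries only; the
    returned mapping always has exactly the 37 catalogue keys in order.
    """
    x = np.asarray(x, dtype=float)
    values: dict[str, float] = dict.fromkeys(FEATURE_CATALOG, NA)

    groups = (
        lambda: basic_stats(x, fs),
        lambda: distribution_stats(x, fs),
        lambda: peak_stats(x, fs, config.prominence_fraction),
        lambda: {"flat_spots": flat_spots(x)},
        lambda: spectral_stats(x, fs),
        lambda: decomposition_stats(x, fs, config.loess_span),
        lambda: window_stats(x, fs, config.window_width, config.kl_epsilon),
        lambda: {"kpss_stat": kpss_statistic(x)},
        lambda: acf_stats(x, fs, config.acf_lag_cap),
    )
    for group in groups:
        try:
            values.update(group())
        except Exception:
            pass  # entries stay NaN
    return {name: values[name] for name in FEATURE_CATALOG}


def segment_features(seg: ForceSegment, config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """Feature vector for one segment on the designated analysis channel."""
    return extract_features(seg.channel(config.channel), seg.sampling_rate, config)


def extract_all(table: SegmentTable, config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Feature table: one row per segment, metadata then the 37 features.

    With ``config.both_channels`` the 37 columns appear twice with
    ``_left``/``_right`` suffixes instead of the canonical single-channel set.
    """
    rows = []
    for s in table:
        row: dict[str, object] = {
            "segment_id": s.segment_id,
            "case_id": s.case_id,
            "task": s.task,
            "surgeon_id": s.surgeon_id,
            "experience": s.experience,
        }
        if config.both_channels:
            for chan in ("left", "right"):
                vals = extract_features(s.channel(chan), s.sampling_rate, config)
                row.update({f"{k}_{chan}": v for k, v in vals.items()})
        else:
            row.update(segment_features(s, config))
        rows.append(row)
    if config.both_channels:
        feat_cols = [f"{k}_{c}" for c in ("left", "right") for k in FEATURE_CATALOG]
    else:
        feat_cols = list(FEATURE_CATALOG)
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + feat_cols)


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Wide CSV; not-available values written as empty cells."""
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    from .errors import FormatError

    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} is missing columns {missing}")
    return df
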