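"""103-dimension feature extraction from one denoised measurement.

Five blocks, in a fixed canonical order:

1. ``cat1`` (1): hours elapsed since the previous meal.
2. ``cat2`` (2): systolic and diastolic blood pressure.
3. ``cat3`` (8): mean and sample variance of each of the four denoised
   1450/1650 nm absorption channels.
4. ``cat4`` (52): 13 HRV features per 880 nm channel -- six time-domain
   statistics of the PP-interval series and seven frequency-domain band
   powers of the interpolated tachogram.
5. ``cat5`` (40): 10 descriptive statistics of the beat-to-beat heart
   rate per 880 nm channel.

PP intervals outside the physiologic 333-1500 ms window are discarded
before any HRV statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .errors import FeatureExtractionError, InsufficientDataError
from .synth import Measurement

__all__ = [
    "FeatureVector",
    "PPSeries",
    "detect_peaks",
    "compute_pp_intervals",
    "hrv_time_features",
    "hrv_freq_features",
    "hr_stats_features",
    "absorption_features",
    "meal_time_feature",
    "extract_features",
    "feature_names",
    "CATEGORY_SIZES",
]

CATEGORY_SIZES = (1, 2, 8, 52, 40)
N_FEATURES = sum(CATEGORY_SIZES)  # 103

PP_MIN_MS = 333.0
PP_MAX_MS = 1500.0
MIN_PEAK_SEPARATION_S = 1.0 / 3.0  # <= 180 bpm
TACHO_RESAMPLE_HZ = 4.0
_LFHF_SENTINEL = 1e6

_HRV_NAMES = (
    "meanPP",
    "sdnn",
    "rmssd",
    "sdsd",
    "nn50",
    "pnn50",
    "tp",
    "vlf",
    "lf",
    "hf",
    "lfhf",
    "lfnu",
    "hfnu",
)
_HR_STAT_NAMES = (
    "mean",
    "median",
    "mode",
    "var",
    "sd",
    "range",
    "iqr",
    "skew",
    "kurt",
    "mad",
)
_ABSORB_LABELS = ("1450a", "1450b", "1650a", "1650b")


@dataclass
class FeatureVector:
    """Ordered 103-value feature vector with canonical names."""

    values: np.ndarray
    names: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != N_FEATURES or len(self.names) != N_FEATURES:
            raise ValueError(f"feature vector must have {N_FEATURES} entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


@dataclass
class PPSeries:
    """Physiologically filtered PP-interval series.

    ``peak_times_s`` holds the running timestamps of surviving interval
    endpoints (rebuilt cumulatively after filtering), so that
    ``len(intervals_ms) == len(peak_times_s) - 1`` always holds and the
    series forms a valid tachogram.
    """

    intervals_ms: np.ndarray
    peak_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.intervals_ms.size != self.peak_times_s.size - 1:
            raise ValueError("intervals and peak times are inconsistent")


def feature_names() -> tuple:
    """The canonical 103 feature labels, category-prefixed."""
    names = ["cat1_meal_dt", "cat2_sbp", "cat2_dbp"]
    for ch in _ABSORB_LABELS:
        names += [f"cat3_{ch}_mean", f"cat3_{ch}_var"]
    for ch in range(4):
        names += [f"cat4_ch{ch}_{k}" for k in _HRV_NAMES]
    for ch in range(4):
        names += [f"cat5_ch{ch}_{k}" for k in _HR_STAT_NAMES]
    return tuple(names)


def detect_peaks(signal, fs: float) -> np.ndarray:
    """Systolic peak indices of a (denoised) PPG.

    Local maxima above an adaptive threshold -- the sliding 5-second
    window mean plus 0.3 of the window SD -- separated by at least 0.333 s
    (<= 180 bpm).  Deterministic; raises if fewer than 3 peaks survive.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2 * fs:
        raise InsufficientDataError("need at least 2 s of samples for peak detection")
    w = max(3, int(round(5.0 * fs)))
    mean = uniform_filter1d(x, w, mode="nearest")
    sq = uniform_filter1d(x * x, w, mode="nearest")
    sd = np.sqrt(np.clip(sq - mean * mean, 0.0, None))
    threshold = mean + 0.3 * sd
    distance = max(1, int(round(MIN_PEAK_SEPARATION_S * fs)))
    peaks, _ = sps.find_peaks(x, height=threshold, distance=distance)
    if peaks.size < 3:
        raise FeatureExtractionError(
            f"only {peaks.size} peaks detected; at least 3 are required"
        )
    return peaks


def compute_pp_intervals(peaks, fs: float) -> PPSeries:
    """PP intervals (ms) between consecutive peaks, physiologically filtered.

    Intervals outside [333, 1500] ms are dropped together with their
    timestamps; timestamps of the survivors are rebuilt cumulatively so the
    tachogram stays consistent.  Raises if fewer than 2 intervals survive.
    """
    peaks = np.asarray(peaks)
    if peaks.size < 3:
        raise InsufficientDataError("need at least 3 peaks")
    intervals = np.diff(peaks) * 1000.0 / fs
    valid = (intervals >= PP_MIN_MS) & (intervals <= PP_MAX_MS)
    kept = intervals[valid]
    if kept.size < 2:
        raise InsufficientDataError(
            f"only {kept.size} physiologic PP intervals survive filtering"
        )
    times = np.concatenate([[peaks[0] / fs], peaks[0] / fs + np.cumsum(kept) / 1000.0])
    return PPSeries(intervals_ms=kept, peak_times_s=times)


def hrv_time_features(pp: PPSeries) -> np.ndarray:
    """Six time-domain HRV statistics.

    meanPP and SDNN of the intervals; RMSSD and SDSD of successive
    differences; NN50 = count of successive differences strictly greater
    than 50 ms in magnitude; pNN50 = 100 * NN50 / (n - 1).
    Sample (n-1) standard deviations throughout.
    """
    iv = pp.intervals_ms
    if iv.size < 3:
        raise InsufficientDataError("need >= 3 intervals for difference statistics")
    d = np.diff(iv)
    nn50 = int(np.sum(np.abs(d) > 50.0))
    return np.array(
        [
            float(np.mean(iv)),
            float(np.std(iv, ddof=1)),
            float(np.sqrt(np.mean(d * d))),
            float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
            float(nn50),
            100.0 * nn50 / d.size,
        ]
    )


def hrv_freq_features(pp: PPSeries) -> np.ndarray:
    """Seven frequency-domain HRV features: TP, VLF, LF, HF, LF/HF, LFnu, HFnu.

    The tachogram is cubic-spline interpolated onto a uniform 4 Hz grid,
    mean-removed, and its spectrum estimated with a Welch periodogram
    (segment length min(256, N), 50% overlap).  Band powers are trapezoidal
    integrals over [0, 0.04), [0.04, 0.15) and [0.15, 0.4) Hz; TP spans
    [0, Nyquist].  LFnu/HFnu use the LF+HF denominator; an HF of exactly
    zero makes LF/HF the finite sentinel 1e6.
    """
    t = pp.peak_times_s[1:]  # interval i is attributed to its end time
    iv = pp.intervals_ms
    span = t[-1] - t[0]
    if span < 30.0:
        raise InsufficientDataError(
            f"tachogram spans {span:.1f} s; >= 30 s required for band powers"
        )
    spline = CubicSpline(t, iv)
    n_grid = int(np.floor(span * TACHO_RESAMPLE_HZ)) + 1
    grid = t[0] + np.arange(n_grid) / TACHO_RESAMPLE_HZ
    series = spline(grid)
    series = series - np.mean(series)
    nperseg = min(256, series.size)
    freqs, psd = sps.welch(series, fs=TACHO_RESAMPLE_HZ, nperseg=nperseg, noverlap=nperseg // 2)

    def band(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    tp = float(np.trapezoid(psd, freqs))
    vlf = band(0.0, 0.04)
    lf = band(0.04, 0.15)
    hf = band(0.15, 0.4)
    lfhf = lf / hf if hf > 0 else _LFHF_SENTINEL
    denom = lf + hf
    lfnu = 100.0 * lf / denom if denom > 0 else 0.0
    hfnu = 100.0 * hf / denom if denom > 0 else 0.0
    return np.array([tp, vlf, lf, hf, lfhf, lfnu, hfnu])


def hr_stats_features(pp: PPSeries) -> np.ndarray:
    """Ten descriptive statistics of the beat-to-beat heart rate (bpm).

    HR_i = 60000 / PP_i.  Mode uses 1-bpm bins (round-to-nearest integer
    centres, ties to the lowest bin); skewness m3/m2^1.5 and kurtosis
    m4/m2^2 (non-excess) with the zero-variance convention skew = kurt = 0;
    MAD is the unscaled median absolute deviation; variance/SD use n-1.
    """
    iv = pp.intervals_ms
    if iv.size < 2:
        raise InsufficientDataError("need >= 2 intervals for HR statistics")
    hr = 60000.0 / iv
    rounded = np.rint(hr).astype(int)
    vals, counts = np.unique(rounded, return_counts=True)
    mode = float(vals[np.argmax(counts)])  # np.unique sorts, argmax -> lowest tie
    m = hr.mean()
    m2 = float(np.mean((hr - m) ** 2))
    if m2 > 0:
        skew = float(np.mean((hr - m) ** 3)) / m2**1.5
        kurt = float(np.mean((hr - m) ** 4)) / m2**2
    else:
        skew = kurt = 0.0
    q75, q25 = np.percentile(hr, [75, 25])
    return np.array(
        [
            float(m),
            float(np.median(hr)),
            mode,
            float(np.var(hr, ddof=1)),
            float(np.std(hr, ddof=1)),
            float(hr.max() - hr.min()),
            float(q75 - q25),
            skew,
            kurt,
            float(np.median(np.abs(hr - np.median(hr)))),
        ]
    )


def absorption_features(signal) -> tuple[float, float]:
    """Mean and sample (n-1) variance of a denoised absorption channel."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty signal")
    var = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), var


def meal_time_feature(acq_time: float, meal_times) -> float:
    """Hours between acquisition and the previous meal.

    The latest meal at or before ``acq_time`` is used; when the
    acquisition precedes the first meal of the day, the gap is measured
    across midnight from the last meal of the (identical) previous-day
    schedule.
    """
    meals = sorted(float(m) for m in meal_times)
    if not meals:
        raise ValueError("meal schedule is empty")
    prior = [m for m in meals if m <= acq_time]
    if prior:
        return float(acq_time - prior[-1])
    return float(24.0 + acq_time - meals[-1])


def _pp_for_channel(rec) -> PPSeries:
    peaks = detect_peaks(rec.samples, rec.fs)
    return compute_pp_intervals(peaks, rec.fs)


def extract_features(measurement: Measurement) -> FeatureVector:
    """Assemble the canonical 103-feature vector of one denoised measurement.

    Category order: meal interval (1), blood pressures (2), absorption
    means/variances (8), HRV per 880 nm channel (52), HR statistics per
    880 nm channel (40).  Any per-channel failure is re-raised naming the
    channel and the block that failed.
    """
    values: list[float] = []
    values.append(meal_time_feature(measurement.acq_time, measurement.meal_times))
    values += [float(measurement.sbp), float(measurement.dbp)]

    for label, rec in zip(_ABSORB_LABELS, measurement.ppg_absorb):
        try:
            mean, var = absorption_features(rec.samples)
        except Exception as exc:  # pragma: no cover - defensive
            raise FeatureExtractionError(f"absorption block failed on channel {label}: {exc}") from exc
        values += [mean, var]

    pp_series = []
    for ch, rec in enumerate(measurement.ppg_880):
        try:
            pp_series.append(_pp_for_channel(rec))
        except Exception as exc:
            raise FeatureExtractionError(f"PP-interval block failed on 880 nm channel {ch}: {exc}") from exc

    for ch, pp in enumerate(pp_series):
        try:
            values += list(hrv_time_features(pp))
            values += list(hrv_freq_features(pp))
        except Exception as exc:
            raise FeatureExtractionError(f"HRV block failed on 880 nm channel {ch}: {exc}") from exc
    for ch, pp in enumerate(pp_series):
        try:
            values += list(hr_stats_features(pp))
        except Exception as exc:
            raise FeatureExtractionError(f"HR-statistics block failed on 880 nm channel {ch}: {exc}") from exc

    return FeatureVector(values=np.asarray(values), names=feature_names())
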