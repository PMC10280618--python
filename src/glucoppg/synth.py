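"""Synthetic multi-wavelength PPG dataset generator.

Emulates a wearable acquisition campaign in which eight finger-cot optical
channels are recorded per measurement -- four at 880 nm sampled fast (HRV
channels) and four at 1450/1650 nm sampled slow (absorption channels) --
together with a reference blood glucose value, blood pressures, the
acquisition clock time and the daily meal schedule.

The glucose trajectory follows a 12-day three-phase diet protocol: a
low-carbohydrate (ketogenic) phase on days 1-4, a normal diet on days 5-8
and a sugared-drink phase with pronounced post-meal excursions on days
9-12.  Glucose couples into the waveform through affine DC / AC amplitude
maps; beat-to-beat intervals carry sinusoidal LF and HF modulation plus
white jitter so that the heart-rate-variability spectrum has power in the
conventional bands.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` spawned per subject and per measurement, so
identical configurations yield byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SynthConfig",
    "PPGRecord",
    "Measurement",
    "generate_glucose_trajectory",
    "generate_beat_intervals",
    "generate_ppg_record",
    "generate_measurement",
    "generate_dataset",
    "MEAL_TIMES",
]

#: Fixed daily meal schedule, hours after midnight (breakfast, lunch, dinner).
MEAL_TIMES = (7.5, 12.5, 18.5)

# Affine glucose -> waveform coupling (amplitude units per mmol/L).  The DC
# level rises with glucose while the pulsatile AC amplitude shrinks,
# saturating at zero; `SynthConfig.coupling` scales both slopes.
_DC_BASE, _DC_SLOPE = 1.0, 0.05
_AC_BASE, _AC_SLOPE = 0.50, 0.02

_MEAN_BEAT_MS = 800.0
_PHASE_DAYS = 4  # days per diet phase; three phases = 12 simulated days


@dataclass
class SynthConfig:
    """Configuration of the synthetic acquisition campaign.

    Parameters
    ----------
    n_subjects, measurements_per_subject : int
        Campaign size.
    duration_s : float
        Length of each PPG record in seconds.
    fs_slow, fs_fast : float
        Sampling rates (Hz) of the 1450/1650 nm and 880 nm channels.
    glucose_range : (float, float)
        Hard clamp on generated glucose, mmol/L.
    coupling : float
        Dimensionless strength of the glucose -> (DC, AC) maps; 0 removes
        the optical glucose signal entirely.
    hrv_lf_hz, hrv_hf_hz : float
        Centre frequencies of the two sinusoidal beat-interval modulators.
    noise_sd : float
        White measurement noise SD, amplitude units.
    drift_amp : float
        Peak amplitude of the slow baseline wander.
    seed : int
        Root seed; every derived stream is spawned from it.
    """

    n_subjects: int = 8
    measurements_per_subject: int = 40
    duration_s: float = 60.0
    fs_slow: float = 50.0
    fs_fast: float = 1000.0
    glucose_range: tuple[float, float] = (3.5, 12.0)
    coupling: float = 1.0
    hrv_lf_hz: float = 0.1
    hrv_hf_hz: float = 0.25
    noise_sd: float = 0.02
    drift_amp: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.measurements_per_subject < 1:
            raise ConfigurationError("subject and measurement counts must be >= 1")
        if not (self.fs_slow > 0 and self.fs_fast > 0 and self.duration_s > 0):
            raise ConfigurationError("rates and duration must be positive")
        if self.fs_slow >= self.fs_fast:
            raise ConfigurationError(
                f"fs_slow ({self.fs_slow}) must be below fs_fast ({self.fs_fast})"
            )
        lo, hi = self.glucose_range
        if not lo < hi:
            raise ConfigurationError(f"glucose_range low must be < high, got {self.glucose_range}")
        if lo <= 0:
            raise ConfigurationError("glucose must be positive")
        if self.hrv_lf_hz <= 0 or self.hrv_hf_hz <= 0:
            raise ConfigurationError("HRV modulation frequencies must be positive")
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise ConfigurationError("noise_sd and drift_amp must be non-negative")


@dataclass
class PPGRecord:
    """One optical channel of one measurement."""

    samples: np.ndarray
    fs: float
    wavelength_nm: int
    channel_id: int
    subject_id: str = ""
    measurement_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.wavelength_nm not in (880, 1450, 1650):
            raise ConfigurationError(f"unsupported wavelength {self.wavelength_nm} nm")


@dataclass
class Measurement:
    """Eight PPG channels plus reference values for one acquisition."""

    ppg_880: list  # 4 PPGRecord, fast rate
    ppg_absorb: list  # 4 PPGRecord: 2 x 1450 nm, 2 x 1650 nm, slow rate
    glucose_ref: float
    sbp: float
    dbp: float
    acq_time: float  # hours after midnight
    meal_times: tuple = MEAL_TIMES
    subject_id: str = ""
    measurement_id: str = ""

    def __post_init__(self) -> None:
        if self.glucose_ref <= 0:
            raise ConfigurationError("glucose_ref must be positive")
        if len(self.ppg_880) != 4 or len(self.ppg_absorb) != 4:
            raise ConfigurationError("a measurement carries 4 + 4 channels")

    @property
    def channels(self):
        return list(self.ppg_880) + list(self.ppg_absorb)


def _phase_mean(day: int) -> float:
    """Baseline glucose (mmol/L) for the diet phase containing ``day`` (0-based)."""
    if day < _PHASE_DAYS:
        return 4.8  # ketogenic
    if day < 2 * _PHASE_DAYS:
        return 6.0  # normal diet
    return 7.2  # sugared-drink phase


def generate_glucose_trajectory(config: SynthConfig, subject_seed: int):
    """Diet-driven glucose values over the 12-day protocol.

    Returns
    -------
    times_h : ndarray
        Measurement times in hours since midnight of day 1, ascending,
        spread over waking hours (07:00-22:00) of the 12 days.
    glucose : ndarray
        mmol/L, clamped to ``config.glucose_range``.

    The sugared-drink phase adds exponentially decaying post-meal spikes
    after lunch and dinner; a small AR(1) disturbance models metabolic
    noise.  Deterministic for a given ``(config, subject_seed)``.
    """
    rng = np.random.default_rng(int(subject_seed))
    n = config.measurements_per_subject
    n_days = 3 * _PHASE_DAYS
    # evenly allotted slots over waking hours of the whole protocol
    slots = np.linspace(0.0, n_days, n, endpoint=False)
    day = slots.astype(int)
    frac = slots - day
    times_h = day * 24.0 + 7.0 + frac * 15.0 + rng.uniform(-0.3, 0.3, size=n)
    times_h = np.sort(times_h)

    day = (times_h // 24.0).astype(int)
    tod = times_h % 24.0
    glucose = np.array([_phase_mean(int(d)) for d in day])

    # post-meal spikes: strongest in the sugared-drink phase, mild otherwise
    spike_amp = np.where(day >= 2 * _PHASE_DAYS, 2.5, 0.8)
    for meal in MEAL_TIMES:
        dt = tod - meal
        mask = dt > 0
        glucose = glucose + np.where(mask, spike_amp * np.exp(-np.clip(dt, 0, None) / 0.9), 0.0)

    ar = np.empty(n)
    eps = rng.normal(0.0, 0.35, size=n)
    prev = 0.0
    for i in range(n):
        prev = 0.6 * prev + eps[i]
        ar[i] = prev
    glucose = glucose + ar

    lo, hi = config.glucose_range
    return times_h, np.clip(glucose, lo, hi)


def generate_beat_intervals(
    config: SynthConfig, duration_s: float, glucose: float, rng: np.random.Generator
) -> np.ndarray:
    """Beat-to-beat interval sequence (ms) covering ``duration_s`` seconds.

    Mean interval 800 ms, modulated by sinusoids at the configured LF and
    HF frequencies plus white jitter.  The HF modulation depth shrinks
    mildly with glucose, mimicking the reduced vagal variability reported
    in hyperglycaemia, which plants an HRV-glucose correlation for the
    downstream models to find.
    """
    m_lf = 0.04
    m_hf = 0.03 * max(0.2, 1.0 - 0.05 * (glucose - 5.5))
    intervals = []
    t = 0.0
    while t < duration_s + 2.0:
        mod = 1.0 + m_lf * np.sin(2 * np.pi * config.hrv_lf_hz * t) + m_hf * np.sin(
            2 * np.pi * config.hrv_hf_hz * t
        )
        iv = _MEAN_BEAT_MS * mod + rng.normal(0.0, 10.0)
        iv = max(iv, 350.0)
        intervals.append(iv)
        t += iv / 1000.0
    return np.asarray(intervals)


def _pulse_train(t: np.ndarray, beat_onsets_s: np.ndarray, beat_periods_s: np.ndarray) -> np.ndarray:
    """Two-Gaussian pulse per beat: systolic peak plus a dicrotic bump at
    0.4 of the beat period.  Unit systolic amplitude."""
    y = np.zeros_like(t)
    for onset, period in zip(beat_onsets_s, beat_periods_s):
        sys_c = onset + 0.18 * period
        dic_c = onset + 0.4 * period
        sig_s = 0.07 * period
        sig_d = 0.12 * period
        lo = np.searchsorted(t, onset - 0.5 * period)
        hi = np.searchsorted(t, onset + 1.5 * period)
        seg = t[lo:hi]
        y[lo:hi] += np.exp(-0.5 * ((seg - sys_c) / sig_s) ** 2)
        y[lo:hi] += 0.22 * np.exp(-0.5 * ((seg - dic_c) / sig_d) ** 2)
    return y


def generate_ppg_record(
    beat_intervals_ms,
    wavelength_nm: int,
    fs: float,
    duration_s: float,
    glucose: float,
    config: SynthConfig,
    seed: int,
    channel_id: int = 0,
) -> PPGRecord:
    """Synthesize one channel: DC(glucose) + AC(glucose) * pulse train
    + baseline drift + white noise.  Sample count is round(duration_s * fs)."""
    intervals = np.asarray(beat_intervals_ms, dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("beat intervals must be positive")
    if intervals.sum() / 1000.0 < duration_s or intervals.size < 5:
        raise ValueError("beat intervals must cover the record duration (>= 5 beats)")
    rng = np.random.default_rng(int(seed))
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    onsets = np.concatenate([[0.0], np.cumsum(intervals)[:-1]]) / 1000.0
    keep = onsets < duration_s + intervals[-1] / 1000.0
    onsets = onsets[keep]
    periods = intervals[keep] / 1000.0

    dc = _DC_BASE + config.coupling * _DC_SLOPE * glucose
    ac = max(_AC_BASE - config.coupling * _AC_SLOPE * glucose, 0.0)

    y = dc + ac * _pulse_train(t, onsets, periods)
    if config.drift_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        f_drift = rng.uniform(0.01, 0.05)
        y = y + config.drift_amp * np.sin(2 * np.pi * f_drift * t + phase)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=n)
    return PPGRecord(samples=y, fs=fs, wavelength_nm=wavelength_nm, channel_id=channel_id)


def _child_seed(root_seed: int, *path: int) -> int:
    """Deterministic 31-bit seed derived from the root seed and a path of
    integer indices (subject, measurement, channel)."""
    ss = np.random.SeedSequence(entropy=(int(root_seed),) + tuple(int(p) for p in path))
    return int(ss.generate_state(1)[0] % 2**31)


def generate_measurement(
    config: SynthConfig,
    subject_idx: int,
    measurement_idx: int,
    acq_time_h: float,
    glucose: float,
) -> Measurement:
    """Build one 8-channel Measurement at a point of the glucose trajectory."""
    rng = np.random.default_rng(_child_seed(config.seed, subject_idx, measurement_idx))
    intervals = generate_beat_intervals(config, config.duration_s, glucose, rng)
    sid = f"S{subject_idx:02d}"
    mid = f"S{subject_idx:02d}M{measurement_idx:03d}"

    ppg_880 = []
    for ch in range(4):
        rec = generate_ppg_record(
            intervals,
            880,
            config.fs_fast,
            config.duration_s,
            glucose,
            config,
            seed=_child_seed(config.seed, subject_idx, measurement_idx, ch),
            channel_id=ch,
        )
        rec.subject_id, rec.measurement_id = sid, mid
        ppg_880.append(rec)

    ppg_absorb = []
    for ch, wl in enumerate((1450, 1450, 1650, 1650)):
        rec = generate_ppg_record(
            intervals,
            wl,
            config.fs_slow,
            config.duration_s,
            glucose,
            config,
            seed=_child_seed(config.seed, subject_idx, measurement_idx, 4 + ch),
            channel_id=ch,
        )
        rec.subject_id, rec.measurement_id = sid, mid
        ppg_absorb.append(rec)

    sbp = float(rng.normal(120.0, 8.0))
    dbp = float(rng.normal(75.0, 6.0))
    return Measurement(
        ppg_880=ppg_880,
        ppg_absorb=ppg_absorb,
        glucose_ref=float(glucose),
        sbp=sbp,
        dbp=dbp,
        acq_time=float(acq_time_h % 24.0),
        meal_times=MEAL_TIMES,
        subject_id=sid,
        measurement_id=mid,
    )


def generate_dataset(config: SynthConfig) -> dict[str, list[Measurement]]:
    """Generate the full campaign: per subject, ``measurements_per_subject``
    Measurements sampled along that subject's diet-driven glucose
    trajectory.  Fully deterministic for a given config."""
    dataset: dict[str, list[Measurement]] = {}
    for s in range(config.n_subjects):
        subject_seed = _child_seed(config.seed, s)
        times_h, glucose = generate_glucose_trajectory(config, subject_seed)
        measurements = [
            generate_measurement(config, s, m, times_h[m], glucose[m])
            for m in range(config.measurements_per_subject)
        ]
        dataset[f"S{s:02d}"] = measurements
    return dataset


def clean_config(config: SynthConfig) -> SynthConfig:
    """Copy of ``config`` with noise and drift disabled (planted-signal runs)."""
    return replace(config, noise_sd=0.0, drift_amp=0.0)
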