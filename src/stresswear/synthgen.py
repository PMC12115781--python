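"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Each synthetic subject is a two-hour session of six scenario segments; one
segment is a forced-high-stress medical emergency.  A piecewise stress
profile (with smooth bounded jitter) drives the three channels at their
native rates with the directions and group means observed in wearable
stress studies: heart rate rises under stress, peripheral skin temperature
falls (vasoconstriction), and electrodermal activity rises both in its
tonic level and in its phasic skin-conductance-response rate.  About 1% of
samples are knocked out at random to exercise imputation.

Default per-level calibration targets:

==========  ========  ========  ========
channel      level 0   level 1   level 2
==========  ========  ========  ========
HR (bpm)      82.23     86.30     84.79
TEMP (°C)     31.81     31.49     31.23
EDA (µS)       0.68      2.09      1.87
==========  ========  ========  ========

Note the deliberately non-monotone HR target at level 2: the generator
follows the calibration table, not a monotone idealization, so HR
monotonicity holds for levels 0 -> 1 while TEMP and EDA are monotone across
all three levels (EDA levels 1-2 both well above level 0).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from stresswear.errors import ValidationError
from stresswear.labeling import LabelConfig, classify_level
from stresswear.sensor_io import ChannelRecording, SessionRecording, StressTrace

CHANNEL_RATES = {"EDA": 4.0, "HR": 1.0, "TEMP": 4.0}


@dataclasses.dataclass
class GeneratorParams:
    """Cohort-level knobs; defaults are the study conditions being emulated."""

    n_subjects: int = 12
    session_duration: float = 7200.0  # seconds per subject
    n_segments: int = 6
    emergency_segment: int = 4  # 1-based segment forced to high stress
    hr_means: tuple[float, float, float] = (82.23, 86.30, 84.79)  # bpm per level
    temp_means: tuple[float, float, float] = (31.81, 31.49, 31.23)  # °C per level
    eda_means: tuple[float, float, float] = (0.68, 2.09, 1.87)  # µS per level
    scr_rate: tuple[float, float, float] = (1.0, 4.0, 8.0)  # SCR events/min per level
    level_values: tuple[float, float, float] = (1 / 6, 1 / 2, 5 / 6)  # band centres
    stress_jitter: float = 0.04  # sd of the smooth stress jitter (hard-clipped at 0.1)
    hr_ar: float = 0.9  # AR(1) coefficient of the HR noise
    hr_noise: float = 1.2  # stationary sd of the HR noise, bpm
    temp_noise: float = 0.05  # white TEMP noise sd, °C
    temp_drift: float = 0.08  # amplitude of the slow TEMP drift, °C
    eda_noise: float = 0.01  # sd of the smoothed EDA noise, µS
    scr_amp: tuple[float, float] = (0.2, 0.4)  # uniform SCR amplitude range, µS
    scr_rise: float = 0.75  # SCR kernel rise time constant, s
    scr_decay: float = 2.0  # SCR kernel decay time constant, s
    trace_rate: float = 1.0  # stress-annotation sampling rate, Hz
    missing_rate: float = 0.0102
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_duration <= 0 or self.n_subjects < 1:
            raise ValidationError("need positive session duration and >= 1 subject")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if not (1 <= self.emergency_segment <= self.n_segments):
            raise ValidationError("emergency_segment out of range")
        if not (self.hr_means[1] > self.hr_means[0]):
            raise ValidationError("HR target must rise from level 0 to level 1")
        if not (self.temp_means[0] > self.temp_means[1] > self.temp_means[2]):
            raise ValidationError("TEMP targets must decrease with stress level")
        if not (min(self.eda_means[1], self.eda_means[2]) > self.eda_means[0]):
            raise ValidationError("EDA targets at levels 1-2 must exceed level 0")


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually emitted, for end-to-end checks."""

    trace: StressTrace
    window_start: np.ndarray  # default windowing (10 s windows every 5 s)
    true_class: np.ndarray
    segment_id: np.ndarray
    segment_levels: np.ndarray  # base stress level per scenario segment


def _segment_levels(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Random segment base levels: a shuffled, near-balanced multiset of
    {low, medium, high} with the emergency segment forced high, so every
    subject visits all three stress levels."""
    pool = np.resize([0, 1, 2], params.n_segments - 1)
    rng.shuffle(pool)
    levels = np.empty(params.n_segments, dtype=int)
    levels[: params.emergency_segment - 1] = pool[: params.emergency_segment - 1]
    levels[params.emergency_segment - 1] = 2
    levels[params.emergency_segment :] = pool[params.emergency_segment - 1 :]
    return levels


def make_stress_profile(
    params: GeneratorParams, seed: int, segment_levels: Optional[np.ndarray] = None
) -> tuple[StressTrace, np.ndarray]:
    """One subject's continuous stress annotation.

    Piecewise-constant base values per segment (levels drawn from
    {low, medium, high}; the emergency segment forced high) plus smooth
    bounded jitter, clipped to [0, 1].  The jitter is clipped at ±0.10,
    less than the ±1/6 half-width of each class band, so every instant
    keeps its intended class.  Returns the trace and the segment levels.
    """
    rng = np.random.default_rng(seed)
    if segment_levels is None:
        segment_levels = _segment_levels(params, rng)
    segment_levels = np.asarray(segment_levels)
    n = int(round(params.session_duration * params.trace_rate))
    t = np.arange(n) / params.trace_rate
    seg_len = params.session_duration / params.n_segments
    seg_of_t = np.minimum((t / seg_len).astype(int), params.n_segments - 1)
    base = np.asarray(params.level_values)[segment_levels[seg_of_t]]
    if params.stress_jitter > 0:
        raw = rng.standard_normal(n)
        smooth = gaussian_filter1d(raw, sigma=8.0 * params.trace_rate)
        sd = smooth.std()
        jitter = np.clip(smooth / sd * params.stress_jitter if sd > 0 else smooth, -0.1, 0.1)
    else:
        jitter = np.zeros(n)
    values = np.clip(base + jitter, 0.0, 1.0)
    return StressTrace(timestamps=t, values=values), segment_levels


def _stress_at(trace: StressTrace, times: np.ndarray) -> np.ndarray:
    return np.interp(times, trace.timestamps, trace.values)


def _scr_kernel(params: GeneratorParams, rate: float) -> np.ndarray:
    """Bi-exponential skin-conductance-response shape, peak-normalized to 1."""
    t = np.arange(0, 10.0, 1.0 / rate)
    kernel = np.exp(-t / params.scr_decay) - np.exp(-t / params.scr_rise)
    return kernel / kernel.max()


def synth_channel(
    trace: StressTrace, channel: str, params: GeneratorParams, seed: int
) -> ChannelRecording:
    """Synthesize one channel at its native rate from a stress trace.

    HR (1 Hz): per-level target mean plus stationary AR(1) noise.
    TEMP (4 Hz): per-level target mean plus a slow sinusoidal drift and
    white noise.  EDA (4 Hz): tonic level at the per-level target plus a
    Poisson process of bi-exponential SCR bumps whose rate increases with
    stress, plus smoothed noise, floored at 0 µS.
    """
    if channel not in CHANNEL_RATES:
        raise ValidationError(f"unknown channel {channel!r}")
    rng = np.random.default_rng(seed)
    rate = CHANNEL_RATES[channel]
    n = int(round(params.session_duration * rate)) + 1
    times = np.arange(n) / rate
    stress = _stress_at(trace, times)
    levels = np.fromiter((classify_level(s) for s in stress), dtype=int, count=n)

    if channel == "HR":
        target = np.asarray(params.hr_means)[levels]
        eps_sd = params.hr_noise * np.sqrt(1.0 - params.hr_ar**2)
        eps = rng.normal(0.0, eps_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, params.hr_noise)
        for i in range(1, n):
            noise[i] = params.hr_ar * noise[i - 1] + eps[i]
        samples = target + noise
    elif channel == "TEMP":
        target = np.asarray(params.temp_means)[levels]
        period = 1200.0  # 20-minute quasi-thermoregulatory drift cycle
        drift = params.temp_drift * np.sin(2 * np.pi * times / period + rng.uniform(0, 2 * np.pi))
        samples = target + drift + rng.normal(0.0, params.temp_noise, size=n)
    else:  # EDA
        tonic = gaussian_filter1d(np.asarray(params.eda_means)[levels], sigma=4.0 * rate)
        event_prob = np.asarray(params.scr_rate)[levels] / 60.0 / rate
        events = rng.random(n) < event_prob
        amplitudes = np.where(events, rng.uniform(*params.scr_amp, size=n), 0.0)
        phasic = np.convolve(amplitudes, _scr_kernel(params, rate))[:n]
        noise = gaussian_filter1d(rng.standard_normal(n), sigma=2.0 * rate)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * params.eda_noise
        samples = np.maximum(tonic + phasic + noise, 0.0)
    return ChannelRecording(channel=channel, start_time=0.0, rate=rate, samples=samples)


def count_scr_events(trace: StressTrace, params: GeneratorParams, seed: int) -> np.ndarray:
    """Per-segment count of generated SCR events (replays the EDA event draw)."""
    rng = np.random.default_rng(seed)
    rate = CHANNEL_RATES["EDA"]
    n = int(round(params.session_duration * rate)) + 1
    times = np.arange(n) / rate
    stress = _stress_at(trace, times)
    levels = np.fromiter((classify_level(s) for s in stress), dtype=int, count=n)
    events = rng.random(n) < np.asarray(params.scr_rate)[levels] / 60.0 / rate
    seg_len = params.session_duration / params.n_segments
    seg_of_t = np.minimum((times / seg_len).astype(int), params.n_segments - 1)
    return np.bincount(seg_of_t[events], minlength=params.n_segments)


def inject_missing(rec: ChannelRecording, rate: float, seed: int) -> ChannelRecording:
    """Knock out each sample independently with probability ``rate`` (MCAR)."""
    if not (0 <= rate < 1):
        raise ValidationError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = rec.samples.copy()
    samples[rng.random(samples.size) < rate] = np.nan
    return ChannelRecording(
        channel=rec.channel, start_time=rec.start_time, rate=rec.rate, samples=samples
    )


def _ground_truth(
    trace: StressTrace,
    segment_levels: np.ndarray,
    params: GeneratorParams,
    window: float = 10.0,
    step: float = 5.0,
) -> GroundTruth:
    starts = np.arange(0.0, params.session_duration - window + 1e-9, step)
    classes = np.empty(starts.size, dtype=int)
    cfg = LabelConfig()
    for i, s in enumerate(starts):
        mask = (trace.timestamps >= s) & (trace.timestamps < s + window)
        classes[i] = classify_level(float(trace.values[mask].mean()), cfg)
    seg_len = params.session_duration / params.n_segments
    segment_id = np.minimum((starts / seg_len).astype(int), params.n_segments - 1) + 1
    return GroundTruth(
        trace=trace,
        window_start=starts,
        true_class=classes,
        segment_id=segment_id,
        segment_levels=np.asarray(segment_levels),
    )


def generate_subject(
    params: GeneratorParams,
    subject_id: str,
    seed_sequence: np.random.SeedSequence,
    segment_levels: Optional[Sequence[int]] = None,
) -> tuple[SessionRecording, StressTrace, GroundTruth]:
    """One synthetic session: three channels, stress trace and ground truth."""
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_sequence.spawn(7)]
    trace, levels = make_stress_profile(params, seeds[0], segment_levels)
    channels = {}
    for i, channel in enumerate(("EDA", "HR", "TEMP")):
        rec = synth_channel(trace, channel, params, seeds[1 + i])
        if params.missing_rate > 0:
            rec = inject_missing(rec, params.missing_rate, seeds[4 + i])
        channels[channel] = rec
    boundaries = list(
        np.linspace(0.0, params.session_duration, params.n_segments + 1)
    )
    session = SessionRecording(
        subject_id=subject_id, channels=channels, segment_boundaries=boundaries
    )
    truth = _ground_truth(trace, levels, params)
    return session, trace, truth


def generate_eda_only_cohort(
    params: GeneratorParams,
) -> list[tuple[SessionRecording, StressTrace, GroundTruth]]:
    """Cohort in which only EDA carries the stress signal.

    EDA follows the usual stress-driven model; HR and TEMP are
    stress-independent noise around fixed baselines.  Used to check that
    importance analysis attributes the class signal to EDA-derived
    features.
    """
    root = np.random.SeedSequence(params.seed)
    cohort = []
    for i, child in enumerate(root.spawn(params.n_subjects)):
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in child.spawn(4)]
        trace, levels = make_stress_profile(params, seeds[0])
        rng = np.random.default_rng(seeds[1])
        n1 = int(round(params.session_duration)) + 1
        n4 = int(round(params.session_duration * 4)) + 1
        channels = {
            "EDA": synth_channel(trace, "EDA", params, seeds[2]),
            "HR": ChannelRecording(
                "HR", 0.0, 1.0, 75.0 + rng.normal(0.0, params.hr_noise or 1.0, n1)
            ),
            "TEMP": ChannelRecording(
                "TEMP", 0.0, 4.0, 32.0 + rng.normal(0.0, params.temp_noise or 0.05, n4)
            ),
        }
        session = SessionRecording(
            subject_id=f"S{i + 1:02d}",
            channels=channels,
            segment_boundaries=list(
                np.linspace(0.0, params.session_duration, params.n_segments + 1)
            ),
        )
        cohort.append((session, trace, _ground_truth(trace, levels, params)))
    return cohort


def generate_cohort(
    params: GeneratorParams = GeneratorParams(),
) -> list[tuple[SessionRecording, StressTrace, GroundTruth]]:
    """Generate the full cohort; per-subject seeds derive from the master seed.

    At defaults: 12 subjects x 7200 s = 86,400 s of recordings in total.
    The same master seed always reproduces the identical cohort.
    """
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_subjects)
    cohort = []
    for i, child in enumerate(children):
        subject_id = f"S{i + 1:02d}"
        cohort.append(generate_subject(params, subject_id, child))
    return cohort
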