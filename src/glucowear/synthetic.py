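"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Interstitial glucose is modelled as baseline + circadian sinusoid + meal-driven
postprandial bumps (difference-of-exponentials kernels normalised so the peak
equals the configured amplitude) + AR(1) noise, clamped to [40, 400] mg/dL.
Sensor channels are nonlinear, lagged, gain-scaled images of glucose plus a
glucose-independent confound drift (partially shared across channels within a
participant), white measurement noise, seeded missing samples and injected
6-10 sigma artifact spikes.  Temperature channels additionally carry a
per-calendar-day ambient (seasonal) offset, so 'days_from_2021' is real signal.

This is deliberately NOT a mechanistic glucose-insulin model; it reproduces
only the dependence structure the downstream analysis is designed to exploit.
Identical configuration (including seed) yields bit-identical cohorts.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import PID_COL, TARGET_COL, TIME_COL, FeatureMatrix
from .types import (
    ConfigError, Demographics, GlucoseTrace, MODALITIES, ParticipantRecord,
    Phase, SensorStream, TEMPERATURE_MODALITIES, GLUCOSE_RANGE,
)

NONLINEARITIES = ("linear", "saturating", "threshold")

#: device-native sampling rates, Hz
DEFAULT_CHANNEL_RATES = {
    "STEMP": 4.0, "EDA": 4.0, "BVP": 64.0, "HR": 1.0,
    "BTEMP": 200.0, "PZT": 200.0, "EGG": 200.0, "EOG": 200.0,
}

# rng stream tags (spawn keys) so every randomness source is independent
_TAG_GLUCOSE = 1
_TAG_MEALS = 2
_TAG_DEMOGRAPHICS = 3
_TAG_SHARED_CONFOUND = 4
_TAG_CHANNEL_BASE = 100  # + modality index


@dataclass
class MealEvent:
    """One scheduled meal: peak excursion and rise/decay kinetics."""

    time: float  # minutes from midnight
    amplitude: float  # peak glucose excursion, mg/dL
    rise_time: float = 15.0  # minutes
    decay_time: float = 45.0  # minutes
    kind: str = "free"  # {MMT, OGTT, free}

    def __post_init__(self) -> None:
        if not 0 <= self.time < 1440:
            raise ConfigError("meal time must be in [0, 1440) minutes")
        if self.amplitude < 0:
            raise ConfigError("meal amplitude must be >= 0")
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise ConfigError("rise/decay times must be positive")
        if self.kind not in ("MMT", "OGTT", "free"):
            raise ConfigError(f"unknown meal kind {self.kind!r}")


def meal_kernel(t_minutes, rise: float, decay: float) -> np.ndarray:
    """Unit-peak postprandial bump at t minutes after intake (0 before)."""
    t = np.asarray(t_minutes, dtype=float)
    if abs(decay - rise) < 1e-9:
        out = (t / rise) * np.exp(1.0 - t / rise)
    else:
        t_peak = np.log(decay / rise) * rise * decay / (decay - rise)
        norm = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
        out = (np.exp(-t / decay) - np.exp(-t / rise)) / norm
    return np.where(t > 0, out, 0.0)


@dataclass
class ChannelCoupling:
    """How one sensor channel reflects (or ignores) glucose."""

    gain: float = 0.0  # channel units per mg/dL of glucose excursion
    lag_min: float = 0.0  # minutes the channel trails glucose
    nonlinearity: str = "linear"
    noise_sd: float = 0.0  # white measurement noise, channel units
    confound_sd: float = 0.0  # glucose-independent drift, channel units
    baseline: float = 0.0  # resting channel level
    sat_scale: float | None = None  # soft-saturation knee (channel units)
    threshold: float = 0.0  # dead zone for the 'threshold' nonlinearity

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.confound_sd < 0:
            raise ConfigError("noise_sd/confound_sd must be >= 0")
        if self.lag_min < 0:
            raise ConfigError("lag must be >= 0")
        if self.nonlinearity not in NONLINEARITIES:
            raise ConfigError(f"nonlinearity must be one of {NONLINEARITIES}")


@dataclass
class CouplingSpec:
    """Per-channel couplings plus the shared fraction of the confound drift.

    ``confound_shared_fraction`` f mixes one per-participant drift process
    (loading sqrt(f)) with a private per-channel drift (loading sqrt(1-f)).
    A shared drift is what lets several channels jointly resolve glucose even
    though each one alone is confound-dominated.
    """

    channels: dict[str, ChannelCoupling] = field(default_factory=dict)
    confound_shared_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.confound_shared_fraction <= 1.0:
            raise ConfigError("confound_shared_fraction must be in [0, 1]")
        for name in self.channels:
            if name not in MODALITIES:
                raise ConfigError(f"unknown modality {name!r} in coupling spec")

    def for_channel(self, name: str) -> ChannelCoupling:
        return self.channels.get(name, ChannelCoupling())


def default_coupling() -> CouplingSpec:
    """Plausible resting levels and mild couplings for the wristband channels."""
    return CouplingSpec(channels={
        "STEMP": ChannelCoupling(gain=0.02, lag_min=2.0, nonlinearity="saturating",
                                 noise_sd=0.1, confound_sd=0.8, baseline=33.5),
        "EDA": ChannelCoupling(gain=0.05, lag_min=1.0, nonlinearity="saturating",
                               noise_sd=0.2, confound_sd=1.5, baseline=6.0),
        "BVP": ChannelCoupling(gain=0.4, lag_min=0.0, nonlinearity="linear",
                               noise_sd=2.0, confound_sd=10.0, baseline=0.0),
        "HR": ChannelCoupling(gain=0.15, lag_min=0.0, nonlinearity="linear",
                              noise_sd=1.0, confound_sd=4.0, baseline=70.0),
        "BTEMP": ChannelCoupling(gain=0.012, lag_min=3.0, nonlinearity="saturating",
                                 noise_sd=0.05, confound_sd=0.5, baseline=36.8),
        "PZT": ChannelCoupling(gain=0.0, noise_sd=1.0, confound_sd=2.0,
                               baseline=15.0),
        "EGG": ChannelCoupling(gain=0.0, noise_sd=0.5, confound_sd=1.0),
        "EOG": ChannelCoupling(gain=0.0, noise_sd=0.5, confound_sd=1.0),
    })


def _default_meals() -> list[MealEvent]:
    return [
        MealEvent(time=9 * 60 + 30, amplitude=55.0, rise_time=15.0,
                  decay_time=45.0, kind="MMT"),
        MealEvent(time=12 * 60 + 30, amplitude=75.0, rise_time=12.0,
                  decay_time=40.0, kind="OGTT"),
    ]


@dataclass
class SyntheticConfig:
    """Cohort-level generator configuration; identical config => identical cohort."""

    n_participants: int = 5
    days_per_participant: int = 2
    channel_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_RATES))
    cgm_cadence_min: float = 15.0
    hours_per_day: float = 24.0  # daily CGM coverage
    day_start_hour: float = 0.0
    sensor_hours_per_day: float | None = None  # defaults to hours_per_day
    sensor_start_hour: float | None = None  # defaults to day_start_hour
    baseline_glucose: float = 90.0
    circadian_amplitude: float = 8.0  # mg/dL
    circadian_phase_hour: float = 16.0  # hour of the sinusoid peak
    randomize_circadian_phase: bool = False
    glucose_noise_sd: float = 4.0  # stationary AR(1) sd, mg/dL
    glucose_ar_coef: float = 0.8  # at the CGM cadence
    meal_schedule: list[MealEvent] = field(default_factory=_default_meals)
    meal_time_jitter_min: float = 0.0  # uniform +- jitter per participant-day
    meal_amplitude_rel_sd: float = 0.0  # relative lognormal-ish amplitude spread
    coupling: CouplingSpec = field(default_factory=default_coupling)
    missing_fraction: float = 0.0
    artifact_rate: float = 0.0  # events/hour
    seasonal_amplitude: float = 3.0  # degC ambient offset on temperature channels
    start_date: str = "2021-06-01"
    age_range: tuple[int, int] = (20, 40)
    study_arm: str = "main"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.days_per_participant < 1:
            raise ConfigError("need >= 1 participant and >= 1 day")
        if self.cgm_cadence_min <= 0:
            raise ConfigError("cgm_cadence_min must be positive")
        if not self.channel_rates:
            raise ConfigError("channel_rates must not be empty")
        for name, rate in self.channel_rates.items():
            if name not in MODALITIES:
                raise ConfigError(f"unknown modality {name!r}")
            if rate <= 0:
                raise ConfigError(f"rate for {name} must be > 0")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigError("missing_fraction must be in [0, 1)")
        if self.artifact_rate < 0:
            raise ConfigError("artifact_rate must be >= 0")
        if self.hours_per_day <= 0 or self.hours_per_day > 24:
            raise ConfigError("hours_per_day must be in (0, 24]")

    @property
    def start_epoch(self) -> float:
        d = _dt.date.fromisoformat(self.start_date)
        return float((d - _dt.date(1970, 1, 1)).days) * 86400.0

    def _sensor_window(self) -> tuple[float, float]:
        start = (self.day_start_hour if self.sensor_start_hour is None
                 else self.sensor_start_hour)
        hours = (self.hours_per_day if self.sensor_hours_per_day is None
                 else self.sensor_hours_per_day)
        return start, hours


def _rng(cfg: SyntheticConfig, participant_index: int, tag: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF,
                                int(participant_index), int(tag)]))


def _participant_index(cfg: SyntheticConfig, participant_id) -> int:
    if isinstance(participant_id, (int, np.integer)):
        return int(participant_id)
    return int(str(participant_id).lstrip("PG").lstrip("0") or 0)


def _draw_meals(cfg: SyntheticConfig, pidx: int) -> list[list[MealEvent]]:
    """Realised per-day meal events (shared by glucose and phase annotation)."""
    rng = _rng(cfg, pidx, _TAG_MEALS)
    per_day: list[list[MealEvent]] = []
    for _ in range(cfg.days_per_participant):
        meals = []
        for m in cfg.meal_schedule:
            dt = rng.uniform(-cfg.meal_time_jitter_min, cfg.meal_time_jitter_min)
            amp = m.amplitude * max(
                0.0, 1.0 + cfg.meal_amplitude_rel_sd * rng.standard_normal())
            meals.append(replace(m, time=float(np.clip(m.time + dt, 0, 1439.99)),
                                 amplitude=amp))
        per_day.append(meals)
    return per_day


def _glucose_clean(cfg: SyntheticConfig, pidx: int, t: np.ndarray,
                   per_day_meals: list[list[MealEvent]],
                   phase_hour: float) -> np.ndarray:
    """Noise-free glucose value at arbitrary master-clock times t (seconds)."""
    hours = np.mod(t, 86400.0) / 3600.0
    g = cfg.baseline_glucose + cfg.circadian_amplitude * np.sin(
        2 * np.pi * (hours - phase_hour) / 24.0 + np.pi / 2.0)
    for d, meals in enumerate(per_day_meals):
        day0 = cfg.start_epoch + d * 86400.0
        for m in meals:
            dt_min = (t - (day0 + m.time * 60.0)) / 60.0
            g = g + m.amplitude * meal_kernel(dt_min, m.rise_time, m.decay_time)
    return g


def _circadian_phase(cfg: SyntheticConfig, pidx: int) -> float:
    if not cfg.randomize_circadian_phase:
        return cfg.circadian_phase_hour
    rng = _rng(cfg, pidx, _TAG_GLUCOSE + 50)
    return float(rng.uniform(0.0, 24.0))


def _label_times(cfg: SyntheticConfig) -> np.ndarray:
    per_day = int(round(cfg.hours_per_day * 60.0 / cfg.cgm_cadence_min))
    if per_day < 1:
        raise ConfigError("day span shorter than one CGM cadence")
    times = []
    for d in range(cfg.days_per_participant):
        day0 = cfg.start_epoch + d * 86400.0 + cfg.day_start_hour * 3600.0
        times.append(day0 + np.arange(per_day) * cfg.cgm_cadence_min * 60.0)
    return np.concatenate(times)


def simulate_glucose(cfg: SyntheticConfig, participant_id) -> GlucoseTrace:
    """CGM label trace for one participant at the configured cadence."""
    pidx = _participant_index(cfg, participant_id)
    t = _label_times(cfg)
    meals = _draw_meals(cfg, pidx)
    g = _glucose_clean(cfg, pidx, t, meals, _circadian_phase(cfg, pidx))
    if cfg.glucose_noise_sd > 0:
        rng = _rng(cfg, pidx, _TAG_GLUCOSE)
        eps = rng.standard_normal(t.size)
        phi = cfg.glucose_ar_coef
        noise = np.empty(t.size)
        noise[0] = cfg.glucose_noise_sd * eps[0]
        innov_sd = cfg.glucose_noise_sd * np.sqrt(max(1.0 - phi * phi, 0.0))
        for k in range(1, t.size):
            noise[k] = phi * noise[k - 1] + innov_sd * eps[k]
        g = g + noise
    return GlucoseTrace(timestamps=t,
                        values=np.clip(g, GLUCOSE_RANGE[0], GLUCOSE_RANGE[1]))


def _smooth_drift(rng, t: np.ndarray, n_components: int = 4) -> np.ndarray:
    """Approximately unit-sd smooth drift: a few random-phase sinusoids."""
    periods = rng.uniform(20.0, 240.0, n_components) * 60.0  # seconds
    phases = rng.uniform(0.0, 2 * np.pi, n_components)
    out = np.zeros_like(t, dtype=float)
    for p, ph in zip(periods, phases):
        out += np.sin(2 * np.pi * t / p + ph)
    return out / np.sqrt(n_components / 2.0)


def _sensor_times(cfg: SyntheticConfig, rate: float) -> np.ndarray:
    start_hour, hours = cfg._sensor_window()
    per_day = int(round(hours * 3600.0 * rate))
    chunks = []
    for d in range(cfg.days_per_participant):
        day0 = cfg.start_epoch + d * 86400.0 + start_hour * 3600.0
        chunks.append(day0 + np.arange(per_day) / rate)
    return np.concatenate(chunks)


def _apply_nonlinearity(u: np.ndarray, c: ChannelCoupling) -> np.ndarray:
    if c.nonlinearity == "linear":
        return u
    if c.nonlinearity == "saturating":
        if c.gain == 0:
            return np.zeros_like(u)
        s = c.sat_scale if c.sat_scale is not None else abs(c.gain) * 75.0
        return s * np.tanh(u / s)
    return np.maximum(u - c.threshold, 0.0)  # threshold


def simulate_sensors(
    glucose: GlucoseTrace, cfg: SyntheticConfig, participant_id
) -> list[SensorStream]:
    """One stream per configured modality, coupled to the given glucose trace."""
    if len(glucose) == 0:
        raise ConfigError("glucose trace must be nonempty")
    pidx = _participant_index(cfg, participant_id)
    shared_rng = _rng(cfg, pidx, _TAG_SHARED_CONFOUND)
    f = cfg.coupling.confound_shared_fraction
    streams = []
    shared_cache: np.ndarray | None = None
    shared_t: np.ndarray | None = None
    for name, rate in sorted(cfg.channel_rates.items()):
        if name not in MODALITIES:
            raise ConfigError(f"unknown modality {name!r}")
        c = cfg.coupling.for_channel(name)
        rng = _rng(cfg, pidx, _TAG_CHANNEL_BASE + MODALITIES.index(name))
        t = _sensor_times(cfg, rate)
        g = np.interp(t - c.lag_min * 60.0, glucose.timestamps, glucose.values)
        x = c.baseline + _apply_nonlinearity(
            c.gain * (g - cfg.baseline_glucose), c)
        if c.confound_sd > 0:
            if shared_cache is None:
                # shared drift realised once per participant on a 1-min grid
                t0 = cfg.start_epoch
                t1 = t0 + cfg.days_per_participant * 86400.0
                shared_t = np.arange(t0, t1, 60.0)
                shared_cache = _smooth_drift(shared_rng, shared_t)
            shared = np.interp(t, shared_t, shared_cache)
            private = _smooth_drift(rng, t)
            x = x + c.confound_sd * (
                np.sqrt(f) * shared + np.sqrt(1.0 - f) * private)
        if c.noise_sd > 0:
            x = x + rng.normal(0.0, c.noise_sd, t.size)
        if name in TEMPERATURE_MODALITIES and cfg.seasonal_amplitude != 0:
            days = np.floor((t - 1609459200.0) / 86400.0)
            x = x + cfg.seasonal_amplitude * np.sin(
                2 * np.pi * (days - 80.0) / 365.25)
        if cfg.missing_fraction > 0:
            keep = rng.random(t.size) >= cfg.missing_fraction
            t, x = t[keep], x[keep]
        if cfg.artifact_rate > 0 and t.size:
            _, hours = cfg._sensor_window()
            n_art = rng.poisson(
                cfg.artifact_rate * hours * cfg.days_per_participant)
            if n_art:
                idx = rng.choice(t.size, size=min(n_art, t.size), replace=False)
                sigma = max(float(np.std(x)), 1e-9)
                mags = rng.uniform(6.0, 10.0, idx.size) * sigma
                signs = rng.choice([-1.0, 1.0], idx.size)
                x = x.copy()
                x[idx] += signs * mags
        streams.append(SensorStream(
            modality=name, native_rate=rate, timestamps=t, values=x))
    return streams


def _demographics(cfg: SyntheticConfig, pidx: int) -> Demographics:
    rng = _rng(cfg, pidx, _TAG_DEMOGRAPHICS)
    age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
    sex = "F" if rng.random() < 0.5 else "M"
    height = float(np.clip(rng.normal(169.0 if sex == "F" else 177.0, 7.0),
                           150.0, 205.0))
    bmi = float(rng.uniform(19.0, 29.0))
    weight = bmi * (height / 100.0) ** 2
    return Demographics(age=age, sex=sex, height_cm=height, weight_kg=weight)


def _phases(cfg: SyntheticConfig, pidx: int,
            per_day_meals: list[list[MealEvent]]) -> list[Phase] | None:
    if not any(m.kind in ("MMT", "OGTT") for meals in per_day_meals
               for m in meals):
        return None
    start_hour, hours = cfg._sensor_window()
    phases: list[Phase] = []
    for d, meals in enumerate(per_day_meals):
        day0 = cfg.start_epoch + d * 86400.0
        rec_start = day0 + start_hour * 3600.0
        rec_end = rec_start + hours * 3600.0
        interventions = []
        for m in sorted(meals, key=lambda m: m.time):
            if m.kind not in ("MMT", "OGTT"):
                continue
            s = day0 + m.time * 60.0
            e = min(s + 7200.0, rec_end)
            if interventions and s < interventions[-1].end:
                s = interventions[-1].end
            if e > s:
                interventions.append(Phase(start=s, end=e, label=m.kind))
        cursor = rec_start
        for iv in interventions:
            if iv.start > cursor:
                phases.append(Phase(start=cursor, end=iv.start, label="washout"))
            phases.append(iv)
            cursor = iv.end
        if rec_end > cursor:
            phases.append(Phase(start=cursor, end=rec_end, label="washout"))
    return phases


def generate_cohort(cfg: SyntheticConfig) -> list[ParticipantRecord]:
    """Full cohort: demographics, sensor streams, glucose and phase annotations."""
    records = []
    for pidx in range(1, cfg.n_participants + 1):
        glucose = simulate_glucose(cfg, pidx)
        streams = simulate_sensors(glucose, cfg, pidx)
        meals = _draw_meals(cfg, pidx)
        records.append(ParticipantRecord(
            id=f"P{pidx:02d}",
            demographics=_demographics(cfg, pidx),
            streams={s.modality: s for s in streams},
            glucose=glucose,
            phases=_phases(cfg, pidx, meals),
            study_arm=cfg.study_arm,
        ))
    return records


# ------------------------------------------------------- selector test beds

def planted_feature_matrix(
    n_participants: int = 32,
    rows_per_participant: int = 30,
    n_features: int = 20,
    n_informative: int = 3,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Grouped regression matrix with a known set of informative features.

    The target is an affine combination of the first ``n_informative``
    standard-normal features (coefficients 15, 10, 8, ...) around 110 mg/dL
    plus Gaussian noise; the remaining features are independent noise.  Used
    to measure selector recall against the generative truth.
    """
    rng = np.random.default_rng(seed)
    n = n_participants * rows_per_participant
    X = rng.standard_normal((n, n_features))
    coefs = np.zeros(n_features)
    base = [15.0, 10.0, 8.0]
    for i in range(n_informative):
        coefs[i] = base[i % 3] * (1.0 + i // 3)
    y = 110.0 + X @ coefs + noise_sd * rng.standard_normal(n)
    y = np.clip(y, GLUCOSE_RANGE[0], GLUCOSE_RANGE[1])
    names = [f"signal_{i}" if i < n_informative else f"noise_{i:02d}"
             for i in range(n_features)]
    frame = pd.DataFrame(X, columns=names)
    frame[PID_COL] = np.repeat(
        [f"G{i:02d}" for i in range(n_participants)], rows_per_participant)
    frame[TIME_COL] = np.arange(n, dtype=float) * 300.0
    frame[TARGET_COL] = y
    return FeatureMatrix(frame=frame, feature_names=names)


def planted_informative_names(n_informative: int = 3) -> list[str]:
    return [f"signal_{i}" for i in range(n_informative)]
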