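"""Hand-crafted feature registry over prediction-horizon windows.

Four feature domains are produced for every usable window: per-channel
statistical order features, per-channel frequency/amplitude features,
time-context features (circadian minutes from midnight, seasonal days from
2021-01-01), and demographics broadcast per participant, plus an optional
meal-phase marker in the main-study configuration.  Per-participant z-score
variants (Gamma = (x - mu)/sigma) are appended ALONGSIDE raw values for all
sensor-data features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import argrelextrema
from scipy.stats import kurtosis as _kurtosis

from . import preprocessing as prep
from .types import ConfigError, ParticipantRecord

log = logging.getLogger(__name__)

EPOCH_2021 = 1609459200.0  # 2021-01-01T00:00:00, master-clock frame

#: per-channel statistical order features (temperature difference is
#: per-window, emitted once, see assemble_features)
STAT_NAMES = (
    "mean", "max", "min", "std", "median", "zero_crossings",
    "p20", "p50", "p80", "iqr_25_75", "autocorr_lag1",
)

_N_IFFT = 10  # retained leading inverse-FFT coefficient magnitudes

#: per-channel frequency/amplitude-domain features (23)
SPECTRAL_NAMES = (
    "argrelextrema_number_of_peaks",
    "argrelextrema_number_of_pits",
    "argrelextrema_mean_peak_amplitude",
    "argrelextrema_mean_pit_amplitude",
    "dwt_approx_mean", "dwt_approx_std", "dwt_approx_energy",
    "dwt_detail_mean", "dwt_detail_std", "dwt_detail_energy",
    *[f"ifft_coef_{i}" for i in range(_N_IFFT)],
    "kurtosis", "spectralEnergy", "spectralEntropy",
)

TEMPDIFF_NAME = "tempdiff_STEMP_BTEMP"

WAVELET = "db4"
MAX_DWT_LEVEL = 3
EXTREMA_ORDER = 3  # argrelextrema neighbourhood at the working rate

MAIN_CATEGORIES = ("demographics", "time_domain", "phase_marker", "sensor_data")

#: functional subcategories as enumerated in the field taxonomy
CHANNEL_SUBCATEGORY = {
    "STEMP": "skin temperature",
    "BVP": "blood volume pulse",
    "HR": "heart rate",
    "EDA": "electrodermal activity",
    "BTEMP": "body temperature",
    "CTEMP": "body temperature",
    "PZT": "respiratory rate",
    "EGG": "electrogastrography",
    "EOG": "electrooculography",
}


@dataclass(frozen=True)
class FeatureSpec:
    """One named column of the modeling matrix."""

    name: str
    category: str
    subcategory: str
    channel: str | None = None
    extractor: str = ""
    is_zscore: bool = False

    def __post_init__(self) -> None:
        if self.category not in MAIN_CATEGORIES:
            raise ConfigError(f"unknown category {self.category!r}")
        if self.category == "sensor_data" and self.channel is None:
            raise ConfigError(f"sensor-data spec {self.name!r} must name a channel")


PID_COL = "participant_id"
TIME_COL = "window_end_time"
TARGET_COL = "glucose_mgdl"
META_COLS = (PID_COL, TIME_COL, TARGET_COL)


@dataclass
class FeatureMatrix:
    """One row per usable window: named features, target, row provenance."""

    frame: pd.DataFrame
    feature_names: list[str]
    specs: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLS, *self.feature_names)
                   if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"feature matrix missing columns: {missing}")
        feats = self.frame[self.feature_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(feats)):
            raise ConfigError("feature matrix contains non-finite values")
        if np.any(self.frame[TARGET_COL].to_numpy(dtype=float) <= 0):
            raise ConfigError("targets must be positive mg/dL")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[TARGET_COL].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return self.frame[PID_COL].to_numpy()

    @property
    def window_end_times(self) -> np.ndarray:
        return self.frame[TIME_COL].to_numpy(dtype=float)

    def zscored_names(self) -> list[str]:
        return [s.name for s in self.specs if s.is_zscore]

    def restrict(self, names) -> "FeatureMatrix":
        """New matrix keeping only the given feature columns (order preserved)."""
        names = [n for n in self.feature_names if n in set(names)]
        cols = [*META_COLS, *names]
        spec_by_name = {s.name: s for s in self.specs}
        return FeatureMatrix(
            frame=self.frame[cols].copy(),
            feature_names=names,
            specs=[spec_by_name[n] for n in names if n in spec_by_name],
        )

    def subset_rows(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(
            frame=self.frame.loc[mask].reset_index(drop=True),
            feature_names=list(self.feature_names),
            specs=list(self.specs),
        )


def concat_matrices(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    if not matrices:
        raise ConfigError("nothing to concatenate")
    names = matrices[0].feature_names
    for m in matrices[1:]:
        if m.feature_names != names:
            raise ConfigError("feature matrices have mismatching columns")
    return FeatureMatrix(
        frame=pd.concat([m.frame for m in matrices], ignore_index=True),
        feature_names=list(names),
        specs=list(matrices[0].specs),
    )


# ---------------------------------------------------------------- extractors

def _as2d(values) -> tuple[np.ndarray, bool]:
    a = np.asarray(values, dtype=float)
    if a.ndim == 1:
        return a[None, :], True
    return a, False


def _unwrap(d: dict, squeeze: bool) -> dict:
    if squeeze:
        return {k: float(v[0]) for k, v in d.items()}
    return d


def statistical_features(values, channel: str | None = None) -> dict:
    """The per-channel statistical order features of one window (or a stack).

    Accepts a 1-D window or an (n_windows, width) stack; returns a dict of
    scalars resp. arrays.  Degenerate conventions: a single-sample or
    constant window has std = 0, autocorrelation = 0.
    """
    x, squeeze = _as2d(values)
    if x.shape[1] == 0:
        raise ConfigError("window must be nonempty")
    if x.shape[1] == 1:
        log.info("single-sample window: std/autocorrelation defined as 0")
    out = {
        "mean": x.mean(axis=1),
        "max": x.max(axis=1),
        "min": x.min(axis=1),
        "std": x.std(axis=1),  # population
        "median": np.median(x, axis=1),
        "zero_crossings": _zero_crossings(x),
        "p20": np.percentile(x, 20, axis=1),
        "p50": np.percentile(x, 50, axis=1),
        "p80": np.percentile(x, 80, axis=1),
        "iqr_25_75": np.percentile(x, 75, axis=1) - np.percentile(x, 25, axis=1),
        "autocorr_lag1": _autocorr_lag1(x),
    }
    prefix = f"{channel}_" if channel else ""
    return _unwrap({prefix + k: v for k, v in out.items()}, squeeze)


def _zero_crossings(x: np.ndarray) -> np.ndarray:
    """Sign changes of the mean-centred signal; sign(0) counts as positive."""
    c = x - x.mean(axis=1, keepdims=True)
    s = np.where(c >= 0, 1, -1)
    return (np.diff(s, axis=1) != 0).sum(axis=1).astype(float)


def _autocorr_lag1(x: np.ndarray) -> np.ndarray:
    if x.shape[1] < 2:
        return np.zeros(x.shape[0])
    a, b = x[:, :-1], x[:, 1:]
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    num = (am * bm).sum(axis=1)
    den = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def spectral_features(values, channel: str | None = None,
                      rate: float | None = None) -> dict:
    """The 23 frequency/amplitude-domain features of one window (or a stack).

    Relative-extrema peaks/pits (order 3), Daubechies-4 wavelet summary
    statistics, leading inverse-FFT coefficient magnitudes of the spectrum
    envelope, excess kurtosis, spectral energy (unnormalised DFT), and
    Shannon spectral entropy of the L1-normalised one-sided power spectrum.
    """
    x, squeeze = _as2d(values)
    n, w = x.shape
    if w < 8:
        raise ConfigError("spectral features need window length >= 8")
    out: dict[str, np.ndarray] = {}

    # relative extrema
    for name, comparator in (("peak", np.greater), ("pit", np.less)):
        rows, cols = argrelextrema(x, comparator, axis=1, order=EXTREMA_ORDER)
        counts = np.bincount(rows, minlength=n).astype(float)
        sums = np.zeros(n)
        np.add.at(sums, rows, x[rows, cols])
        means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), 0.0)
        out[f"argrelextrema_number_of_{name}s"] = counts
        out[f"argrelextrema_mean_{name}_amplitude"] = means

    # discrete wavelet summary statistics
    max_level = pywt.dwt_max_level(w, WAVELET)
    level = min(MAX_DWT_LEVEL, max(1, max_level))
    if max_level < 1:
        log.info("window of %d samples below %s support: decomposition level "
                 "reduced to 1", w, WAVELET)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, WAVELET, level=level, axis=1)
    approx, details = coeffs[0], np.concatenate(coeffs[1:], axis=1)
    out["dwt_approx_mean"] = approx.mean(axis=1)
    out["dwt_approx_std"] = approx.std(axis=1)
    out["dwt_approx_energy"] = (approx**2).sum(axis=1)
    out["dwt_detail_mean"] = details.mean(axis=1)
    out["dwt_detail_std"] = details.std(axis=1)
    out["dwt_detail_energy"] = (details**2).sum(axis=1)

    # spectrum, envelope, inverse transform
    spectrum = np.fft.rfft(x, axis=1)
    envelope = np.abs(spectrum)
    inv = np.abs(np.fft.irfft(envelope, n=w, axis=1))
    for i in range(_N_IFFT):
        out[f"ifft_coef_{i}"] = inv[:, i] if i < w else np.zeros(n)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant windows
        kur = _kurtosis(x, axis=1, fisher=True, bias=True)
    out["kurtosis"] = np.nan_to_num(kur, nan=0.0)  # constant window -> 0

    power = envelope**2
    # unnormalised-DFT energy over all K coefficients (conjugate pairs doubled)
    full = 2.0 * power.sum(axis=1) - power[:, 0]
    if w % 2 == 0:
        full -= power[:, -1]
    out["spectralEnergy"] = full
    total = power.sum(axis=1, keepdims=True)
    q = np.divide(power, total, out=np.zeros_like(power), where=total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1)
    out["spectralEntropy"] = ent

    prefix = f"{channel}_" if channel else ""
    return _unwrap({prefix + k: v for k, v in out.items()}, squeeze)


def time_context_features(end_times, reference_epoch: float = EPOCH_2021) -> dict:
    """Circadian and seasonal context of the window end time.

    ``minutes_from_midnight`` in [0, 1440); ``days_from_2021`` counts whole
    calendar days since the reference epoch (2021-01-01 on the master clock).
    """
    t = np.atleast_1d(np.asarray(end_times, dtype=float))
    minutes = np.mod(t, 86400.0) / 60.0
    days = np.floor((t - reference_epoch) / 86400.0)
    out = {"minutes_from_midnight": minutes, "days_from_2021": days}
    if np.isscalar(end_times) or np.ndim(end_times) == 0:
        return {k: float(v[0]) for k, v in out.items()}
    return out


def zscore(values, mu: float, sigma: float) -> np.ndarray:
    """Standard score Gamma = (x - mu)/sigma; sigma = 0 maps to all zeros."""
    if sigma < 0:
        raise ConfigError("sigma must be non-negative")
    x = np.asarray(values, dtype=float)
    if sigma == 0:
        return np.zeros_like(x)
    return (x - mu) / sigma


# ---------------------------------------------------------------- registry

def build_registry(
    channels,
    mode: str = "followup",
    include_zscores: bool = True,
    include_consumed_food: bool = False,
) -> list[FeatureSpec]:
    """Feature registry for the given channels and study configuration.

    ``mode='main'`` adds the meal-phase marker (and optionally the
    'consumed_food' diary category); ``mode='followup'`` omits both so the
    model relies on sensor and time context alone.
    """
    if mode not in ("main", "followup"):
        raise ConfigError("mode must be 'main' or 'followup'")
    channels = list(channels)
    specs: list[FeatureSpec] = []
    sensor: list[FeatureSpec] = []
    for ch in channels:
        sub = CHANNEL_SUBCATEGORY.get(ch)
        if sub is None:
            raise ConfigError(f"unknown channel {ch!r}")
        for stat in STAT_NAMES:
            sensor.append(FeatureSpec(f"{ch}_{stat}", "sensor_data", sub, ch, "statistical"))
        for sp in SPECTRAL_NAMES:
            sensor.append(FeatureSpec(f"{ch}_{sp}", "sensor_data", sub, ch, "spectral"))
    if "STEMP" in channels and "BTEMP" in channels:
        sensor.append(FeatureSpec(
            TEMPDIFF_NAME, "sensor_data", "skin temperature", "STEMP", "statistical"))
    specs.extend(sensor)
    if include_zscores:
        for s in sensor:
            specs.append(FeatureSpec(
                _zscore_name(s.name, s.channel), s.category, s.subcategory,
                s.channel, s.extractor, is_zscore=True))
    specs.append(FeatureSpec("minutes_from_midnight", "time_domain",
                             "consumption time", extractor="time"))
    specs.append(FeatureSpec("days_from_2021", "time_domain",
                             "seasons", extractor="time"))
    specs.append(FeatureSpec("bio_age", "demographics", "biological age"))
    specs.append(FeatureSpec("bio_sex", "demographics", "biological sex"))
    specs.append(FeatureSpec("bio_bmi", "demographics",
                             "biological BMI (height and weight)"))
    if mode == "main":
        specs.append(FeatureSpec("phase_marker", "phase_marker",
                                 "meal study phase"))
        if include_consumed_food:
            specs.append(FeatureSpec("consumed_food", "phase_marker",
                                     "meal study phase"))
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate feature names in registry")
    return specs


def _zscore_name(raw_name: str, channel: str | None) -> str:
    if channel and raw_name.startswith(channel + "_"):
        return f"{channel}_zscore_{raw_name[len(channel) + 1:]}"
    return f"zscore_{raw_name}"


PHASE_CODE = {"washout": 0.0, "MMT": 1.0, "OGTT": 2.0}


def assemble_features(
    record: ParticipantRecord,
    windows: prep.WindowSet,
    specs: list[FeatureSpec] | None = None,
    mode: str = "followup",
) -> FeatureMatrix:
    """One matrix row per usable window of one participant.

    Sensor-data columns are the per-channel statistical + spectral features;
    time-context and demographics columns are broadcast; per-participant
    z-score variants are appended where the registry flags them.
    """
    if windows.usable_count == 0:
        raise ConfigError(f"no usable windows for participant {record.id}")
    if specs is None:
        specs = build_registry(sorted(windows.channels), mode=mode)
    missing = sorted(
        {s.channel for s in specs if s.category == "sensor_data"}
        - set(windows.channels)
    )
    if missing:
        raise ConfigError(f"registry references absent channels: {missing}")

    n = windows.usable_count
    cols: dict[str, np.ndarray] = {}
    for ch, arr in windows.channels.items():
        cols.update(statistical_features(arr, channel=ch))
        cols.update(spectral_features(arr, channel=ch))
    if "STEMP" in windows.channels and "BTEMP" in windows.channels:
        cols[TEMPDIFF_NAME] = (
            windows.channels["STEMP"].mean(axis=1)
            - windows.channels["BTEMP"].mean(axis=1)
        )
    cols.update(time_context_features(windows.label_times))
    cols["bio_age"] = np.full(n, float(record.demographics.age))
    cols["bio_sex"] = np.full(n, 1.0 if record.demographics.sex == "M" else 0.0)
    cols["bio_bmi"] = np.full(n, float(record.demographics.bmi))
    if mode == "main":
        labels = [record.phase_at(t) or "washout" for t in windows.label_times]
        cols["phase_marker"] = np.array([PHASE_CODE[l] for l in labels])
        cols["consumed_food"] = _consumed_food(record, windows.label_times)

    # per-participant z-score variants (population sigma over this record)
    for s in specs:
        if not s.is_zscore:
            continue
        raw = _raw_name(s)
        if raw not in cols:
            raise ConfigError(f"z-score spec {s.name!r} has no raw column {raw!r}")
        v = cols[raw]
        cols[s.name] = zscore(v, float(np.mean(v)), float(np.std(v)))

    names = [s.name for s in specs]
    missing_cols = [nm for nm in names if nm not in cols]
    if missing_cols:
        raise ConfigError(f"registry columns not computed: {missing_cols[:5]}")
    frame = pd.DataFrame(
        {
            PID_COL: np.full(n, record.id, dtype=object),
            TIME_COL: windows.label_times,
            TARGET_COL: windows.targets,
            **{nm: cols[nm] for nm in names},
        }
    )
    return FeatureMatrix(frame=frame, feature_names=names, specs=list(specs))


def _raw_name(spec: FeatureSpec) -> str:
    if spec.channel and spec.name.startswith(f"{spec.channel}_zscore_"):
        return f"{spec.channel}_{spec.name[len(spec.channel) + 8:]}"
    return spec.name.removeprefix("zscore_")


def _consumed_food(record: ParticipantRecord, times: np.ndarray) -> np.ndarray:
    """Most recent meal intervention started at or before each window end."""
    out = np.zeros(len(times))
    meals = [ph for ph in (record.phases or []) if ph.label in ("MMT", "OGTT")]
    for i, t in enumerate(times):
        past = [ph for ph in meals if ph.start <= t]
        if past:
            out[i] = PHASE_CODE[max(past, key=lambda ph: ph.start).label]
    return out


def featurize_records(
    records: list[ParticipantRecord],
    rate_hz: float = 20.0,
    p_minutes: float = 15.0,
    mode: str = "followup",
    resample_method: str = "linear",
    outlier_k: float = 4.0,
) -> FeatureMatrix:
    """End-to-end preprocessing + feature assembly for a cohort.

    Per participant: master timeline at ``rate_hz`` spanning the sensor
    recording, linear resampling of every channel, 4-sigma outlier
    replacement, prediction-horizon windowing, feature assembly; matrices
    are then concatenated across participants.
    """
    parts = []
    for rec in records:
        streams = list(rec.streams.values())
        t0 = max(s.timestamps[0] for s in streams)
        t1 = min(s.timestamps[-1] for s in streams)
        timeline = prep.MasterTimeline.spanning(t0, t1, rate_hz)
        resampled = []
        for s in streams:
            r = prep.resample_to_timeline(s, timeline, method=resample_method)
            r, _ = prep.replace_outliers(r, k=outlier_k)
            resampled.append(r)
        windows = prep.segment_windows(
            resampled, rec.glucose, p_minutes,
            stride_minutes=rec.glucose.cadence_seconds / 60.0,
        )
        if windows.usable_count == 0:
            log.warning("participant %s: no usable windows, skipped", rec.id)
            continue
        specs = build_registry(sorted(windows.channels), mode=mode)
        parts.append(assemble_features(rec, windows, specs=specs, mode=mode))
    if not parts:
        raise ConfigError("no participant produced usable windows")
    return concat_matrices(parts)
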