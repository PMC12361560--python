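"""Canonical in-memory data model shared by every pipeline stage.

All time is seconds since the UNIX epoch on a single master clock;
device-local clock conversion is the responsibility of the readers.
Glucose is mg/dL throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sensor modalities the pipeline knows about.
MODALITIES = ("STEMP", "BVP", "EDA", "HR", "BTEMP", "CTEMP", "PZT", "EGG", "EOG")

#: Channels that receive the ambient/seasonal temperature offset in simulation.
TEMPERATURE_MODALITIES = ("STEMP", "BTEMP", "CTEMP")

PHASE_LABELS = ("MMT", "OGTT", "washout")

#: Physiological clamp for simulated CGM readings, mg/dL.
GLUCOSE_RANGE = (40.0, 400.0)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ConfigError(ValueError):
    """A configuration value violates a documented invariant."""


@dataclass
class Demographics:
    """Per-participant biological covariates (kept constant per participant)."""

    age: float
    sex: str  # "F" or "M"
    height_cm: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ConfigError(f"age must be positive, got {self.age}")
        if self.sex not in ("F", "M"):
            raise ConfigError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.bmi is None:
            if self.height_cm is None or self.weight_kg is None:
                raise ConfigError("bmi or (height_cm, weight_kg) required")
            self.bmi = self.weight_kg / (self.height_cm / 100.0) ** 2
        elif self.height_cm is not None and self.weight_kg is not None:
            derived = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(derived - self.bmi) > 0.1:
                raise ConfigError(
                    f"bmi {self.bmi:.2f} inconsistent with height/weight "
                    f"(derived {derived:.2f})"
                )
        if self.bmi <= 0:
            raise ConfigError(f"bmi must be positive, got {self.bmi}")


@dataclass
class SensorStream:
    """One modality's timestamped sample sequence at its native rate."""

    modality: str
    native_rate: float  # Hz
    timestamps: np.ndarray  # seconds since epoch, strictly increasing
    values: np.ndarray  # modality units (degC, a.u., uS, bpm)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ConfigError(f"unknown modality {self.modality!r}")
        if self.native_rate <= 0:
            raise ConfigError(f"native_rate must be > 0, got {self.native_rate}")
        if self.timestamps.shape != self.values.shape:
            raise ConfigError("timestamps and values must have equal length")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ConfigError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class GlucoseTrace:
    """CGM label sequence: nominally equidistant interstitial glucose, mg/dL.

    Gaps (sensor off-body, day boundaries) are tolerated as integer multiples
    of the nominal cadence; sub-cadence jitter above 10% is rejected.
    """

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ConfigError("timestamps and values must have equal length")
        if self.timestamps.size == 0:
            raise ConfigError("glucose trace must be nonempty")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ConfigError("glucose timestamps must be strictly increasing")
        if np.any(self.values <= 0):
            raise ConfigError("glucose values must be positive (mg/dL)")
        if self.timestamps.size > 2:
            diffs = np.diff(self.timestamps)
            cadence = float(np.median(diffs))
            # each interval must sit within 10% of an integer number of cadences
            mult = np.round(diffs / cadence)
            if np.any(mult < 1) or np.any(
                np.abs(diffs - mult * cadence) > 0.1 * cadence
            ):
                raise ConfigError("glucose cadence jitter exceeds 10% of nominal")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def cadence_seconds(self) -> float:
        """Nominal inter-sample interval (median of the observed intervals)."""
        if len(self) < 2:
            raise ConfigError("cadence undefined for a single-sample trace")
        return float(np.median(np.diff(self.timestamps)))


@dataclass
class Phase:
    """A labelled study interval: meal intervention or washout."""

    start: float  # seconds since epoch
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ConfigError(f"phase label must be one of {PHASE_LABELS}")
        if self.end <= self.start:
            raise ConfigError("phase end must be after start")


@dataclass
class ParticipantRecord:
    """Everything recorded for one participant."""

    id: str
    demographics: Demographics
    streams: dict[str, SensorStream]
    glucose: GlucoseTrace
    phases: list[Phase] | None = None
    study_arm: str = "main"

    def __post_init__(self) -> None:
        if self.study_arm not in ("main", "followup"):
            raise ConfigError("study_arm must be 'main' or 'followup'")
        for name, stream in self.streams.items():
            if name != stream.modality:
                raise ConfigError(
                    f"stream keyed {name!r} carries modality {stream.modality!r}"
                )
        if self.phases:
            ordered = sorted(self.phases, key=lambda ph: ph.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ConfigError(
                        f"overlapping phases {a.label}/{b.label} for {self.id}"
                    )

    def phase_at(self, t: float) -> str | None:
        """Label of the phase containing time ``t`` (half-open [start, end))."""
        if not self.phases:
            return None
        for ph in self.phases:
            if ph.start <= t < ph.end:
                return ph.label
        return None
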