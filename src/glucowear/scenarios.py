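"""Shipped synthetic study scenarios.

These configurations define the reference conditions the test suite and the
reproduction script run under.  They mirror the two study arms structurally
— a main-study-like cohort with annotated MMT/OGTT interventions and a
follow-up-like free-living cohort at 5-min CGM cadence over ten days — at
problem sizes a single CPU handles comfortably (6-7 recorded hours/day,
4 Hz native channel rates for the wristband set).

The coupling design: every channel is confound-dominated on its own (the
glucose-independent drift carries ~3x the signal's standard deviation) but
the drift is almost entirely shared across channels within a participant, so
a multi-channel learner can cancel it.  This realises the qualitative
pattern the pipeline is built around — no single modality tracks glucose,
while combinations do.
"""

from __future__ import annotations

from .synthetic import ChannelCoupling, CouplingSpec, MealEvent, SyntheticConfig

#: the five wristband-era modalities used for prediction
IC2_CHANNELS = ("BTEMP", "BVP", "EDA", "HR", "STEMP")

_SCENARIO_RATES = {ch: 4.0 for ch in IC2_CHANNELS}


#: channel gain (channel units per mg/dL), resting baseline, confound-to-signal
#: ratio and lag.  The ratios DIFFER per channel on purpose: if every channel
#: carried the same confound-to-gain ratio, the glucose and drift directions
#: would be collinear in channel space and no combination of channels could
#: separate them.
_CHANNEL_DESIGN = {
    # name: (gain, baseline, confound_ratio, lag_min, nonlinearity)
    "STEMP": (0.04, 33.5, 3.0, 2.0, "saturating"),
    "EDA": (0.08, 6.0, 5.0, 1.0, "saturating"),
    "BVP": (0.50, 0.0, 8.0, 0.0, "linear"),
    "HR": (0.20, 70.0, 2.6, 0.0, "linear"),
    "BTEMP": (0.025, 36.8, 6.5, 3.0, "saturating"),
}

_GLUCOSE_SD = 25.0  # rough within-day glucose sd the gains are scaled against
_NOISE_FRACTION = 0.03  # white measurement noise relative to the signal sd


def _coupling(nonlinear: bool, shared_fraction: float) -> CouplingSpec:
    channels = {}
    for name, (gain, baseline, ratio, lag, nl) in _CHANNEL_DESIGN.items():
        s = gain * _GLUCOSE_SD
        channels[name] = ChannelCoupling(
            gain=gain,
            confound_sd=ratio * s,
            noise_sd=_NOISE_FRACTION * s,
            baseline=baseline,
            lag_min=lag if nonlinear else 0.0,
            nonlinearity=nl if nonlinear else "linear",
        )
    return CouplingSpec(channels=channels,
                        confound_shared_fraction=shared_fraction)


def coupled_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Follow-up-style free-living cohort: 5 participants x 10 days, 5-min CGM.

    Meal times jitter participant-day to participant-day and the circadian
    phase is drawn per participant, so glucose is not predictable from clock
    time alone across participants; the sensor coupling carries the signal.
    """
    return SyntheticConfig(
        n_participants=5,
        days_per_participant=10,
        channel_rates=dict(_SCENARIO_RATES),
        cgm_cadence_min=5.0,
        hours_per_day=6.0,
        day_start_hour=8.0,
        baseline_glucose=90.0,
        circadian_amplitude=8.0,
        randomize_circadian_phase=True,
        glucose_noise_sd=4.0,
        meal_schedule=[
            MealEvent(time=9 * 60, amplitude=55.0, rise_time=15.0,
                      decay_time=45.0, kind="free"),
            MealEvent(time=12 * 60, amplitude=70.0, rise_time=12.0,
                      decay_time=40.0, kind="free"),
        ],
        meal_time_jitter_min=45.0,
        meal_amplitude_rel_sd=0.15,
        coupling=_coupling(nonlinear=True, shared_fraction=0.97),
        missing_fraction=0.02,
        artifact_rate=0.2,
        seasonal_amplitude=3.0,
        study_arm="followup",
        seed=seed,
    )


def zero_coupling_config(seed: int = 0) -> SyntheticConfig:
    """Negative control: identical shape, all channel gains zero.

    Meal times are scattered widely and circadian phases are random per
    participant, so neither sensors nor clock time carry cross-participant
    information about glucose; any held-out skill is spurious.
    """
    cfg = coupled_cohort_config(seed)
    cfg.meal_time_jitter_min = 150.0
    cfg.coupling = CouplingSpec(
        channels={
            name: ChannelCoupling(
                gain=0.0, confound_sd=c.confound_sd, noise_sd=c.noise_sd,
                baseline=c.baseline)
            for name, c in cfg.coupling.channels.items()
        },
        confound_shared_fraction=cfg.coupling.confound_shared_fraction,
    )
    return cfg


def ablation_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Main-study-style cohort with annotated MMT/OGTT interventions.

    6 participants x 2 days, sensors 8:00-15:00, MMT at 9:00 and OGTT at
    13:00 (two-hour intervention windows with a washout between), linear
    lag-free couplings so the two-hour-segment ablation is a clean test of
    the confound-cancellation structure.
    """
    return SyntheticConfig(
        n_participants=6,
        days_per_participant=2,
        channel_rates=dict(_SCENARIO_RATES),
        cgm_cadence_min=5.0,
        hours_per_day=7.0,
        day_start_hour=8.0,
        baseline_glucose=90.0,
        circadian_amplitude=5.0,
        glucose_noise_sd=2.0,
        meal_schedule=[
            MealEvent(time=9 * 60, amplitude=60.0, rise_time=15.0,
                      decay_time=45.0, kind="MMT"),
            MealEvent(time=13 * 60, amplitude=75.0, rise_time=12.0,
                      decay_time=40.0, kind="OGTT"),
        ],
        meal_time_jitter_min=10.0,
        meal_amplitude_rel_sd=0.2,
        coupling=_coupling(nonlinear=False, shared_fraction=1.0),
        seasonal_amplitude=2.0,
        study_arm="main",
        seed=seed,
    )


def mini_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Small cohort for round-trip and determinism checks."""
    cfg = ablation_cohort_config(seed)
    cfg.n_participants = 2
    cfg.days_per_participant = 1
    cfg.hours_per_day = 3.0
    cfg.meal_schedule = [MealEvent(time=9 * 60, amplitude=60.0, kind="MMT")]
    cfg.missing_fraction = 0.01
    cfg.artifact_rate = 0.5
    return cfg
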