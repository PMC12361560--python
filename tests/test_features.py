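"""Feature extractors: worked examples, equivariances, registry contracts."""

import numpy as np
import pytest

from glucowear import ConfigError
from glucowear.features import (
    SPECTRAL_NAMES, STAT_NAMES, assemble_features, build_registry,
    spectral_features, statistical_features, time_context_features, zscore,
)
from glucowear.preprocessing import MasterTimeline, resample_to_timeline, \
    segment_windows


def test_statistical_examples():
    f = statistical_features([1.0, 2, 3, 4])
    assert f["mean"] == 2.5 and f["max"] == 4 and f["min"] == 1
    assert f["median"] == 2.5
    assert statistical_features([1.0, -1, 1, -1])["zero_crossings"] == 3
    const = statistical_features([5.0] * 12)
    assert const["std"] == 0 and const["iqr_25_75"] == 0
    assert const["autocorr_lag1"] == 0  # degenerate convention
    single = statistical_features([3.0])
    assert single["std"] == 0 and single["autocorr_lag1"] == 0


def test_spectral_energy_matches_brute_force_dft():
    f = spectral_features([1.0, 1, 1, 1, 1, 1, 1, 1])
    # oracle: full unnormalised DFT sum of squared magnitudes
    x = np.ones(8)
    brute = sum(abs(sum(x[k] * np.exp(-2j * np.pi * j * k / 8)
                        for k in range(8))) ** 2 for j in range(8))
    assert f["spectralEnergy"] == pytest.approx(brute)
    assert f["spectralEnergy"] == pytest.approx(64.0)


def test_spectral_energy_random_window_oracle(rng):
    x = rng.normal(size=16)
    f = spectral_features(x)
    X = np.fft.fft(x)
    assert f["spectralEnergy"] == pytest.approx(np.sum(np.abs(X) ** 2))


def test_spectral_degenerate_windows():
    const = spectral_features([3.0] * 16)
    assert const["spectralEntropy"] == pytest.approx(0.0, abs=1e-9)
    assert const["argrelextrema_number_of_peaks"] == 0
    mono = spectral_features(np.arange(20, dtype=float))
    assert mono["argrelextrema_number_of_peaks"] == 0
    assert mono["argrelextrema_number_of_pits"] == 0
    with pytest.raises(ConfigError):
        spectral_features([1.0, 2, 3])  # below the 8-sample minimum


def test_time_context_examples():
    epoch_2021 = 1609459200.0
    assert time_context_features(epoch_2021) == {
        "minutes_from_midnight": 0.0, "days_from_2021": 0.0}
    jan2_0630 = epoch_2021 + 86400 + 6 * 3600 + 30 * 60
    f = time_context_features(jan2_0630)
    assert f["minutes_from_midnight"] == 390.0 and f["days_from_2021"] == 1.0
    last_minute = epoch_2021 + 86400 * 10 + 23 * 3600 + 59 * 60
    assert time_context_features(last_minute)["minutes_from_midnight"] == 1439.0


def test_zscore_examples():
    assert zscore([2.0], 2.0, 0.5)[0] == 0.0
    vals = np.array([1.0, 2.0, 3.0])
    mu, sd = vals.mean(), vals.std()
    assert zscore(vals, mu, sd)[2] == pytest.approx(1.2247, abs=1e-4)
    assert np.array_equal(zscore(vals, 2.0, 0.0), np.zeros(3))


def test_scaling_equivariances(rng):
    """Positive scaling: location/scale stats scale, counts and entropy do not,
    spectral energy scales quadratically."""
    x = rng.normal(size=(100, 64))
    c = 3.7
    s1, s2 = statistical_features(x), statistical_features(c * x)
    for name in ("mean", "max", "min", "std", "median", "p20", "p50", "p80",
                 "iqr_25_75"):
        assert np.allclose(s2[name], c * s1[name])
    assert np.array_equal(s2["zero_crossings"], s1["zero_crossings"])
    assert np.allclose(s2["autocorr_lag1"], s1["autocorr_lag1"])
    f1, f2 = spectral_features(x), spectral_features(c * x)
    assert np.array_equal(f2["argrelextrema_number_of_peaks"],
                          f1["argrelextrema_number_of_peaks"])
    assert np.allclose(f2["spectralEntropy"], f1["spectralEntropy"])
    assert np.allclose(f2["spectralEnergy"], c**2 * f1["spectralEnergy"])


def test_features_finite_on_degenerate_windows(rng):
    windows = np.vstack([
        np.zeros(32),
        np.full(32, 9.9),
        np.arange(32, dtype=float),
        np.r_[np.zeros(31), 1e6],  # spike
        rng.normal(size=32),
    ])
    for d in (statistical_features(windows), spectral_features(windows)):
        for name, v in d.items():
            assert np.all(np.isfinite(v)), name


def test_registry_contains_published_feature_names():
    specs = build_registry(["BTEMP", "BVP", "EDA", "HR", "STEMP"],
                           mode="followup")
    names = {s.name for s in specs}
    for required in ("minutes_from_midnight", "days_from_2021", "bio_age",
                     "EDA_zscore_spectralEnergy", "BTEMP_spectralEntropy",
                     "BVP_argrelextrema_number_of_peaks"):
        assert required in names
    # registry size follows from its configuration
    sensor_raw = 5 * (len(STAT_NAMES) + len(SPECTRAL_NAMES)) + 1  # + tempdiff
    assert len(specs) == 2 * sensor_raw + 2 + 3


def test_registry_modes_and_subcategories():
    main = build_registry(["EDA"], mode="main", include_consumed_food=True)
    names = {s.name for s in main}
    assert "phase_marker" in names and "consumed_food" in names
    follow = build_registry(["EDA"], mode="followup")
    assert "phase_marker" not in {s.name for s in follow}
    subs = {s.subcategory for s in main}
    assert {"electrodermal activity", "consumption time", "seasons",
            "meal study phase"} <= subs


def _windows_for(record, rate=4.0, p=15.0):
    streams = list(record.streams.values())
    t0 = max(s.timestamps[0] for s in streams)
    t1 = min(s.timestamps[-1] for s in streams)
    tl = MasterTimeline.spanning(t0, t1, rate)
    resampled = [resample_to_timeline(s, tl) for s in streams]
    return segment_windows(resampled, record.glucose, p,
                           stride_minutes=record.glucose.cadence_seconds / 60)


def test_assemble_features_contract(mini_records):
    rec = mini_records[0]
    ws = _windows_for(rec)
    specs = build_registry(sorted(ws.channels), mode="main")
    m = assemble_features(rec, ws, specs=specs, mode="main")
    assert len(m) == ws.usable_count
    assert m.feature_names == [s.name for s in specs]
    # demographics constant within participant
    assert m.frame["bio_age"].nunique() == 1
    # per-participant z-scored columns: population mean 0, sd 1 (or all-zero)
    for name in m.zscored_names():
        col = m.frame[name].to_numpy()
        if col.std() > 0:
            assert abs(col.mean()) < 1e-9
            assert abs(col.std() - 1.0) < 1e-9
    # phase marker reflects the MMT annotation for some windows
    assert set(np.unique(m.frame["phase_marker"])) <= {0.0, 1.0, 2.0}


def test_assemble_features_missing_channel_error(mini_records):
    rec = mini_records[0]
    ws = _windows_for(rec)
    ws.channels.pop("EDA")
    specs = build_registry(["BTEMP", "BVP", "EDA", "HR", "STEMP"])
    with pytest.raises(ConfigError, match="EDA"):
        assemble_features(rec, ws, specs=specs)
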