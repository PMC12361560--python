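"""Interpolation schemes, outlier replacement and horizon windowing."""

import numpy as np
import pytest

from glucowear import ConfigError, GlucoseTrace
from glucowear.preprocessing import (
    MasterTimeline, compute_body_temperature, densify_glucose, interpolate,
    replace_outliers, resample_to_timeline, segment_windows,
)

from conftest import make_stream


# ---------------------------------------------------------- interpolation

def test_linear_interpolation_example():
    assert interpolate([(0, 2), (4, 6)], [1.0], "linear")[0] == pytest.approx(3.0)


def test_nearest_interpolation_with_earlier_node_tie():
    pts = [(0, 1), (10, 9)]
    assert interpolate(pts, [4.0], "nearest")[0] == 1.0
    assert interpolate(pts, [6.0], "nearest")[0] == 9.0
    assert interpolate(pts, [5.0], "nearest")[0] == 1.0  # tie -> earlier node


def test_lagrange_reproduces_quadratic():
    pts = [(x, x**2) for x in range(6)]
    assert interpolate(pts, [2.5], "lagrange")[0] == pytest.approx(6.25)


def test_interpolation_errors():
    with pytest.raises(ConfigError):
        interpolate([(0, 1), (0, 2), (1, 3)], [0.5], "linear")  # duplicate x
    with pytest.raises(ConfigError):
        interpolate([(0, 1), (1, 2)], [1.5], "linear")  # no extrapolation
    with pytest.raises(ConfigError):
        interpolate([(0, 1)], [0.0], "linear")  # single node


def test_linear_reproduces_affine_functions(rng):
    for _ in range(50):
        x = np.sort(rng.uniform(0, 10, rng.integers(2, 12)))
        x = x[np.concatenate([[True], np.diff(x) > 1e-3])]
        if x.size < 2:
            continue
        a, b = rng.normal(size=2)
        q = rng.uniform(x[0], x[-1], 20)
        out = interpolate(np.column_stack([x, a * x + b]), q, "linear")
        assert np.allclose(out, a * q + b, rtol=1e-10, atol=1e-10)


def test_nearest_outputs_subset_of_inputs(rng):
    x = np.sort(rng.uniform(0, 10, 15))
    y = rng.normal(size=15)
    out = interpolate(np.column_stack([x, y]), rng.uniform(x[0], x[-1], 40),
                      "nearest")
    assert set(np.round(out, 12)) <= set(np.round(y, 12))


def test_lagrange_reproduces_degree5_polynomials_piecewise(rng):
    """An order-5 interpolant is exact for any polynomial of degree <= 5,
    regardless of which sliding 6-node neighbourhood evaluates the query."""
    for _ in range(25):
        x = np.cumsum(rng.uniform(0.3, 1.0, 12))
        coef = rng.normal(size=6)
        y = np.polyval(coef, x)
        q = rng.uniform(x[0], x[-1], 30)
        out = interpolate(np.column_stack([x, y]), q, "lagrange")
        assert np.allclose(out, np.polyval(coef, q), rtol=1e-9, atol=1e-9)


def test_lagrange_passes_through_nodes(rng):
    x = np.cumsum(rng.uniform(0.5, 1.0, 10))
    y = rng.normal(size=10)
    out = interpolate(np.column_stack([x, y]), x, "lagrange")
    assert np.allclose(out, y, rtol=1e-9, atol=1e-12)


# ------------------------------------------------------------- resampling

def test_resample_constant_and_ramp():
    tl = MasterTimeline.spanning(1_600_000_000.0, 1_600_000_002.0, 20.0)
    const = make_stream(np.full(9, 7.0), rate=4.0)
    out = resample_to_timeline(const, tl)
    assert np.allclose(out.values, 7.0)
    assert len(out) == 41  # timeline points inside the stream span
    ramp = make_stream(np.arange(9, dtype=float), rate=4.0)
    out = resample_to_timeline(ramp, tl)
    expect = (out.timestamps - ramp.timestamps[0]) * 4.0
    assert np.allclose(out.values, expect)  # linear reproduces affine signals


def test_densify_glucose_to_one_per_minute():
    t = np.arange(0, 3600.0 + 1, 300.0) + 1_600_000_000.0
    g = GlucoseTrace(timestamps=t, values=100 + 20 * np.sin(t / 900.0))
    dense = densify_glucose(g, step_seconds=60.0)
    assert len(dense) == 61
    assert np.allclose(dense.values[::5], g.values, rtol=1e-3)


# ------------------------------------------------------- body temperature

def test_body_temperature_weighting():
    ct = make_stream([37.0, 37.0], modality="CTEMP")
    st = make_stream([33.0, 33.0], modality="STEMP")
    bt = compute_body_temperature(ct, st, alpha=0.67)
    assert bt.modality == "BTEMP"
    assert np.allclose(bt.values, 35.68)
    same = compute_body_temperature(make_stream([36.0], modality="CTEMP"),
                                    make_stream([36.0], modality="STEMP"),
                                    alpha=0.3)
    assert np.allclose(same.values, 36.0)
    only_core = compute_body_temperature(ct, st, alpha=1.0)
    assert np.allclose(only_core.values, ct.values)
    with pytest.raises(ConfigError):
        compute_body_temperature(ct, make_stream([33.0], modality="STEMP"))


# ----------------------------------------------------------- outliers

def test_outliers_constant_stream_unchanged():
    s = make_stream(np.full(10, 5.0))
    out, rep = replace_outliers(s)
    assert rep.n_flagged == 0 and np.array_equal(out.values, s.values)


def test_four_sigma_is_deliberately_conservative():
    # [0,0,0,0,100]: mu=20, population sigma=40, bounds [-140, 180] -> no flags
    s = make_stream([0.0, 0.0, 0.0, 0.0, 100.0])
    out, rep = replace_outliers(s, k=4.0)
    assert rep.mean == pytest.approx(20.0)
    assert rep.std == pytest.approx(40.0)
    assert rep.n_flagged == 0


def test_outlier_postcondition_against_brute_force(rng):
    for _ in range(30):
        v = rng.normal(0, 1, 200)
        v[rng.integers(0, 200, 3)] += rng.choice([-1, 1], 3) * 10.0
        s = make_stream(v)
        out, rep = replace_outliers(s, k=4.0)
        mu, sd = v.mean(), v.std()
        brute = np.nonzero(np.abs(v - mu) > 4.0 * sd)[0]
        assert np.array_equal(rep.flagged_indices, brute)
        # no value in the output violates the ORIGINAL bounds
        assert not np.any((out.values > mu + 4 * sd) | (out.values < mu - 4 * sd))
        assert np.allclose(out.values[brute], mu)


# ----------------------------------------------------------- windowing

def _window_fixture(n_minutes=70, rate=4.0, start=1_600_000_000.0):
    n = int(n_minutes * 60 * rate) + 1
    return make_stream(np.sin(np.arange(n) / 50.0), rate=rate, t0=start)


def test_window_count_formula():
    s = _window_fixture()
    labels = GlucoseTrace(
        timestamps=s.timestamps[0] + np.arange(5) * 900.0,
        values=np.full(5, 100.0))
    ws = segment_windows([s], labels, p_minutes=15.0)
    assert ws.formula_count == 5  # 60/15 + 1
    assert ws.usable_count == 4  # the first label has no preceding 15 min
    assert ws.dropped_count == 1
    assert ws.channels["EDA"].shape == (4, int(15 * 60 * 4))


def test_window_count_formula_five_minute_horizon():
    s = _window_fixture()
    labels = GlucoseTrace(
        timestamps=s.timestamps[0] + np.arange(13) * 300.0,
        values=np.full(13, 100.0))
    ws = segment_windows([s], labels, p_minutes=5.0)
    assert ws.formula_count == 13  # 60/5 + 1


def test_window_halving_law():
    """Halving p on an equidistant label grid maps |J| -> 2|J| - 1."""
    s = _window_fixture()
    t0 = s.timestamps[0]
    for p, expected in [(15.0, 5), (7.5, 9)]:
        labels = GlucoseTrace(
            timestamps=t0 + np.arange(0, 3601, p * 60.0),
            values=np.full(int(60 / p) + 1, 100.0))
        ws = segment_windows([s], labels, p_minutes=p)
        assert ws.formula_count == expected


def test_window_targets_and_alignment():
    s = _window_fixture()
    t0 = s.timestamps[0]
    labels = GlucoseTrace(timestamps=t0 + np.arange(5) * 900.0,
                          values=np.array([90.0, 95, 100, 105, 110]))
    ws = segment_windows([s], labels, p_minutes=15.0)
    assert np.array_equal(ws.targets, [95.0, 100, 105, 110])
    # each window ends exactly at its label: last sample equals the stream there
    for i in range(ws.usable_count):
        k = int(round((ws.label_times[i] - t0) * 4.0))
        assert ws.channels["EDA"][i, -1] == s.values[k]


def test_window_stride_below_horizon():
    """Follow-up design: 5-min label cadence with a 15-min horizon."""
    s = _window_fixture()
    t0 = s.timestamps[0]
    labels = GlucoseTrace(timestamps=t0 + np.arange(13) * 300.0,
                          values=np.full(13, 100.0))
    ws = segment_windows([s], labels, p_minutes=15.0, stride_minutes=5.0)
    assert ws.formula_count == 13
    assert ws.usable_count == 10  # first three labels lack 15-min history
    assert ws.usable_count <= ws.formula_count


def test_window_errors():
    s = _window_fixture()
    labels = GlucoseTrace(timestamps=s.timestamps[0] + np.arange(5) * 900.0,
                          values=np.full(5, 100.0))
    with pytest.raises(ConfigError):
        segment_windows([s], labels, p_minutes=0.13)  # not a step multiple
    with pytest.raises(ConfigError):
        segment_windows([], labels, p_minutes=15.0)
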