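"""Signal alignment and windowing ahead of feature extraction.

Heterogeneous device streams are resampled onto one master timeline with
fixed, equidistant steps (default 20 Hz); the interpolation schemes offered
are first-order (linear), nearest-neighbour, and piecewise Lagrange of order
five over sliding 6-node neighbourhoods.  Outliers beyond ``k`` standard
deviations of a stream's own mean are replaced by the mean, and sensor data
is cut into prediction-horizon windows that END at each glucose label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import ConfigError, GlucoseTrace, SensorStream

log = logging.getLogger(__name__)

#: interior gaps longer than this are still bridged by interpolation but logged
GAP_LIMIT_SECONDS = 5.0

INTERPOLATION_METHODS = ("linear", "nearest", "lagrange")

#: node count of the sliding Lagrange neighbourhood (order five)
_LAGRANGE_NODES = 6


@dataclass
class MasterTimeline:
    """Equidistant reference grid: points are ``t0 + k*step`` for k < n_points."""

    t0: float
    step: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigError(f"timeline step must be > 0, got {self.step}")
        if self.n_points < 0:
            raise ConfigError("n_points must be non-negative")

    @classmethod
    def spanning(cls, t_start: float, t_end: float, rate: float) -> "MasterTimeline":
        """Grid at ``rate`` Hz covering [t_start, t_end]."""
        if rate <= 0:
            raise ConfigError(f"rate must be > 0, got {rate}")
        step = 1.0 / rate
        n = int(np.floor((t_end - t_start) / step + 1e-9)) + 1
        return cls(t0=t_start, step=step, n_points=max(n, 0))

    @property
    def rate(self) -> float:
        return 1.0 / self.step

    def points(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(self.n_points)


@dataclass
class OutlierReport:
    """Bookkeeping for the k-sigma outlier replacement of one stream."""

    modality: str
    mean: float
    std: float  # population standard deviation of the original values
    k: float
    flagged_indices: np.ndarray
    replacement_value: float

    @property
    def n_flagged(self) -> int:
        return int(np.size(self.flagged_indices))


@dataclass
class Window:
    """One usable prediction-horizon window ending at a glucose label."""

    label_time: float
    target: float  # mg/dL at label_time
    channels: dict[str, np.ndarray]


@dataclass
class WindowSet:
    """Per-label windows of length p across resampled channels.

    ``channels`` holds one (n_usable, samples_per_window) array per modality,
    row-aligned with ``label_times`` and ``targets``.
    """

    p_minutes: float
    label_times: np.ndarray
    targets: np.ndarray
    channels: dict[str, np.ndarray]
    formula_count: int
    usable_count: int
    dropped_count: int
    samples_per_window: int

    def __len__(self) -> int:
        return self.usable_count

    def window(self, i: int) -> Window:
        return Window(
            label_time=float(self.label_times[i]),
            target=float(self.targets[i]),
            channels={m: a[i] for m, a in self.channels.items()},
        )


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        arr = np.column_stack([np.asarray(p, dtype=float) for p in zip(*points)])
    x, y = arr[:, 0], arr[:, 1]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size < 2:
        raise ConfigError("interpolation needs at least 2 points")
    if np.any(np.diff(x) == 0):
        raise ConfigError("duplicate x values in interpolation nodes")
    return x, y


def interpolate(points, queries, method: str = "linear") -> np.ndarray:
    """Interpolate ``queries`` from ``points`` (pairs of (x, y)).

    ``linear``   first-order polynomial between the bracketing pair.
    ``nearest``  value of the closest node; an equidistant tie takes the
                 earlier node.
    ``lagrange`` order-five Lagrange polynomial over the sliding 6-node
                 neighbourhood around each query, falling back to the largest
                 available order when fewer nodes exist.

    Queries outside [min x, max x] raise; there is no extrapolation.
    """
    if method not in INTERPOLATION_METHODS:
        raise ConfigError(f"method must be one of {INTERPOLATION_METHODS}")
    x, y = _as_points(points)
    q = np.atleast_1d(np.asarray(queries, dtype=float))
    if q.size and (q.min() < x[0] or q.max() > x[-1]):
        raise ConfigError(
            f"query outside node range [{x[0]}, {x[-1]}]; no extrapolation"
        )

    if method == "linear":
        return np.interp(q, x, y)

    if method == "nearest":
        right = np.searchsorted(x, q)
        right = np.clip(right, 1, x.size - 1)
        left = right - 1
        # tie (equidistant) goes to the earlier node
        take_left = (q - x[left]) <= (x[right] - q)
        return np.where(take_left, y[left], y[right])

    # lagrange: sliding 6-node neighbourhoods, evaluated with the
    # numerically stable barycentric form of the same polynomial
    n_nodes = min(_LAGRANGE_NODES, x.size)
    out = np.empty_like(q)
    # bracketing interval index of each query
    idx = np.clip(np.searchsorted(x, q, side="right") - 1, 0, x.size - 2)
    # neighbourhood start so the query sits mid-window
    start = np.clip(idx - (n_nodes // 2 - 1), 0, x.size - n_nodes)
    for s in np.unique(start):
        sel = start == s
        xs = x[s : s + n_nodes]
        ys = y[s : s + n_nodes]
        out[sel] = _barycentric(xs, ys, q[sel])
    return out


def _barycentric(xs: np.ndarray, ys: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Evaluate the Lagrange interpolant through (xs, ys) at q."""
    w = np.ones_like(xs)
    for j in range(xs.size):
        diff = xs[j] - np.delete(xs, j)
        w[j] = 1.0 / np.prod(diff)
    d = q[:, None] - xs[None, :]
    exact = d == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = w[None, :] / d
        num = (terms * ys[None, :]).sum(axis=1)
        den = terms.sum(axis=1)
        res = num / den
    hit_rows = exact.any(axis=1)
    if hit_rows.any():
        res[hit_rows] = ys[exact.argmax(axis=1)[hit_rows]]
    return res


def resample_to_timeline(
    stream: SensorStream, timeline: MasterTimeline, method: str = "linear"
) -> SensorStream:
    """Sample ``stream`` exactly at timeline points inside the stream's span."""
    if len(stream) == 0:
        raise ConfigError(f"cannot resample empty stream {stream.modality}")
    pts = timeline.points()
    inside = (pts >= stream.timestamps[0]) & (pts <= stream.timestamps[-1])
    q = pts[inside]
    if len(stream) == 1:
        vals = np.full(q.shape, stream.values[0])
    else:
        gaps = np.diff(stream.timestamps)
        n_gaps = int(np.sum(gaps > GAP_LIMIT_SECONDS))
        if n_gaps:
            log.info(
                "%s: bridging %d interior gap(s) > %.0f s by %s interpolation",
                stream.modality, n_gaps, GAP_LIMIT_SECONDS, method,
            )
        vals = interpolate(
            np.column_stack([stream.timestamps, stream.values]), q, method=method
        )
    return SensorStream(
        modality=stream.modality,
        native_rate=timeline.rate,
        timestamps=q,
        values=vals,
    )


def densify_glucose(
    glucose: GlucoseTrace, step_seconds: float = 60.0, method: str = "lagrange"
) -> GlucoseTrace:
    """Dense glucose curve (default 1 value per minute) via Lagrange order 5."""
    t0, t1 = glucose.timestamps[0], glucose.timestamps[-1]
    n = int(np.floor((t1 - t0) / step_seconds + 1e-6)) + 1
    q = t0 + step_seconds * np.arange(n)
    vals = interpolate(
        np.column_stack([glucose.timestamps, glucose.values]), q, method=method
    )
    return GlucoseTrace(timestamps=q, values=np.clip(vals, 1e-6, None))


def compute_body_temperature(
    ctemp: SensorStream, stemp: SensorStream, alpha: float = 0.67
) -> SensorStream:
    """Weighted body temperature: alpha*CTEMP + (1 - alpha)*STEMP, pointwise."""
    if len(ctemp) != len(stemp) or not np.allclose(
        ctemp.timestamps, stemp.timestamps
    ):
        raise ConfigError("CTEMP and STEMP must share a common timeline")
    return SensorStream(
        modality="BTEMP",
        native_rate=ctemp.native_rate,
        timestamps=ctemp.timestamps.copy(),
        values=alpha * ctemp.values + (1.0 - alpha) * stemp.values,
    )


def replace_outliers(
    stream: SensorStream, k: float = 4.0
) -> tuple[SensorStream, OutlierReport]:
    """Replace samples beyond ``k`` population standard deviations by the mean.

    Statistics are computed once on the original values; replacement is a
    single pass (no re-flagging after replacement).  A zero-variance stream
    is returned unchanged with an empty flag set.
    """
    if len(stream) == 0:
        raise ConfigError("cannot de-outlier an empty stream")
    mu = float(np.mean(stream.values))
    sigma = float(np.std(stream.values))  # population (divisor n)
    if sigma == 0.0:
        flagged = np.array([], dtype=int)
    else:
        flagged = np.nonzero(
            (stream.values > mu + k * sigma) | (stream.values < mu - k * sigma)
        )[0]
    cleaned = stream.values.copy()
    cleaned[flagged] = mu
    report = OutlierReport(
        modality=stream.modality,
        mean=mu,
        std=sigma,
        k=k,
        flagged_indices=flagged,
        replacement_value=mu,
    )
    if report.n_flagged:
        log.info("%s: replaced %d outlier(s) beyond %.0f sigma",
                 stream.modality, report.n_flagged, k)
    out = SensorStream(
        modality=stream.modality,
        native_rate=stream.native_rate,
        timestamps=stream.timestamps.copy(),
        values=cleaned,
    )
    return out, report


def segment_windows(
    streams: list[SensorStream] | dict[str, SensorStream],
    glucose: GlucoseTrace,
    p_minutes: float,
    stride_minutes: float | None = None,
) -> WindowSet:
    """Cut per-label windows spanning the p minutes BEFORE each glucose value.

    Windows are half-open ``(t - p, t]`` so consecutive windows are disjoint
    when the label cadence equals p.  Labels whose preceding span is not fully
    covered by every channel are dropped (not padded) and counted.

    ``stride_minutes`` is the nominal label spacing used for the window-count
    bookkeeping; it defaults to ``p_minutes`` (the design where cadence = p),
    in which case ``formula_count = span/p + 1``.
    """
    if isinstance(streams, dict):
        streams = list(streams.values())
    if not streams:
        raise ConfigError("segment_windows needs at least one stream")
    if p_minutes <= 0:
        raise ConfigError("prediction horizon p must be positive")
    stride = p_minutes if stride_minutes is None else stride_minutes

    ref = streams[0]
    if len(ref) < 2:
        raise ConfigError("streams too short to window")
    step = float(ref.timestamps[1] - ref.timestamps[0])
    for s in streams:
        if len(s) < 2:
            raise ConfigError(f"stream {s.modality} too short to window")
        if not np.allclose(np.diff(s.timestamps), step, rtol=0, atol=step * 1e-6):
            raise ConfigError(
                f"stream {s.modality} is not on an equidistant master timeline"
            )
    p_sec = p_minutes * 60.0
    w = p_sec / step
    if abs(w - round(w)) > 1e-6:
        raise ConfigError(
            f"p = {p_minutes} min is not a positive multiple of the timeline "
            f"step ({step} s)"
        )
    w = int(round(w))

    span = float(glucose.timestamps[-1] - glucose.timestamps[0])
    formula_count = int(round(span / (stride * 60.0))) + 1

    starts = np.array([s.timestamps[0] for s in streams])
    ends = np.array([s.timestamps[-1] for s in streams])
    t_lo, t_hi = starts.max(), ends.min()

    label_times, targets, rows = [], [], {s.modality: [] for s in streams}
    dropped = 0
    for t, g in zip(glucose.timestamps, glucose.values):
        ok = True
        idx = {}
        for s in streams:
            k_end = int(round((t - s.timestamps[0]) / step))
            aligned = abs(s.timestamps[0] + k_end * step - t) <= step * 1e-6
            if not aligned or k_end - w + 1 < 0 or k_end >= len(s):
                ok = False
                break
            idx[s.modality] = (k_end - w + 1, k_end + 1)
        if not ok or t - p_sec < t_lo - step * 1e-6 or t > t_hi + step * 1e-6:
            dropped += 1
            continue
        label_times.append(t)
        targets.append(g)
        for s in streams:
            a, b = idx[s.modality]
            rows[s.modality].append(s.values[a:b])

    channels = {
        m: (np.vstack(v) if v else np.empty((0, w))) for m, v in rows.items()
    }
    if dropped:
        log.info("windowing: dropped %d label(s) without full %g-min coverage",
                 dropped, p_minutes)
    return WindowSet(
        p_minutes=p_minutes,
        label_times=np.asarray(label_times),
        targets=np.asarray(targets),
        channels=channels,
        formula_count=formula_count,
        usable_count=len(label_times),
        dropped_count=dropped,
        samples_per_window=w,
    )
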