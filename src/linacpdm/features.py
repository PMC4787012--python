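"""Daily feature extraction: trajectory + text logs -> 525 parameter values.

The QA delivery is designed so that fixed snapshot windows challenge each
axis: the gantry speed is measured over two sectors of maximal speed, each
MLC leaf speed over its two maximum-speed gap displacements, and positional
fidelity is scored by cross-correlating each day's gantry/leaf trace against
a stored reference trace over a designed baseline window.  Jaw and carriage
positions are read as the average over a designed-static window, which is
robust to the 20 ms sampling noise.

Default windows (snapshot indices, 0-based, start-inclusive/end-exclusive
duration arithmetic):

* gantry speed segments 10-760 and 4120-4250, CC baseline 2525-3350;
* MLC speed segments 1780-1830 and 4115-4165, CC baseline 2450-3200;
* cross-correlation lag window +/-50 snapshots.

Cross-correlation is normalized per lag (zero-mean, unit-norm), so the max
value is a unitless fidelity score in [-1, 1] and the max location is the
signed lag (in snapshots) at which the day's trace best matches the
reference; positive lag means the day's motion is delayed relative to the
reference.  Ties are broken toward the lag of smallest absolute value.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from . import _defaults as d
from .errors import DegenerateTraceError, ExtractionError, ValidationError
from .logio import TextSnapshot, TrajectoryLog
from .registry import ParameterRegistry

# Default window indices at full scale (delivery of 4500 snapshots at 20 ms).
GANTRY_SPEED_SEGMENT_1 = (10, 760)
GANTRY_SPEED_SEGMENT_2 = (4120, 4250)
GANTRY_CC_SEGMENT = (2525, 3350)
MLC_SPEED_SEGMENT_1 = (1780, 1830)
MLC_SPEED_SEGMENT_2 = (4115, 4165)
MLC_CC_SEGMENT = (2450, 3200)
DEFAULT_LAG_WINDOW = 50
DEFAULT_DURATION = 4500


@dataclass(frozen=True)
class SegmentSpec:
    """A half-open snapshot window [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid segment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CCResult:
    """Cross-correlation fidelity: (max normalized correlation, arg-max lag)."""

    max_value: float
    max_location: int


@dataclass(frozen=True)
class ReferenceTrace:
    """Baseline positional trace of one axis over its CC segment."""

    axis: str
    positions: np.ndarray
    segment: SegmentSpec

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.shape != (len(self.segment),):
            raise ValidationError(
                f"reference trace for {self.axis}: length {pos.size} != "
                f"segment length {len(self.segment)}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"reference trace for {self.axis} must be finite")


@dataclass(frozen=True)
class FeatureConfig:
    """Per-axis extraction windows.

    ``speed_segments`` maps each speed-monitored axis to its two segments,
    ``cc_segments`` each CC-monitored axis to its baseline window, and
    ``position_segments`` each static axis to the window over which its
    position is averaged.
    """

    speed_segments: dict[str, tuple[SegmentSpec, SegmentSpec]]
    cc_segments: dict[str, SegmentSpec]
    position_segments: dict[str, SegmentSpec]
    lag_window: int = DEFAULT_LAG_WINDOW

    def __post_init__(self) -> None:
        if self.lag_window < 0:
            raise ValidationError("lag_window must be >= 0")


def default_feature_config(scale: int = 1) -> FeatureConfig:
    """The default windows, optionally compressed by an integer factor.

    ``scale > 1`` divides every snapshot index (and the lag window) by
    ``scale`` — used with a delivery plan built at the same scale to keep
    tests and demonstrations fast while preserving the geometry.
    """
    if scale < 1:
        raise ValidationError("scale must be >= 1")

    def seg(pair: tuple[int, int]) -> SegmentSpec:
        return SegmentSpec(pair[0] // scale, pair[1] // scale)

    speed: dict[str, tuple[SegmentSpec, SegmentSpec]] = {
        d.GANTRY_AXIS: (seg(GANTRY_SPEED_SEGMENT_1), seg(GANTRY_SPEED_SEGMENT_2)),
    }
    cc: dict[str, SegmentSpec] = {d.GANTRY_AXIS: seg(GANTRY_CC_SEGMENT)}
    for axis in d.MLC_AXES:
        speed[axis] = (seg(MLC_SPEED_SEGMENT_1), seg(MLC_SPEED_SEGMENT_2))
        cc[axis] = seg(MLC_CC_SEGMENT)
    position = {axis: seg(GANTRY_CC_SEGMENT)
                for axis in d.JAW_AXES + d.CARRIAGE_AXES}
    return FeatureConfig(
        speed_segments=speed,
        cc_segments=cc,
        position_segments=position,
        lag_window=max(1, DEFAULT_LAG_WINDOW // scale),
    )


@dataclass(frozen=True)
class DailySample:
    """One day's vector of extracted parameter values.

    ``provenance`` records, per parameter, whether the value came straight
    from the text log or from which trajectory axis.
    """

    machine_id: str
    date: _dt.date
    values: dict[str, float]
    provenance: dict[str, str]


# ---------------------------------------------------------------------------
# primitive operations


def segment_velocity(trace: np.ndarray, segment: SegmentSpec,
                     sample_interval_ms: float) -> float:
    """Average axis velocity over a window: positional change over time.

    ``(trace[end] - trace[start]) / ((end - start) * interval)`` in units/s;
    the sign of the motion is preserved.
    """
    trace = np.asarray(trace, dtype=float)
    if segment.end >= trace.size:
        raise ValidationError(
            f"segment [{segment.start}, {segment.end}) out of range for "
            f"trace of {trace.size} snapshots"
        )
    dt_s = sample_interval_ms / 1000.0
    return float(
        (trace[segment.end] - trace[segment.start]) / (len(segment) * dt_s)
    )


def cross_correlate(trace: np.ndarray, reference: ReferenceTrace,
                    lag_window: int = DEFAULT_LAG_WINDOW) -> CCResult:
    """Normalized cross-correlation of a day's trace against the reference.

    For each lag in ``[-lag_window, +lag_window]`` the window
    ``trace[start+lag : end+lag]`` is compared with the reference positions
    by zero-mean, unit-norm (Pearson) correlation.  Returns the maximum and
    its lag; ties go to the smallest ``|lag|`` (and the negative lag on an
    exact +/- tie).  Positive lag = trace delayed relative to the reference.
    """
    trace = np.asarray(trace, dtype=float)
    seg = reference.segment
    if seg.start - lag_window < 0 or seg.end + lag_window > trace.size:
        raise ValidationError(
            f"trace of {trace.size} snapshots cannot cover segment "
            f"[{seg.start}, {seg.end}) at every lag in +/-{lag_window}"
        )
    ref = reference.positions - reference.positions.mean()
    ref_norm = float(np.sqrt(np.sum(ref * ref)))
    if ref_norm == 0.0:
        raise DegenerateTraceError(
            f"reference trace for axis {reference.axis!r} has zero variance"
        )

    span = trace[seg.start - lag_window: seg.end + lag_window]
    if np.ptp(span) == 0.0:
        raise DegenerateTraceError(
            f"trace for axis {reference.axis!r} has zero variance over the "
            "lag-extended correlation window"
        )

    best_value = -np.inf
    best_lag = 0
    # lags ordered by |lag| (negative first on magnitude ties) with strict
    # improvement => documented tie-break.
    lags = sorted(range(-lag_window, lag_window + 1), key=lambda l: (abs(l), l))
    n = len(seg)
    for lag in lags:
        w = trace[seg.start + lag: seg.end + lag]
        w = w - w.mean()
        w_norm = float(np.sqrt(np.sum(w * w)))
        if w_norm == 0.0:
            continue  # constant window at this lag: correlation undefined
        r = float(np.dot(w, ref)) / (w_norm * ref_norm)
        if r > best_value:
            best_value = r
            best_lag = lag
    if not np.isfinite(best_value):
        raise DegenerateTraceError(
            f"trace for axis {reference.axis!r} is constant at every lag"
        )
    return CCResult(max_value=best_value, max_location=best_lag)


def build_reference_traces(tlog: TrajectoryLog,
                           config: FeatureConfig) -> dict[str, ReferenceTrace]:
    """Reference traces for every CC-monitored axis, cut from one delivery.

    The default monitoring strategy takes the first in-control baseline day
    as the motion reference.
    """
    refs: dict[str, ReferenceTrace] = {}
    for axis, seg in config.cc_segments.items():
        trace = tlog.trace(axis)
        if seg.end > trace.size:
            raise ValidationError(
                f"CC segment for {axis} exceeds log length {trace.size}"
            )
        refs[axis] = ReferenceTrace(axis=axis,
                                    positions=trace[seg.start:seg.end].copy(),
                                    segment=seg)
    return refs


# ---------------------------------------------------------------------------
# daily extraction


def extract_daily_sample(tlog: TrajectoryLog, ttxt: TextSnapshot,
                         registry: ParameterRegistry,
                         refs: dict[str, ReferenceTrace],
                         config: FeatureConfig) -> DailySample:
    """Populate every registry parameter from one day's log pair."""
    if tlog.machine_id != ttxt.machine_id:
        raise ExtractionError(
            f"machine mismatch: trajectory {tlog.machine_id!r} vs "
            f"text {ttxt.machine_id!r}"
        )
    if tlog.date != ttxt.date:
        raise ExtractionError(
            f"date mismatch: trajectory {tlog.date} vs text {ttxt.date}"
        )

    missing: list[str] = []
    recorded = set(tlog.axis_names)
    for p in registry:
        if p.source == "text" and p.id not in ttxt.values:
            missing.append(p.id)
        elif p.source == "trajectory":
            if p.axis not in recorded:
                missing.append(p.id)
            elif p.metric.startswith("cc_") and p.axis not in refs:
                missing.append(p.id)
    if missing:
        raise ExtractionError("cannot populate daily sample", missing)

    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    cc_cache: dict[str, CCResult] = {}

    for p in registry:
        if p.source == "text":
            values[p.id] = float(ttxt.values[p.id])
            provenance[p.id] = "text"
            continue
        provenance[p.id] = f"trajectory:{p.axis}"
        trace = tlog.trace(p.axis)
        if p.metric == "position":
            seg = config.position_segments[p.axis]
            values[p.id] = float(trace[seg.start:seg.end].mean())
        elif p.metric in ("speed_segment_1", "speed_segment_2"):
            seg = config.speed_segments[p.axis][0 if p.metric.endswith("1") else 1]
            values[p.id] = segment_velocity(trace, seg, tlog.sample_interval_ms)
        else:
            cc = cc_cache.get(p.axis)
            if cc is None:
                cc = cross_correlate(trace, refs[p.axis], config.lag_window)
                cc_cache[p.axis] = cc
            values[p.id] = (cc.max_value if p.metric == "cc_max_value"
                            else float(cc.max_location))

    return DailySample(machine_id=tlog.machine_id, date=tlog.date,
                       values=values, provenance=provenance)
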