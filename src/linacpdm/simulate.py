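"""Synthetic daily-QA delivery, machine noise and fault injection.

The generator emulates a robust VMAT QA delivery designed to stress the
interplay of gantry and MLC motion: the gantry sweeps through maximal-speed
sectors with acceleration/deceleration ramps, while every MLC leaf performs
delayed maximum-speed gap displacements that end in an abrupt halt.  The
default plan spans 4500 snapshots at 20 ms (90 s) and places its motion so
that the default feature-extraction windows (see :mod:`linacpdm.features`)
fall on the designed events:

* gantry: 4 deg/s over both speed segments; a nominally constant 1 deg/s
  sector covers the CC baseline window, with a brief 0.4 deg/s dose-rate
  notch (snapshots 2700-2900) inside it so that the cross-correlation lag is
  identifiable (a strictly linear trace correlates equally at every lag);
* each MLC leaf: static gap, +2.5 cm/s displacement over speed segment 1,
  a triangular excursion inside the CC baseline window, and a -2.5 cm/s
  return displacement over speed segment 2;
* jaws, carriages and couch axes hold static setpoints.

Machine noise is independent per-snapshot Gaussian positional noise per axis
plus Gaussian noise (and optional linear drift) on each text-log value.  All
randomness is seeded and reproducible per (seed, day, axis), which lets the
fault injector regenerate a single axis bit-identically.

Fault injection reproduces the published synthetic-error study: sustained
shifts/scalings of text values, constant positional offsets, speed changes
realized by re-timing the planned trace (a ramp over the speed segment) and
positional-timing faults realized by delaying the trace a whole number of
snapshots (edge-value hold).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import _defaults as d
from . import features as ft
from .errors import ValidationError
from .logio import TextSnapshot, TrajectoryLog
from .registry import ParameterRegistry, sp_value

DT_S = 0.020  # 20 ms sampling interval


# ---------------------------------------------------------------------------
# delivery plan


@dataclass(frozen=True)
class DeliveryPlan:
    """Noise-free axis trajectories of the QA delivery."""

    duration_snapshots: int
    traces: dict[str, np.ndarray]
    axis_names: tuple[str, ...] = d.RECORDED_AXES
    sample_interval_ms: float = 20.0
    scale: int = 1

    def trace(self, axis: str) -> np.ndarray:
        return self.traces[axis]


def _piecewise_speed_trace(sectors: Sequence[tuple[int, int, float, float]],
                           duration: int, start_position: float) -> np.ndarray:
    """Integrate a piecewise-linear speed profile into positions.

    ``sectors`` are (start, end, v_start, v_end) with instantaneous speed
    changes allowed at sector boundaries; speed is linearly interpolated
    inside each sector.  Left-endpoint integration is used, so over any
    window inside a constant sector the positional change is exactly
    v * dt * (window length) — an abrupt halt does not bleed into the next
    snapshot.
    """
    v = np.zeros(duration)
    for start, end, v0, v1 in sectors:
        n = end - start
        v[start:end] = v0 if v0 == v1 else np.linspace(v0, v1, n, endpoint=False)
    pos = np.empty(duration)
    pos[0] = start_position
    np.cumsum(v[:-1] * DT_S, out=pos[1:])
    pos[1:] += start_position
    return pos


def _gantry_sectors(s: int) -> list[tuple[int, int, float, float]]:
    """Gantry speed sectors at scale divisor ``s`` (indices // s)."""
    base = [
        (0, 780, 4.0, 4.0),       # max-speed sector covering speed segment 1
        (780, 1000, 4.0, 1.0),    # deceleration ramp
        (1000, 2700, 1.0, 1.0),
        (2700, 2900, 0.4, 0.4),   # dose-rate notch inside the CC window
        (2900, 3450, 1.0, 1.0),
        (3450, 4100, 1.0, 4.0),   # acceleration ramp
        (4100, 4270, 4.0, 4.0),   # max-speed sector covering speed segment 2
        (4270, 4500, 4.0, 0.0),   # deceleration to rest
    ]
    return [(a // s, b // s, v0, v1) for a, b, v0, v1 in base]


def _leaf_profile(s: int, duration: int) -> np.ndarray:
    """Relative leaf motion: two max-speed displacements + CC-window triangle."""
    sectors = [
        (0, 1780 // s, 0.0, 0.0),
        (1780 // s, 1830 // s, 2.5, 2.5),      # gap displacement, max speed
        (1830 // s, 2450 // s, 0.0, 0.0),
        (2450 // s, 2800 // s, 0.5, 0.5),      # triangular excursion out
        (2800 // s, 3200 // s, -0.4375, -0.4375),  # ... and back
        (3200 // s, 4115 // s, 0.0, 0.0),
        (4115 // s, 4165 // s, -2.5, -2.5),    # return displacement
        (4165 // s, duration, 0.0, 0.0),
    ]
    return _piecewise_speed_trace(sectors, duration, 0.0)


_JAW_SETPOINTS = {"jaw_x1": -5.0, "jaw_x2": 5.0, "jaw_y1": -5.5, "jaw_y2": 5.5}
_CARRIAGE_SETPOINTS = {"carriage_a": -1.0, "carriage_b": 1.0}
_COUCH_SETPOINTS = {"couch_vrt": 8.0, "couch_lng": 95.0, "couch_lat": 0.5,
                    "couch_rtn": 0.0}
_MLC_BANK_BASE = {"a": -2.0, "b": 2.0}


def default_delivery_plan(scale: int = 1) -> DeliveryPlan:
    """The default Snooker-Cue-style plan; ``scale`` compresses time.

    Use together with ``features.default_feature_config(scale)``: every
    extraction window at the same scale lands on its designed motion event.
    """
    if scale < 1:
        raise ValidationError("scale must be >= 1")
    duration = ft.DEFAULT_DURATION // scale
    traces: dict[str, np.ndarray] = {}
    traces[d.GANTRY_AXIS] = _piecewise_speed_trace(
        _gantry_sectors(scale), duration, -179.0)
    for axis, setpoint in {**_JAW_SETPOINTS, **_CARRIAGE_SETPOINTS,
                           **_COUCH_SETPOINTS}.items():
        traces[axis] = np.full(duration, setpoint)
    profile = _leaf_profile(scale, duration)
    for axis in d.MLC_AXES:
        bank = axis[4]  # 'a' or 'b'
        leaf = int(axis[-2:])
        base = _MLC_BANK_BASE[bank] + 0.05 * ((leaf - 1) % 4)
        traces[axis] = base + profile
    return DeliveryPlan(duration_snapshots=duration, traces=traces, scale=scale)


# ---------------------------------------------------------------------------
# machine model


@dataclass(frozen=True)
class TextParamModel:
    nominal: float
    sigma: float
    drift_per_day: float = 0.0


@dataclass(frozen=True)
class MachineModel:
    """Per-axis positional noise and per-text-value nominal/noise/drift."""

    axis_sigma: dict[str, float]
    text_params: dict[str, TextParamModel]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.axis_sigma.values()):
            raise ValidationError("axis noise sigma must be >= 0")
        if any(p.sigma < 0 for p in self.text_params.values()):
            raise ValidationError("text noise sigma must be >= 0")

    def with_drift(self, parameter_id: str, drift_per_day: float) -> "MachineModel":
        params = dict(self.text_params)
        params[parameter_id] = replace(params[parameter_id],
                                       drift_per_day=drift_per_day)
        return MachineModel(axis_sigma=self.axis_sigma, text_params=params)


def default_machine_model(noiseless: bool = False) -> MachineModel:
    """Default synthetic machine.

    Axis noise: 0.05 deg (gantry), 0.02 cm (MLC/jaws/carriages), couch held.
    Text noise: per-parameter sigmas from the defaults table — pinned to the
    published one-standard-deviation values where the fault study specifies
    the deviation as 1 STD.
    """
    axis_sigma: dict[str, float] = {d.GANTRY_AXIS: d.AXIS_SIGMA_GANTRY_DEG}
    for axis in d.JAW_AXES:
        axis_sigma[axis] = d.AXIS_SIGMA_JAW_CM
    for axis in d.CARRIAGE_AXES:
        axis_sigma[axis] = d.AXIS_SIGMA_CARRIAGE_CM
    for axis in d.MLC_AXES:
        axis_sigma[axis] = d.AXIS_SIGMA_MLC_CM
    for axis in d.COUCH_AXES:
        axis_sigma[axis] = d.AXIS_SIGMA_COUCH
    text: dict[str, TextParamModel] = {}
    for row in d.TEXT_PARAMETERS:
        pid, nominal, sigma = row[0], row[4], row[5]
        text[pid] = TextParamModel(nominal=nominal, sigma=sigma)
    for pid, _name, _units, nominal, sigma in d.TEXT_EXTRAS:
        text[pid] = TextParamModel(nominal=nominal, sigma=sigma)
    if noiseless:
        axis_sigma = {a: 0.0 for a in axis_sigma}
        text = {k: replace(v, sigma=0.0) for k, v in text.items()}
    return MachineModel(axis_sigma=axis_sigma, text_params=text)


# ---------------------------------------------------------------------------
# seeded generation


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def day_seed(seed: int, day_index: int) -> np.random.SeedSequence:
    """Deterministic per-day seed stream."""
    return np.random.SeedSequence([int(seed), int(day_index)])


def _axis_children(seed, n_axes: int) -> list[np.random.SeedSequence]:
    return _seedseq(seed).spawn(n_axes + 1)  # last child feeds the text log


def axis_noise(seed, axis_index: int, n_axes: int, n: int,
               sigma: float) -> np.ndarray:
    """Regenerate the noise of one axis exactly as simulate_trajectory drew it."""
    if sigma == 0.0:
        return np.zeros(n)
    child = _axis_children(seed, n_axes)[axis_index]
    return np.random.default_rng(child).normal(0.0, sigma, n)


def simulate_trajectory(plan: DeliveryPlan, machine: MachineModel,
                        machine_id: str, date: _dt.date, seed) -> TrajectoryLog:
    """One day's trajectory log: plan positions + Gaussian axis noise.

    The same seed always yields an identical log; with all sigmas zero the
    log equals the plan exactly.
    """
    children = _axis_children(seed, len(plan.axis_names))
    n = plan.duration_snapshots
    snapshots = np.empty((n, len(plan.axis_names)))
    for i, axis in enumerate(plan.axis_names):
        trace = plan.trace(axis)
        sigma = machine.axis_sigma.get(axis, 0.0)
        if sigma > 0.0:
            noise = np.random.default_rng(children[i]).normal(0.0, sigma, n)
            snapshots[:, i] = trace + noise
        else:
            snapshots[:, i] = trace
    return TrajectoryLog(machine_id=machine_id, date=date,
                         axis_names=plan.axis_names, snapshots=snapshots,
                         sample_interval_ms=plan.sample_interval_ms)


def simulate_text_snapshot(machine: MachineModel, machine_id: str,
                           date: _dt.date, seed,
                           day_index: int = 0) -> TextSnapshot:
    """One day's text snapshot: nominal + drift*day + Gaussian noise (45 values)."""
    children = _axis_children(seed, len(d.RECORDED_AXES))
    rng = np.random.default_rng(children[-1])
    values: dict[str, float] = {}
    for pid, model in machine.text_params.items():
        noise = rng.normal(0.0, model.sigma) if model.sigma > 0 else 0.0
        values[pid] = model.nominal + model.drift_per_day * day_index + noise
    return TextSnapshot(machine_id=machine_id, date=date, values=values)


# ---------------------------------------------------------------------------
# fault injection


ErrorMode = Literal["add_shift", "time_shift_snapshots", "scale"]


@dataclass(frozen=True)
class ErrorSpec:
    """One synthetic deviation.

    ``target`` is a parameter id or an axis key.  ``add_shift`` on an axis is
    a constant positional offset; on a speed parameter it is realized by
    re-timing the trace (a ramp of slope ``magnitude`` across the speed
    segment, held afterwards); on a text parameter it shifts the value.
    ``time_shift_snapshots`` delays an axis trace by ``magnitude`` whole
    snapshots with edge-value hold.  ``scale`` multiplies.
    """

    target: str
    mode: ErrorMode
    magnitude: float
    onset_day: int | None = None
    sustained: bool = True

    def __post_init__(self) -> None:
        if self.mode == "time_shift_snapshots" and self.magnitude != int(self.magnitude):
            raise ValidationError("time shift must be a whole number of snapshots")


def _shift_trace(trace: np.ndarray, snapshots: int) -> np.ndarray:
    """Delay (positive) or advance (negative) a trace with edge-value hold."""
    m = int(snapshots)
    if m == 0:
        return trace.copy()
    out = np.empty_like(trace)
    if m > 0:
        out[m:] = trace[:-m]
        out[:m] = trace[0]
    else:
        out[:m] = trace[-m:]
        out[m:] = trace[-1]
    return out


def _ramp_over_segment(n: int, segment: ft.SegmentSpec, slope: float,
                       dt_s: float) -> np.ndarray:
    """Additive re-timing profile: 0 before the segment, linear ramp of the
    given slope (units/s) across it, constant hold after."""
    t = np.arange(n, dtype=float)
    elapsed = np.clip(t - segment.start, 0.0, len(segment)) * dt_s
    return slope * elapsed


def _resolve_trajectory_target(target: str, registry: ParameterRegistry,
                               config: ft.FeatureConfig):
    """(axis, segments-to-ramp-or-None) for a trajectory-level target."""
    if target in registry:
        p = registry[target]
        if p.source != "trajectory":
            raise ValidationError(f"{target!r} is not a trajectory target")
        if p.metric == "speed_segment_1":
            return p.axis, (config.speed_segments[p.axis][0],)
        if p.metric == "speed_segment_2":
            return p.axis, (config.speed_segments[p.axis][1],)
        return p.axis, None
    return target, None  # bare axis key


def inject_error(obj, spec: ErrorSpec, *,
                 registry: ParameterRegistry | None = None,
                 config: ft.FeatureConfig | None = None):
    """Apply one deviation to a value, a text snapshot or a trajectory log.

    Returns a modified copy; the input is never mutated.  An injection only
    touches its target axis/value — any effect on extracted parameters is
    the mathematical coupling of the metrics on that axis.
    """
    if isinstance(obj, (int, float)):
        if spec.mode == "add_shift":
            return float(obj) + spec.magnitude
        if spec.mode == "scale":
            return float(obj) * spec.magnitude
        raise ValidationError("time shifts apply to trajectory axes only")

    if isinstance(obj, TextSnapshot):
        if spec.target not in obj.values:
            raise ValidationError(f"unknown text value {spec.target!r}")
        values = dict(obj.values)
        values[spec.target] = inject_error(values[spec.target], spec)
        return TextSnapshot(machine_id=obj.machine_id, date=obj.date,
                            values=values)

    if isinstance(obj, TrajectoryLog):
        if registry is None or config is None:
            # bare-axis targets only
            axis, segments = spec.target, None
        else:
            axis, segments = _resolve_trajectory_target(spec.target, registry,
                                                        config)
        if axis not in obj.axis_names:
            raise ValidationError(f"unknown axis {axis!r}")
        snapshots = obj.snapshots.copy()
        col = obj.axis_index(axis)
        trace = snapshots[:, col]
        dt_s = obj.sample_interval_ms / 1000.0
        if spec.mode == "time_shift_snapshots":
            snapshots[:, col] = _shift_trace(trace, int(spec.magnitude))
        elif spec.mode == "scale":
            snapshots[:, col] = trace * spec.magnitude
        elif segments is not None:  # add_shift on a speed parameter
            for seg in segments:
                trace = trace + _ramp_over_segment(trace.size, seg,
                                                   spec.magnitude, dt_s)
            snapshots[:, col] = trace
        else:  # add_shift on the axis: constant positional offset
            snapshots[:, col] = trace + spec.magnitude
        return TrajectoryLog(machine_id=obj.machine_id, date=obj.date,
                             axis_names=obj.axis_names, snapshots=snapshots,
                             sample_interval_ms=obj.sample_interval_ms)

    raise ValidationError(f"cannot inject into {type(obj).__name__}")


# ---------------------------------------------------------------------------
# the fault-injection suite


@dataclass(frozen=True)
class Scenario:
    """One study scenario: a named group of simultaneous ErrorSpecs plus the
    parameters whose charts are watched for the detection verdict."""

    name: str
    parameter_label: str
    error_description: str
    error_level: float
    specs: tuple[ErrorSpec, ...]
    related_parameters: tuple[str, ...]
    is_control: bool = False


@dataclass(frozen=True)
class InjectionSuite:
    scenarios: tuple[Scenario, ...]

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def subset(self, names: Sequence[str]) -> "InjectionSuite":
        wanted = set(names)
        return InjectionSuite(tuple(s for s in self.scenarios if s.name in wanted))


def default_error_suite(registry: ParameterRegistry,
                        per_bank: bool = False) -> InjectionSuite:
    """The default 45-scenario synthetic-deviation suite.

    35 text scenarios (two of them zero-magnitude negative controls), the
    four jaws and two carriages at +0.2 cm, a +0.2 deg/s gantry speed change,
    a 10-snapshot gantry trace delay, a +0.1 cm/s leaf speed change and a
    2-snapshot leaf trace delay (the MLC scenarios act on every leaf of both
    banks).  ``per_bank=True`` splits each MLC scenario into one per bank
    (47 scenarios), matching a per-bank reading of the published table.
    """
    scenarios: list[Scenario] = []

    for (pid, name, _units, _group, _nom, _sig, _b, _r, _f,
         emode, elevel, edesc) in d.TEXT_PARAMETERS:
        scenarios.append(Scenario(
            name=f"text:{pid}",
            parameter_label=name,
            error_description=edesc,
            error_level=elevel,
            specs=(ErrorSpec(target=pid, mode=emode, magnitude=elevel),),  # type: ignore[arg-type]
            related_parameters=(pid,),
            is_control=(emode == "add_shift" and elevel == 0.0),
        ))

    for axis in ("jaw_y1", "jaw_y2", "jaw_x1", "jaw_x2"):
        scenarios.append(Scenario(
            name=f"axis:{axis}",
            parameter_label=axis.split("_")[1].upper(),
            error_description="Add 0.2 cm",
            error_level=d.JAW_SHIFT_CM,
            specs=(ErrorSpec(target=axis, mode="add_shift",
                             magnitude=d.JAW_SHIFT_CM),),
            related_parameters=(f"{axis}/position",),
        ))
    for axis in d.CARRIAGE_AXES:
        scenarios.append(Scenario(
            name=f"axis:{axis}",
            parameter_label=f"Carriage {axis[-1].upper()}",
            error_description="Add 0.2 cm",
            error_level=d.CARRIAGE_SHIFT_CM,
            specs=(ErrorSpec(target=axis, mode="add_shift",
                             magnitude=d.CARRIAGE_SHIFT_CM),),
            related_parameters=(f"{axis}/position",),
        ))

    scenarios.append(Scenario(
        name="gantry:speed",
        parameter_label="Gantry - Speed 1, Speed 2",
        error_description="Add 0.2 deg/sec",
        error_level=d.GANTRY_SPEED_SHIFT,
        specs=(
            ErrorSpec(target="gantry/speed_segment_1", mode="add_shift",
                      magnitude=d.GANTRY_SPEED_SHIFT),
            ErrorSpec(target="gantry/speed_segment_2", mode="add_shift",
                      magnitude=d.GANTRY_SPEED_SHIFT),
        ),
        related_parameters=("gantry/speed_segment_1", "gantry/speed_segment_2"),
    ))
    scenarios.append(Scenario(
        name="gantry:cc_shift",
        parameter_label="Gantry - cross-correlation max value and location",
        error_description="Shift 10 snapshots",
        error_level=float(d.GANTRY_TRACE_SHIFT),
        specs=(ErrorSpec(target=d.GANTRY_AXIS, mode="time_shift_snapshots",
                         magnitude=d.GANTRY_TRACE_SHIFT),),
        related_parameters=("gantry/cc_max_value", "gantry/cc_max_location"),
    ))

    def mlc_scenarios(axes: tuple[str, ...], bank_label: str) -> list[Scenario]:
        speed_specs = tuple(
            ErrorSpec(target=f"{axis}/{metric}", mode="add_shift",
                      magnitude=d.MLC_SPEED_SHIFT)
            for axis in axes
            for metric in ("speed_segment_1", "speed_segment_2")
        )
        speed_related = tuple(
            f"{axis}/{metric}" for axis in axes
            for metric in ("speed_segment_1", "speed_segment_2")
        )
        shift_specs = tuple(
            ErrorSpec(target=axis, mode="time_shift_snapshots",
                      magnitude=d.MLC_TRACE_SHIFT)
            for axis in axes
        )
        cc_related = tuple(
            f"{axis}/{metric}" for axis in axes
            for metric in ("cc_max_value", "cc_max_location")
        )
        return [
            Scenario(
                name=f"mlc:{bank_label}:speed",
                parameter_label=f"MLC {bank_label} - each leaf: Speed 1, Speed 2",
                error_description="Add 0.1 cm/sec",
                error_level=d.MLC_SPEED_SHIFT,
                specs=speed_specs,
                related_parameters=speed_related,
            ),
            Scenario(
                name=f"mlc:{bank_label}:cc_shift",
                parameter_label=f"MLC {bank_label} - each leaf: cross-correlation",
                error_description="Shift 2 snapshots",
                error_level=float(d.MLC_TRACE_SHIFT),
                specs=shift_specs,
                related_parameters=cc_related,
            ),
        ]

    if per_bank:
        scenarios += mlc_scenarios(d.MLC_AXES_A, "Bank A")
        scenarios += mlc_scenarios(d.MLC_AXES_B, "Bank B")
    else:
        scenarios += mlc_scenarios(d.MLC_AXES, "Banks A+B")

    return InjectionSuite(scenarios=tuple(scenarios))


# ---------------------------------------------------------------------------
# detection study


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    parameter_label: str
    error_description: str
    error_level: float
    is_control: bool
    detected_i: bool
    detected_mr: bool
    first_signal_day: int | None      # monitored-day index of first limit hit
    detected_alarm_rule: bool         # windowed 2-of-3 / 3-of-5 alarm fired
    first_alarm_day: int | None


@dataclass(frozen=True)
class DetectionTable:
    """Study results, one row per scenario, mirroring the published layout."""

    results: tuple[ScenarioResult, ...]
    n_baseline_days: int
    n_monitor_days: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {
                "scenario": r.scenario,
                "parameter": r.parameter_label,
                "error_description": r.error_description,
                "error_level": r.error_level,
                "control": r.is_control,
                "detected_i": r.detected_i,
                "detected_mr": r.detected_mr,
                "detected": r.detected_i or r.detected_mr,
                "first_signal_day": r.first_signal_day,
                "detected_alarm_rule": r.detected_alarm_rule,
                "first_alarm_day": r.first_alarm_day,
            }
            for r in self.results
        ])

    def detection_rate(self) -> float:
        """Fraction of non-control scenarios with any I or MR limit hit."""
        errors = [r for r in self.results if not r.is_control]
        if not errors:
            return float("nan")
        hits = sum(1 for r in errors if r.detected_i or r.detected_mr)
        return hits / len(errors)


def _extract_axis_features(trace: np.ndarray, axis: str,
                           registry: ParameterRegistry,
                           config: ft.FeatureConfig,
                           refs: dict[str, ft.ReferenceTrace],
                           interval_ms: float,
                           wanted: set[str] | None = None) -> dict[str, float]:
    """Extract only the parameters derived from one axis trace."""
    out: dict[str, float] = {}
    cc: ft.CCResult | None = None
    for p in registry.by_axis(axis):
        if wanted is not None and p.id not in wanted:
            continue
        if p.metric == "position":
            seg = config.position_segments[axis]
            out[p.id] = float(trace[seg.start:seg.end].mean())
        elif p.metric in ("speed_segment_1", "speed_segment_2"):
            seg = config.speed_segments[axis][0 if p.metric.endswith("1") else 1]
            out[p.id] = ft.segment_velocity(trace, seg, interval_ms)
        else:
            if cc is None:
                cc = ft.cross_correlate(trace, refs[axis], config.lag_window)
            out[p.id] = cc.max_value if p.metric == "cc_max_value" else float(cc.max_location)
    return out


def run_detection_study(suite: InjectionSuite, *,
                        registry: ParameterRegistry,
                        plan: DeliveryPlan | None = None,
                        machine: MachineModel | None = None,
                        config: ft.FeatureConfig | None = None,
                        n_baseline_days: int = 20,
                        n_monitor_days: int = 30,
                        seed: int = 0,
                        machine_id: str = "SIM01") -> DetectionTable:
    """Re-enact the synthetic-deviation study.

    For each scenario: simulate ``n_baseline_days`` in-control days, build
    the related parameters' charts on that baseline, then monitor
    ``n_monitor_days`` further days with the deviation injected from its
    onset day (default: the first monitored day, sustained).  A scenario is
    *detected* when any related parameter posts a single point beyond the
    hybrid I-chart limits (detected_i) and/or above the MR-chart UCL
    (detected_mr); the windowed alarm-rule verdict is recorded alongside.

    Fully seeded: identical seeds yield identical tables.  The in-control
    days are simulated once and shared across scenarios; injected axes are
    regenerated from the same per-(day, axis) noise stream, so an injection
    differs from the in-control day by exactly the injected deviation.
    """
    from .spc import ControlChart

    plan = plan if plan is not None else default_delivery_plan()
    machine = machine if machine is not None else default_machine_model()
    config = config if config is not None else ft.default_feature_config(plan.scale)
    if n_baseline_days < 2:
        raise ValidationError("n_baseline_days must be >= 2")

    n_days = n_baseline_days + n_monitor_days
    start = _dt.date(2026, 1, 5)
    dates = [start + _dt.timedelta(days=i) for i in range(n_days)]

    # --- shared in-control history ---------------------------------------
    refs: dict[str, ft.ReferenceTrace] = {}
    values: dict[str, np.ndarray] = {p.id: np.empty(n_days) for p in registry}
    for day in range(n_days):
        ss = day_seed(seed, day)
        tlog = simulate_trajectory(plan, machine, machine_id, dates[day], ss)
        ttxt = simulate_text_snapshot(machine, machine_id, dates[day], ss,
                                      day_index=day)
        if day == 0:
            refs = ft.build_reference_traces(tlog, config)
        sample = ft.extract_daily_sample(tlog, ttxt, registry, refs, config)
        for pid, v in sample.values.items():
            values[pid][day] = v

    axis_order = {a: i for i, a in enumerate(plan.axis_names)}
    n_axes = len(plan.axis_names)
    interval = plan.sample_interval_ms

    results: list[ScenarioResult] = []
    for scenario in suite:
        onset = n_baseline_days
        if scenario.specs and scenario.specs[0].onset_day is not None:
            onset = n_baseline_days + scenario.specs[0].onset_day

        # injected values for related parameters, starting from in-control
        injected = {pid: values[pid].copy() for pid in scenario.related_parameters}

        text_specs = [s for s in scenario.specs if s.target in registry
                      and registry[s.target].source == "text"]
        traj_specs = [s for s in scenario.specs if s not in text_specs]

        for s in text_specs:
            days = range(onset, n_days) if s.sustained else range(onset, onset + 1)
            for day in days:
                injected[s.target][day] = inject_error(values[s.target][day], s)

        if traj_specs:
            # group specs per axis, then regenerate each affected axis/day
            by_axis: dict[str, list[ErrorSpec]] = {}
            for s in traj_specs:
                axis, _ = _resolve_trajectory_target(s.target, registry, config)
                by_axis.setdefault(axis, []).append(s)
            days = (range(onset, n_days) if all(s.sustained for s in traj_specs)
                    else range(onset, onset + 1))
            for day in days:
                ss = day_seed(seed, day)
                children = _axis_children(ss, n_axes)
                for axis, specs in by_axis.items():
                    sigma = machine.axis_sigma.get(axis, 0.0)
                    idx = axis_order[axis]
                    if sigma > 0.0:
                        noise = np.random.default_rng(children[idx]).normal(
                            0.0, sigma, plan.duration_snapshots)
                        trace = plan.trace(axis) + noise
                    else:
                        trace = plan.trace(axis).copy()
                    dt_s = interval / 1000.0
                    for s in specs:
                        _, segments = _resolve_trajectory_target(s.target,
                                                                 registry, config)
                        if s.mode == "time_shift_snapshots":
                            trace = _shift_trace(trace, int(s.magnitude))
                        elif s.mode == "scale":
                            trace = trace * s.magnitude
                        elif segments is not None:
                            for seg in segments:
                                trace = trace + _ramp_over_segment(
                                    trace.size, seg, s.magnitude, dt_s)
                        else:
                            trace = trace + s.magnitude
                    extracted = _extract_axis_features(
                        trace, axis, registry, config, refs, interval,
                        wanted=set(scenario.related_parameters))
                    for pid, v in extracted.items():
                        injected[pid][day] = v

        # --- chart the related parameters and look for signals -----------
        detected_i = False
        detected_mr = False
        first_signal: int | None = None
        detected_rule = False
        first_alarm: int | None = None
        for pid in scenario.related_parameters:
            sp = sp_value(registry[pid].sp_rule)
            chart = ControlChart(pid, sp, T=n_baseline_days)
            series = injected[pid]
            for day in range(n_days):
                point = chart.add_point(float(series[day]), dates[day])
                if day < n_baseline_days or chart.i_limits is None:
                    continue
                monitor_day = day - n_baseline_days
                lim, mrl = chart.i_limits, chart.mr_chart_limits
                i_hit = (not lim.degenerate
                         and (point.value >= lim.ucl or point.value <= lim.lcl))
                mr_hit = (point.moving_range is not None and mrl.sigma3 > 0
                          and point.moving_range >= mrl.ucl)
                if i_hit:
                    detected_i = True
                if mr_hit:
                    detected_mr = True
                if (i_hit or mr_hit) and (first_signal is None
                                          or monitor_day < first_signal):
                    first_signal = monitor_day
                if point.i_alarm_event or point.mr_alarm_event:
                    detected_rule = True
                    if first_alarm is None or monitor_day < first_alarm:
                        first_alarm = monitor_day

        results.append(ScenarioResult(
            scenario=scenario.name,
            parameter_label=scenario.parameter_label,
            error_description=scenario.error_description,
            error_level=scenario.error_level,
            is_control=scenario.is_control,
            detected_i=detected_i,
            detected_mr=detected_mr,
            first_signal_day=first_signal,
            detected_alarm_rule=detected_rule,
            first_alarm_day=first_alarm,
        ))

    return DetectionTable(results=tuple(results),
                          n_baseline_days=n_baseline_days,
                          n_monitor_days=n_monitor_days, seed=seed)
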