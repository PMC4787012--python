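"""Daily ingest pipeline, status rollup and static reporting.

One :class:`MachineState` per accelerator holds the registry, the extraction
configuration, every ingested daily sample and a hybrid I/MR chart per
parameter.  Re-ingesting a date replaces that day's sample (charts are
replayed from the stored history, so the operation is idempotent).  The
non-graphical equivalent of a monitoring dashboard is provided by
:func:`status_report` (per-group red/orange/green rollup, hot list, current
counts over the last ten monitored days) and :func:`render_report` (a static
plain-text/HTML document with per-parameter chart tables, a frequency
distribution of the individuals, a statistical summary and user comments).

State persists as one directory per machine: a registry config, a JSON state
file (samples, comments, rebaseline events, ingest log) and the reference
traces in the trajectory-log dialect.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import features as ft
from .errors import ValidationError
from .logio import (TrajectoryLog, read_text_log, read_trajectory_log,
                    write_trajectory_log)
from .registry import ParameterRegistry, build_default_registry, sp_value
from .spc import (DEFAULT_BASELINE_SIZE, ControlChart, RuleConfig,
                  DEFAULT_RULES, Status, combine_status)

GROUP_COLORS = {"alarm": "red", "warning": "orange", "normal": "green"}


@dataclass
class MachineState:
    """Everything known about one monitored accelerator."""

    machine_id: str
    registry: ParameterRegistry
    config: ft.FeatureConfig
    T: int = DEFAULT_BASELINE_SIZE
    rules: RuleConfig = field(default_factory=lambda: DEFAULT_RULES)
    samples: dict[_dt.date, ft.DailySample] = field(default_factory=dict)
    refs: dict[str, ft.ReferenceTrace] = field(default_factory=dict)
    reference_log: TrajectoryLog | None = None
    comments: dict[str, list[tuple[_dt.date, str]]] = field(default_factory=dict)
    # (parameter_id, date at which the rebaseline was applied, n)
    rebaseline_events: list[tuple[str, _dt.date, int]] = field(default_factory=list)
    charts: dict[str, ControlChart] = field(default_factory=dict)

    @property
    def last_ingest_date(self) -> _dt.date | None:
        return max(self.samples) if self.samples else None

    def chart(self, parameter_id: str) -> ControlChart:
        if parameter_id not in self.charts:
            raise KeyError(f"unknown parameter id {parameter_id!r}")
        return self.charts[parameter_id]


def new_machine_state(machine_id: str,
                      registry: ParameterRegistry | None = None,
                      config: ft.FeatureConfig | None = None,
                      T: int = DEFAULT_BASELINE_SIZE,
                      rules: RuleConfig = DEFAULT_RULES) -> MachineState:
    registry = registry if registry is not None else build_default_registry()
    config = config if config is not None else ft.default_feature_config()
    state = MachineState(machine_id=machine_id, registry=registry,
                         config=config, T=T, rules=rules)
    _rebuild_charts(state)
    return state


def _rebuild_charts(state: MachineState) -> None:
    """Replay the stored history into fresh charts (pure function of state)."""
    events_by_date: dict[tuple[str, _dt.date], int] = {
        (pid, date): n for pid, date, n in state.rebaseline_events
    }
    charts = {
        p.id: ControlChart(p.id, sp_value(p.sp_rule), T=state.T,
                           rules=state.rules)
        for p in state.registry
    }
    for date in sorted(state.samples):
        sample = state.samples[date]
        for pid, chart in charts.items():
            chart.add_point(sample.values[pid], date)
            n = events_by_date.get((pid, date))
            if n is not None:
                chart.rebaseline(n)
    state.charts = charts


def ingest_day(state: MachineState, tlog_path: str | Path,
               ttxt_path: str | Path) -> MachineState:
    """Ingest one day's log pair: parse, extract, update all charts.

    Validates machine identity before touching state; on any failure the
    state is left unchanged.  Re-ingesting an already-seen date replaces
    that day's sample.  The first ingested day's trajectory becomes the
    cross-correlation reference.
    """
    tlog = read_trajectory_log(tlog_path)
    ttxt = read_text_log(ttxt_path)
    if tlog.machine_id != state.machine_id or ttxt.machine_id != state.machine_id:
        raise ValidationError(
            f"log machine id ({tlog.machine_id!r}/{ttxt.machine_id!r}) does "
            f"not match state machine {state.machine_id!r}"
        )

    refs = state.refs
    if not refs:
        refs = ft.build_reference_traces(tlog, state.config)
    sample = ft.extract_daily_sample(tlog, ttxt, state.registry, refs,
                                     state.config)

    # mutate only after full success
    if not state.refs:
        state.refs = refs
        state.reference_log = tlog
    state.samples[sample.date] = sample
    _rebuild_charts(state)
    return state


def add_comment(state: MachineState, parameter_id: str, date: _dt.date,
                text: str) -> MachineState:
    """Append a dated free-text comment to one parameter (order-preserving)."""
    if parameter_id not in state.registry:
        raise KeyError(f"unknown parameter id {parameter_id!r}")
    state.comments.setdefault(parameter_id, []).append((date, text))
    return state


def rebaseline_parameter(state: MachineState, parameter_id: str,
                         n: int) -> MachineState:
    """Recompute one parameter's limits from its last ``n`` points."""
    chart = state.chart(parameter_id)
    chart.rebaseline(n)
    applied = state.last_ingest_date
    if applied is None:
        raise ValidationError("no ingested data to rebaseline from")
    state.rebaseline_events.append((parameter_id, applied, n))
    return state


# ---------------------------------------------------------------------------
# status rollup


@dataclass(frozen=True)
class ParameterCounts:
    parameter_id: str
    status: Status
    current_alarms: int          # alarm windows ending in the last 10 points
    current_beyond_limits: int   # points at >= 3 sigma_hybrid, last 10 points
    total_alarms: int
    total_beyond_limits: int


@dataclass(frozen=True)
class StatusReport:
    machine_id: str
    last_ingest_date: _dt.date | None
    group_colors: dict[str, str]          # red / orange / green
    hot_list: tuple[str, ...]             # parameter ids currently in alarm
    parameter_counts: dict[str, ParameterCounts]

    @property
    def overall_status(self) -> Status:
        if any(c == "red" for c in self.group_colors.values()):
            return "alarm"
        if any(c == "orange" for c in self.group_colors.values()):
            return "warning"
        return "normal"


def _parameter_counts(chart: ControlChart) -> ParameterCounts:
    monitored = [p for p in chart.monitored_points() if p.i_level is not None]
    recent = monitored[-10:]

    def beyond(points) -> int:
        return sum(1 for p in points
                   if p.i_level == 3 or p.mr_level == 3)

    def alarms(points) -> int:
        return sum(1 for p in points if p.i_alarm_event or p.mr_alarm_event)

    return ParameterCounts(
        parameter_id=chart.parameter_id,
        status=chart.status,
        current_alarms=alarms(recent),
        current_beyond_limits=beyond(recent),
        total_alarms=alarms(monitored),
        total_beyond_limits=beyond(monitored),
    )


def status_report(state: MachineState) -> StatusReport:
    """Roll chart statuses up to group colors, hot list and point counts.

    A group is red iff any member is in alarm, orange iff any member warns
    and none alarms, green otherwise.  "Current" counts cover the last ten
    monitored points (calendar gaps are skipped).  The hot list contains
    exactly the parameters in alarm, ordered by severity (current alarm
    count, then beyond-limit count, descending) then id.
    """
    counts: dict[str, ParameterCounts] = {}
    group_status: dict[str, Status] = {g: "normal" for g in state.registry.groups}
    for p in state.registry:
        c = _parameter_counts(state.charts[p.id])
        counts[p.id] = c
        group_status[p.group] = combine_status(group_status[p.group], c.status)

    hot = sorted(
        (pid for pid, c in counts.items() if c.status == "alarm"),
        key=lambda pid: (-counts[pid].current_alarms,
                         -counts[pid].current_beyond_limits, pid),
    )
    return StatusReport(
        machine_id=state.machine_id,
        last_ingest_date=state.last_ingest_date,
        group_colors={g: GROUP_COLORS[s] for g, s in group_status.items()},
        hot_list=tuple(hot),
        parameter_counts=counts,
    )


# ---------------------------------------------------------------------------
# static report


def _frequency_distribution(values: list[float], bins: int = 10) -> list[str]:
    if len(values) < 2 or min(values) == max(values):
        return ["  (not enough spread for a distribution)"]
    hist, edges = np.histogram(values, bins=bins)
    width = max(hist.max(), 1)
    lines = []
    for count, lo, hi in zip(hist, edges[:-1], edges[1:]):
        bar = "#" * int(round(30 * count / width))
        lines.append(f"  [{lo: .6g}, {hi: .6g}) {count:4d} {bar}")
    return lines


def _parameter_section(state: MachineState, pid: str) -> list[str]:
    p = state.registry[pid]
    chart = state.charts[pid]
    lim, mrl = chart.i_limits, chart.mr_chart_limits
    lines = [f"## {p.name} [{pid}]  ({p.group}, units: {p.units or '-'})"]
    if lim is None:
        lines.append(f"  baseline accumulating "
                     f"({len(chart._valid_points())}/{chart.T} points)")
        return lines
    lines.append(
        f"  center {chart.grand_mean:.6g}  UCL {lim.ucl:.6g}  LCL {lim.lcl:.6g}"
        f"  3sigma_hybrid {lim.sigma3:.6g}"
        + ("  [DEGENERATE: zero-width limits]" if lim.degenerate else "")
    )
    lines.append(f"  MR: UCL {mrl.ucl:.6g}  LCL {mrl.lcl:.6g}")
    c = _parameter_counts(chart)
    lines.append(
        f"  status {c.status.upper()}; last 10 days: {c.current_alarms} alarms,"
        f" {c.current_beyond_limits} beyond limits; totals: {c.total_alarms} /"
        f" {c.total_beyond_limits}"
    )
    lines.append("  date        value        MR           I-flag  MR-flag")
    level_tag = {None: "-", 0: "ok", 2: ">=2s", 3: ">=3s"}
    for point in chart.points:
        if point.missing:
            lines.append(f"  {point.date}  (missing)")
            continue
        mr = f"{point.moving_range:<12.6g}" if point.moving_range is not None else "-           "
        iflag = "base" if point.baseline else level_tag[point.i_level]
        if point.i_alarm_event:
            iflag += "!A"
        elif point.i_warning_event:
            iflag += "!W"
        mrflag = level_tag[point.mr_level] if not point.baseline else "base"
        if point.mr_alarm_event:
            mrflag += "!A"
        lines.append(f"  {point.date}  {point.value:<12.6g} {mr} {iflag:<7} {mrflag}")
    values = [pt.value for pt in chart._valid_points()]
    lines.append("  frequency distribution (I values):")
    lines.extend(_frequency_distribution(values))
    vals = np.asarray(values)
    lines.append(
        f"  summary: n={vals.size} mean={vals.mean():.6g} min={vals.min():.6g}"
        f" max={vals.max():.6g} std={vals.std(ddof=1) if vals.size > 1 else 0.0:.6g}"
    )
    for date, text in state.comments.get(pid, []):
        lines.append(f"  comment {date}: {text}")
    return lines


def render_report(state: MachineState, report: StatusReport,
                  destination: str | Path,
                  parameters: list[str] | None = None,
                  timestamp: str = "", html: bool = False) -> Path:
    """Write a static monitoring report.

    Detailed chart sections are emitted for every parameter currently in
    warning or alarm, every parameter carrying comments, and any explicitly
    requested ids.  Regenerating from identical state produces byte-identical
    output (the timestamp is caller-injected, empty by default).
    """
    lines = [f"# Predictive maintenance report - machine {state.machine_id}"]
    if timestamp:
        lines.append(f"generated: {timestamp}")
    lines.append(f"last ingest: {report.last_ingest_date or 'never'}")
    lines.append("")
    lines.append("## Group status")
    for group, color in report.group_colors.items():
        lines.append(f"  {color.upper():6s}  {group}")
    lines.append("")
    lines.append("## Hot list (parameters in alarm)")
    if report.hot_list:
        lines.extend(f"  {pid}" for pid in report.hot_list)
    else:
        lines.append("  (empty)")
    lines.append("")

    selected: list[str] = list(parameters or [])
    for pid, c in report.parameter_counts.items():
        if c.status != "normal" and pid not in selected:
            selected.append(pid)
    for pid in state.comments:
        if pid not in selected:
            selected.append(pid)
    for pid in selected:
        if pid not in state.registry:
            raise KeyError(f"unknown parameter id {pid!r}")
        lines.extend(_parameter_section(state, pid))
        lines.append("")

    text = "\n".join(lines) + "\n"
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    if html:
        body = (text.replace("&", "&amp;").replace("<", "&lt;")
                .replace(">", "&gt;"))
        text = (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            f"<title>PdM report {state.machine_id}</title></head>"
            f"<body><pre>\n{body}</pre></body></html>\n"
        )
    destination.write_text(text)
    return destination


# ---------------------------------------------------------------------------
# persistence


def save_state(state: MachineState, directory: str | Path) -> Path:
    """Persist a machine directory: registry, samples, comments, references."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "registry.yaml", "w") as fh:
        yaml.safe_dump(state.registry.to_config(), fh, sort_keys=False)
    if state.reference_log is not None:
        write_trajectory_log(state.reference_log,
                             directory / "references.tlog.csv")
    payload = {
        "machine_id": state.machine_id,
        "T": state.T,
        "config": {
            "lag_window": state.config.lag_window,
            "speed_segments": {
                axis: [[a.start, a.end], [b.start, b.end]]
                for axis, (a, b) in state.config.speed_segments.items()
            },
            "cc_segments": {
                axis: [seg.start, seg.end]
                for axis, seg in state.config.cc_segments.items()
            },
            "position_segments": {
                axis: [seg.start, seg.end]
                for axis, seg in state.config.position_segments.items()
            },
        },
        "samples": {
            date.isoformat(): {
                "values": sample.values,
                "provenance": sample.provenance,
            }
            for date, sample in sorted(state.samples.items())
        },
        "comments": {
            pid: [[date.isoformat(), text] for date, text in entries]
            for pid, entries in state.comments.items()
        },
        "rebaseline_events": [
            [pid, date.isoformat(), n] for pid, date, n in state.rebaseline_events
        ],
    }
    with open(directory / "state.json", "w") as fh:
        json.dump(payload, fh)
    return directory


def load_state(directory: str | Path) -> MachineState:
    """Restore a machine directory written by :func:`save_state`."""
    directory = Path(directory)
    with open(directory / "registry.yaml") as fh:
        registry = ParameterRegistry.from_config(yaml.safe_load(fh))
    with open(directory / "state.json") as fh:
        payload = json.load(fh)
    config = None
    if "config" in payload:
        c = payload["config"]
        config = ft.FeatureConfig(
            speed_segments={
                axis: (ft.SegmentSpec(*a), ft.SegmentSpec(*b))
                for axis, (a, b) in c["speed_segments"].items()
            },
            cc_segments={axis: ft.SegmentSpec(*seg)
                         for axis, seg in c["cc_segments"].items()},
            position_segments={axis: ft.SegmentSpec(*seg)
                               for axis, seg in c["position_segments"].items()},
            lag_window=c["lag_window"],
        )
    state = new_machine_state(payload["machine_id"], registry=registry,
                              config=config,
                              T=payload.get("T", DEFAULT_BASELINE_SIZE))
    ref_path = directory / "references.tlog.csv"
    if ref_path.exists():
        state.reference_log = read_trajectory_log(ref_path)
        state.refs = ft.build_reference_traces(state.reference_log, state.config)
    for date_str, entry in payload["samples"].items():
        date = _dt.date.fromisoformat(date_str)
        state.samples[date] = ft.DailySample(
            machine_id=state.machine_id, date=date,
            values=dict(entry["values"]), provenance=dict(entry["provenance"]),
        )
    state.comments = {
        pid: [(_dt.date.fromisoformat(ds), text) for ds, text in entries]
        for pid, entries in payload.get("comments", {}).items()
    }
    state.rebaseline_events = [
        (pid, _dt.date.fromisoformat(ds), n)
        for pid, ds, n in payload.get("rebaseline_events", [])
    ]
    _rebuild_charts(state)
    return state
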