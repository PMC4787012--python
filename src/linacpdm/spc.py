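"""Individuals/Moving-Range control charts with hybrid limits.

Each monitored parameter is charted daily with subgroup size n = 1, so the
appropriate pair is the Individuals (I) chart and the Moving-Range (MR)
chart, MR_t = |I_t - I_{t+1}|.  Classical 3-sigma I/MR limits on hundreds of
parameters produce an unacceptable false-positive load, so the limits are
*hybrid*: the 3-sigma half-width estimated from the mean moving range is
inflated by a specification-derived constant S_p (see
:class:`linacpdm.registry.SpRule`):

    I chart:   UCL/LCL = Ibar +/- [E2 * MRbar + S_p],
               3 sigma_(I)hybrid = E2 * MRbar + S_p
    MR chart:  UCL = D4 * MRbar + S_p,   LCL = D3 * MRbar = 0,
               3 sigma_(R)hybrid = D4 * MRbar + S_p

with the standard n = 2 moving-range constants E2 = 2.660, D3 = 0,
D4 = 3.267.  Warning thresholds sit at two thirds of the 3-sigma-hybrid
distance ("2 sigma_hybrid"); all threshold comparisons are inclusive (>=).

Windowed run rules (sliding windows over consecutive monitored points,
same side of the centerline for the I chart):

* I chart alarms: 2-of-3 or 3-of-5 points at >= 3 sigma_hybrid;
  warnings: same windows at >= 2 sigma_hybrid.
* MR chart alarms: 3-of-5 points at >= 3 sigma_hybrid (upper side only);
  warnings: 3-of-5 at >= 2 sigma_hybrid.

The default baseline length is T = 20 points; after a repair or adjustment
the chart can be rebaselined from the most recent n points, which changes the
limits for the latest point and all future points while preserving the
recorded classification of earlier points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import InsufficientBaselineError, ValidationError

Status = Literal["normal", "warning", "alarm"]
_STATUS_ORDER = {"normal": 0, "warning": 1, "alarm": 2}

DEFAULT_BASELINE_SIZE = 20  # T


@dataclass(frozen=True)
class SPCConstants:
    """Moving-range chart constants for subgroup size n = 2."""

    E2: float = 2.660
    D3: float = 0.0
    D4: float = 3.267


CONSTANTS = SPCConstants()


@dataclass(frozen=True)
class RuleConfig:
    """Windowed warning/alarm rules; windows are (hits, length) pairs."""

    i_alarm_windows: tuple[tuple[int, int], ...] = ((2, 3), (3, 5))
    i_warning_windows: tuple[tuple[int, int], ...] = ((2, 3), (3, 5))
    mr_alarm_windows: tuple[tuple[int, int], ...] = ((3, 5),)
    mr_warning_windows: tuple[tuple[int, int], ...] = ((3, 5),)
    same_side_required: bool = True


DEFAULT_RULES = RuleConfig()


@dataclass(frozen=True)
class IndividualLimits:
    ucl: float
    lcl: float
    sigma3: float  # E2*MRbar + Sp, the hybrid 3-sigma half-width

    @property
    def degenerate(self) -> bool:
        """Zero-width limits: chart unusable until noise is observed."""
        return self.sigma3 == 0.0


@dataclass(frozen=True)
class MRLimits:
    ucl: float
    lcl: float
    sigma3: float  # D4*MRbar + Sp


def baseline_stats(values: Sequence[float]) -> tuple[float, np.ndarray, float]:
    """Grand mean, successive moving ranges and their mean for a baseline.

    Returns ``(grand_mean, moving_ranges, mr_mean)`` where ``moving_ranges``
    has length T - 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientBaselineError(
            f"baseline needs at least 2 values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("baseline values must be finite")
    moving_ranges = np.abs(np.diff(arr))
    return float(arr.mean()), moving_ranges, float(moving_ranges.mean())


def individual_limits(grand_mean: float, mr_mean: float, sp: float,
                      constants: SPCConstants = CONSTANTS) -> IndividualLimits:
    """Hybrid I-chart limits: Ibar +/- (E2*MRbar + Sp)."""
    if mr_mean < 0 or sp < 0:
        raise ValidationError("mr_mean and sp must be >= 0")
    sigma3 = constants.E2 * mr_mean + sp
    return IndividualLimits(ucl=grand_mean + sigma3, lcl=grand_mean - sigma3,
                            sigma3=sigma3)


def mr_limits(mr_mean: float, sp: float,
              constants: SPCConstants = CONSTANTS) -> MRLimits:
    """Hybrid MR-chart limits: UCL = D4*MRbar + Sp, LCL = D3*MRbar = 0."""
    if mr_mean < 0 or sp < 0:
        raise ValidationError("mr_mean and sp must be >= 0")
    sigma3 = constants.D4 * mr_mean + sp
    return MRLimits(ucl=sigma3, lcl=constants.D3 * mr_mean, sigma3=sigma3)


# ---------------------------------------------------------------------------
# point classification

# classification levels: 0 = inside, 2 = beyond 2 sigma_hybrid,
# 3 = beyond 3 sigma_hybrid; side: -1 below center, +1 above, 0 at center.


def classify_individual(value: float, center: float,
                        limits: IndividualLimits) -> tuple[int, int]:
    """(level, side) of an I-chart point; inclusive thresholds."""
    dev = value - center
    mag = abs(dev)
    side = 0 if dev == 0 else (1 if dev > 0 else -1)
    if limits.degenerate:
        return (0, side)
    if mag >= limits.sigma3:
        return (3, side)
    if mag >= (2.0 / 3.0) * limits.sigma3:
        return (2, side)
    return (0, side)


def classify_mr(mr: float, limits: MRLimits) -> int:
    """Level of an MR-chart point (upper side only)."""
    if limits.sigma3 == 0.0:
        return 0
    if mr >= limits.sigma3:
        return 3
    if mr >= (2.0 / 3.0) * limits.sigma3:
        return 2
    return 0


def _window_hit(levels: Sequence[int], sides: Sequence[int] | None,
                windows: Iterable[tuple[int, int]], min_level: int,
                same_side: bool) -> bool:
    # A k-of-m rule fires when k qualifying points fall within any span of at
    # most m consecutive monitored points; a run shorter than m is evaluated
    # as a whole (k consecutive hits need not wait for an m-th observation).
    n = len(levels)
    for hits, length in windows:
        length = min(length, n)
        if length < hits:
            continue
        for start in range(0, n - length + 1):
            win = range(start, start + length)
            if same_side and sides is not None:
                for s in (1, -1):
                    count = sum(
                        1 for i in win if levels[i] >= min_level and sides[i] == s
                    )
                    if count >= hits:
                        return True
            else:
                count = sum(1 for i in win if levels[i] >= min_level)
                if count >= hits:
                    return True
    return False


def evaluate_individual_rules(levels: Sequence[int], sides: Sequence[int],
                              rules: RuleConfig = DEFAULT_RULES) -> Status:
    """Windowed status of a run of I-chart classifications.

    Any sliding window inside the supplied run counts; pass the recent run
    (e.g. the last 5 monitored points) to obtain a *current* status.
    """
    if _window_hit(levels, sides, rules.i_alarm_windows, 3,
                   rules.same_side_required):
        return "alarm"
    if _window_hit(levels, sides, rules.i_warning_windows, 2,
                   rules.same_side_required):
        return "warning"
    return "normal"


def evaluate_mr_rules(levels: Sequence[int],
                      rules: RuleConfig = DEFAULT_RULES) -> Status:
    """Windowed status of a run of MR-chart classifications (upper side)."""
    if _window_hit(levels, None, rules.mr_alarm_windows, 3, False):
        return "alarm"
    if _window_hit(levels, None, rules.mr_warning_windows, 2, False):
        return "warning"
    return "normal"


def combine_status(*statuses: Status) -> Status:
    return max(statuses, key=lambda s: _STATUS_ORDER[s], default="normal")


# ---------------------------------------------------------------------------
# the chart


@dataclass
class ChartPoint:
    """One recorded observation with its classification under the limits
    that were in force when it was recorded."""

    date: object  # datetime.date (kept generic for sortable keys)
    value: float
    missing: bool = False
    baseline: bool = False           # part of the accumulating baseline
    moving_range: float | None = None
    i_level: int | None = None       # None while baseline / missing / degenerate
    i_side: int | None = None
    mr_level: int | None = None
    i_alarm_event: bool = False      # an alarm window ends at this point
    i_warning_event: bool = False
    mr_alarm_event: bool = False
    mr_warning_event: bool = False


class ControlChart:
    """Per-parameter hybrid I/MR chart with baseline accumulation.

    The first ``T`` finite points accumulate the baseline; at the T-th point
    the limits are computed (Eqs for Ibar, MRbar, hybrid limits) and
    monitoring starts.  Non-finite values are recorded as missing and the
    rule windows slide over them — windows are over consecutive *monitored*
    points, not calendar days.
    """

    def __init__(self, parameter_id: str, sp: float, *,
                 T: int = DEFAULT_BASELINE_SIZE,
                 rules: RuleConfig = DEFAULT_RULES,
                 constants: SPCConstants = CONSTANTS) -> None:
        if sp < 0:
            raise ValidationError("sp must be >= 0")
        if T < 2:
            raise ValidationError("baseline size T must be >= 2")
        self.parameter_id = parameter_id
        self.sp = float(sp)
        self.T = int(T)
        self.rules = rules
        self.constants = constants
        self.points: list[ChartPoint] = []
        self.i_limits: IndividualLimits | None = None
        self.mr_chart_limits: MRLimits | None = None
        self.grand_mean: float | None = None
        self.mr_mean: float | None = None

    # -- state queries -----------------------------------------------------

    @property
    def has_limits(self) -> bool:
        return self.i_limits is not None

    @property
    def degenerate(self) -> bool:
        return self.i_limits is not None and self.i_limits.degenerate

    def _valid_points(self) -> list[ChartPoint]:
        return [p for p in self.points if not p.missing]

    def monitored_points(self) -> list[ChartPoint]:
        """Classified (post-baseline, non-missing) points in order."""
        return [p for p in self._valid_points() if not p.baseline]

    # -- ingestion ----------------------------------------------------------

    def add_point(self, value: float, date) -> ChartPoint:
        """Record one observation; classify it if the chart is monitoring."""
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            point = ChartPoint(date=date, value=float("nan"), missing=True)
            self.points.append(point)
            return point

        valid = self._valid_points()
        if self.i_limits is None:
            point = ChartPoint(date=date, value=float(value), baseline=True)
            if valid:
                point.moving_range = abs(point.value - valid[-1].value)
            self.points.append(point)
            if len(valid) + 1 == self.T:
                self._compute_limits([p.value for p in self._valid_points()])
            return point

        point = ChartPoint(date=date, value=float(value))
        if valid:
            point.moving_range = abs(point.value - valid[-1].value)
        self.points.append(point)
        self._classify_point(point)
        self._mark_events(point)
        return point

    def _compute_limits(self, baseline_values: Sequence[float]) -> None:
        grand_mean, _, mr_mean = baseline_stats(baseline_values)
        self.grand_mean = grand_mean
        self.mr_mean = mr_mean
        self.i_limits = individual_limits(grand_mean, mr_mean, self.sp,
                                          self.constants)
        self.mr_chart_limits = mr_limits(mr_mean, self.sp, self.constants)

    def _classify_point(self, point: ChartPoint) -> None:
        assert self.i_limits is not None and self.mr_chart_limits is not None
        if self.degenerate:
            point.i_level = None
            point.mr_level = None
            return
        level, side = classify_individual(point.value, self.grand_mean,
                                          self.i_limits)
        point.i_level = level
        point.i_side = side
        if point.moving_range is not None:
            point.mr_level = classify_mr(point.moving_range,
                                         self.mr_chart_limits)

    def _recent_run(self, length: int) -> list[ChartPoint]:
        run = [p for p in self.monitored_points() if p.i_level is not None]
        return run[-length:]

    def _mark_events(self, point: ChartPoint) -> None:
        """Flag alarm/warning windows ending at this point."""
        if point.i_level is None:
            return
        run = self._recent_run(5)
        levels = [p.i_level for p in run]
        sides = [p.i_side for p in run]
        status = evaluate_individual_rules(levels, sides, self.rules)
        point.i_alarm_event = status == "alarm"
        point.i_warning_event = status in ("alarm", "warning")
        mr_levels = [p.mr_level for p in run if p.mr_level is not None]
        mr_status = evaluate_mr_rules(mr_levels[-5:], self.rules)
        point.mr_alarm_event = mr_status == "alarm"
        point.mr_warning_event = mr_status in ("alarm", "warning")

    # -- status --------------------------------------------------------------

    def i_status(self) -> Status:
        run = self._recent_run(5)
        if not run:
            return "normal"
        return evaluate_individual_rules([p.i_level for p in run],
                                         [p.i_side for p in run], self.rules)

    def mr_status(self) -> Status:
        run = [p for p in self._recent_run(5) if p.mr_level is not None]
        if not run:
            return "normal"
        return evaluate_mr_rules([p.mr_level for p in run], self.rules)

    @property
    def status(self) -> Status:
        return combine_status(self.i_status(), self.mr_status())

    # -- rebaselining --------------------------------------------------------

    def rebaseline(self, n: int) -> None:
        """Recompute the limits from the last ``n`` recorded values.

        The new limits govern the most recent point (which is reclassified)
        and all future points; earlier classifications are preserved.
        """
        valid = self._valid_points()
        if n < 2:
            raise InsufficientBaselineError("rebaseline needs n >= 2")
        if n > len(valid):
            raise InsufficientBaselineError(
                f"rebaseline requested {n} points but only {len(valid)} recorded"
            )
        self._compute_limits([p.value for p in valid[-n:]])
        last = valid[-1]
        if not last.baseline:
            self._classify_point(last)
            self._mark_events(last)

    # -- export ---------------------------------------------------------------

    def to_table(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        """Flat per-point table (date, value, MR, statuses, limits)."""
        import pandas as pd

        lim = self.i_limits
        mrl = self.mr_chart_limits
        rows = []
        for p in self.points:
            rows.append({
                "parameter_id": self.parameter_id,
                "date": p.date,
                "value": p.value,
                "moving_range": p.moving_range,
                "baseline": p.baseline,
                "missing": p.missing,
                "i_level": p.i_level,
                "i_side": p.i_side,
                "mr_level": p.mr_level,
                "i_alarm": p.i_alarm_event,
                "mr_alarm": p.mr_alarm_event,
                "grand_mean": self.grand_mean,
                "ucl_i": lim.ucl if lim else None,
                "lcl_i": lim.lcl if lim else None,
                "ucl_mr": mrl.ucl if mrl else None,
                "lcl_mr": mrl.lcl if mrl else None,
            })
        return pd.DataFrame(rows)


def update_chart(chart: ControlChart, value: float, date) -> ControlChart:
    """Functional-style wrapper: append one observation and return the chart."""
    chart.add_point(value, date)
    return chart


def rebaseline(chart: ControlChart, n: int) -> ControlChart:
    """Recompute chart limits from the last ``n`` points (see method)."""
    chart.rebaseline(n)
    return chart
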