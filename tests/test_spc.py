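"""Hybrid I/MR chart math, windowed rules, rebaselining."""

import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linacpdm import (CONSTANTS, ControlChart, baseline_stats,
                      evaluate_individual_rules, evaluate_mr_rules,
                      individual_limits, mr_limits, rebaseline, update_chart)
from linacpdm.errors import InsufficientBaselineError, ValidationError
from linacpdm.spc import DEFAULT_RULES

DAY0 = dt.date(2026, 1, 5)


def _dates(n):
    return [DAY0 + dt.timedelta(days=i) for i in range(n)]


def _fill(chart, values, start=0):
    for i, v in enumerate(values):
        chart.add_point(float(v), DAY0 + dt.timedelta(days=start + i))
    return chart


class TestBaselineStats:
    @pytest.mark.parametrize(
        "values, mean, ranges, mr_mean",
        [
            ([1, 2, 3], 2.0, [1, 1], 1.0),
            ([5, 3, 6], 14 / 3, [2, 3], 2.5),
            ([4.0] * 20, 4.0, [0.0] * 19, 0.0),
        ],
    )
    def test_hand_examples(self, values, mean, ranges, mr_mean):
        gm, mrs, mrm = baseline_stats(values)
        assert gm == pytest.approx(mean)
        assert mrs == pytest.approx(ranges)
        assert mrm == pytest.approx(mr_mean)

    def test_single_point_is_insufficient(self):
        with pytest.raises(InsufficientBaselineError):
            baseline_stats([1.0])


class TestLimits:
    @pytest.mark.parametrize(
        "mean, mr, sp, ucl, lcl, sigma3",
        [
            (10.0, 1.0, 0.0, 12.660, 7.340, 2.660),
            (10.0, 1.0, 0.5, 13.160, 6.840, 3.160),
        ],
    )
    def test_individual_limits(self, mean, mr, sp, ucl, lcl, sigma3):
        lim = individual_limits(mean, mr, sp)
        assert lim.ucl == pytest.approx(ucl)
        assert lim.lcl == pytest.approx(lcl)
        assert lim.sigma3 == pytest.approx(sigma3)
        assert not lim.degenerate

    def test_zero_variance_zero_sp_is_degenerate(self):
        assert individual_limits(5.0, 0.0, 0.0).degenerate

    @pytest.mark.parametrize(
        "mr, sp, ucl, sigma3",
        [(1.0, 0.0, 3.267, 3.267), (0.0, 0.2, 0.2, 0.2)],
    )
    def test_mr_limits(self, mr, sp, ucl, sigma3):
        lim = mr_limits(mr, sp)
        assert lim.ucl == pytest.approx(ucl)
        assert lim.lcl == 0.0
        assert lim.sigma3 == pytest.approx(sigma3)

    @given(mr=st.floats(0, 1e6), sp=st.floats(0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_mr_lcl_always_zero(self, mr, sp):
        assert mr_limits(mr, sp).lcl == 0.0

    @given(
        mean=st.floats(-1e6, 1e6),
        mr=st.floats(0, 1e3),
        sp=st.floats(0, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_limit_identities(self, mean, mr, sp):
        """UCL - LCL = 2*(E2*MRbar + Sp); symmetric about the grand mean."""
        lim = individual_limits(mean, mr, sp)
        assert lim.ucl - lim.lcl == pytest.approx(2 * (CONSTANTS.E2 * mr + sp))
        assert lim.ucl - mean == pytest.approx(mean - lim.lcl)
        assert mr_limits(mr, sp).sigma3 == pytest.approx(CONSTANTS.D4 * mr + sp)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            individual_limits(0.0, -1.0, 0.0)
        with pytest.raises(ValidationError):
            mr_limits(0.0, -0.1)


# ---------------------------------------------------------------------------
# rule engine

from oracles import brute_force_status

I_SYMBOLS = [(0, 1), (2, 1), (3, 1), (2, -1), (3, -1)]  # (level, side)


class TestRuleEngine:
    def test_two_of_three_beyond_ucl_is_alarm(self):
        # above UCL, inside, above UCL
        assert evaluate_individual_rules([3, 0, 3], [1, 1, 1]) == "alarm"

    def test_two_of_three_beyond_2sigma_is_warning(self):
        assert evaluate_individual_rules([2, 0, 2], [1, -1, 1]) == "warning"

    def test_all_inside_is_normal(self):
        assert evaluate_individual_rules([0, 0, 0, 0, 0], [1, -1, 1, 1, -1]) == "normal"

    def test_same_side_requirement(self):
        # two 3-sigma hits on opposite sides: no alarm with same-side rule
        assert evaluate_individual_rules([3, 0, 3], [1, 1, -1]) == "normal"

    def test_three_of_five_mr_alarm(self):
        assert evaluate_mr_rules([3, 0, 3, 0, 3]) == "alarm"
        assert evaluate_mr_rules([3, 0, 3, 0, 0]) == "normal"

    def test_exhaustive_equivalence_short_i_sequences(self):
        """Every I-chart classification sequence up to length 5 agrees with
        the brute-force window enumeration (longer runs in acceptance)."""
        for n in range(1, 6):
            for seq in itertools.product(I_SYMBOLS, repeat=n):
                levels = [s[0] for s in seq]
                sides = [s[1] for s in seq]
                expected = brute_force_status(
                    levels, sides, DEFAULT_RULES.i_alarm_windows,
                    DEFAULT_RULES.i_warning_windows, True)
                assert evaluate_individual_rules(levels, sides) == expected

    @given(st.lists(st.sampled_from([0, 2, 3]), min_size=1, max_size=12),)
    @settings(max_examples=200, deadline=None)
    def test_mr_rules_match_brute_force(self, levels):
        expected = brute_force_status(
            levels, None, DEFAULT_RULES.mr_alarm_windows,
            DEFAULT_RULES.mr_warning_windows, False, upper_only=True)
        assert evaluate_mr_rules(levels) == expected


# ---------------------------------------------------------------------------
# chart lifecycle


class TestControlChart:
    def test_limits_appear_at_twentieth_point(self):
        rng = np.random.default_rng(0)
        chart = ControlChart("p", sp=0.0)
        values = rng.normal(10, 1, 20)
        for i, v in enumerate(values):
            assert not chart.has_limits
            chart.add_point(v, DAY0 + dt.timedelta(days=i))
        assert chart.has_limits
        gm, _, mrm = baseline_stats(values)
        assert chart.grand_mean == pytest.approx(gm)
        assert chart.i_limits.sigma3 == pytest.approx(CONSTANTS.E2 * mrm)

    def test_monitoring_classifies_points(self):
        chart = ControlChart("p", sp=0.0, T=4)
        _fill(chart, [10, 11, 10, 11])
        point = chart.add_point(25.0, DAY0 + dt.timedelta(days=5))
        assert point.i_level == 3
        assert point.i_side == 1
        assert point.mr_level == 3

    def test_sp_reduces_alarm_count_on_same_stream(self):
        """Paired seeded in-control streams: Sp > 0 never adds alarms."""
        rng = np.random.default_rng(42)
        stream = rng.normal(0, 1, 200)
        counts = {}
        for sp in (0.0, 0.5):
            chart = ControlChart("p", sp=sp)
            _fill(chart, stream)
            counts[sp] = sum(p.i_alarm_event for p in chart.monitored_points())
        assert counts[0.5] <= counts[0.0]

    def test_sustained_large_shift_alarms_quickly(self):
        """+5*sigma3 sustained shift: windowed alarm within 3 points of onset
        in at least 99 % of seeded runs (small-scale power check)."""
        hits = 0
        runs = 100
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            chart = ControlChart("p", sp=0.0)
            _fill(chart, rng.normal(0, 1, 25))
            shift = 5 * chart.i_limits.sigma3
            alarm_at = None
            for k in range(5):
                point = chart.add_point(rng.normal(shift, 1),
                                        DAY0 + dt.timedelta(days=25 + k))
                if point.i_alarm_event:
                    alarm_at = k
                    break
            if alarm_at is not None and alarm_at < 3:
                hits += 1
        assert hits >= 0.99 * runs

    def test_missing_values_slide_windows(self):
        chart = ControlChart("p", sp=0.0, T=4)
        _fill(chart, [10, 11, 10, 11])
        chart.add_point(25.0, DAY0 + dt.timedelta(days=5))
        chart.add_point(float("nan"), DAY0 + dt.timedelta(days=6))
        point = chart.add_point(25.0, DAY0 + dt.timedelta(days=7))
        # two beyond-3-sigma points in the 3-point window spanning the gap
        assert point.i_alarm_event
        assert chart.status == "alarm"

    def test_degenerate_chart_flagged(self):
        chart = ControlChart("p", sp=0.0, T=4)
        _fill(chart, [5.0, 5.0, 5.0, 5.0])
        assert chart.has_limits and chart.degenerate
        point = chart.add_point(5.1, DAY0 + dt.timedelta(days=10))
        assert point.i_level is None  # unusable until noise observed
        assert chart.status == "normal"

    def test_false_alarm_rate_matches_classical_i_chart(self):
        """Sp = 0, Gaussian in-control data, long baseline: the per-point
        beyond-3-sigma rate is consistent with the classical ~0.27 %."""
        rng = np.random.default_rng(7)
        baseline = rng.normal(0, 1, 2000)
        gm, _, mrm = baseline_stats(baseline)
        lim = individual_limits(gm, mrm, 0.0)
        n = 100_000
        fresh = rng.normal(0, 1, n)
        beyond = np.sum((fresh >= lim.ucl) | (fresh <= lim.lcl))
        p = 0.0027
        sd = np.sqrt(n * p * (1 - p))
        assert abs(beyond - n * p) < 5 * sd


class TestRebaseline:
    def _shifted_chart(self):
        rng = np.random.default_rng(3)
        chart = ControlChart("p", sp=0.0)
        _fill(chart, rng.normal(0, 1, 20))
        _fill(chart, rng.normal(8, 1, 20), start=20)  # post-repair level
        return chart, rng

    def test_rebaseline_restores_normal_classification(self):
        chart, rng = self._shifted_chart()
        assert chart.status == "alarm"
        rebaseline(chart, 20)
        for k in range(6):
            point = chart.add_point(rng.normal(8, 1),
                                    DAY0 + dt.timedelta(days=40 + k))
        assert point.i_level == 0
        assert chart.status == "normal"

    def test_rebaseline_preserves_prior_classifications(self):
        chart, _ = self._shifted_chart()
        flags_before = [p.i_level for p in chart.monitored_points()][:-1]
        rebaseline(chart, 20)
        flags_after = [p.i_level for p in chart.monitored_points()][:-1]
        assert flags_after == flags_before

    def test_rebaseline_with_all_points_is_idempotent_when_unshifted(self):
        rng = np.random.default_rng(11)
        chart = ControlChart("p", sp=0.1)
        values = rng.normal(0, 1, 20)
        _fill(chart, values)
        before = chart.i_limits
        rebaseline(chart, 20)
        assert chart.i_limits.ucl == pytest.approx(before.ucl)
        assert chart.i_limits.lcl == pytest.approx(before.lcl)

    def test_rebaseline_requires_at_least_two_points(self):
        chart = ControlChart("p", sp=0.0, T=4)
        _fill(chart, [1, 2, 3, 4])
        with pytest.raises(InsufficientBaselineError):
            rebaseline(chart, 1)

    def test_rebaseline_cannot_exceed_available_points(self):
        chart = ControlChart("p", sp=0.0, T=4)
        _fill(chart, [1, 2, 3, 4])
        with pytest.raises(InsufficientBaselineError):
            rebaseline(chart, 10)


@given(
    sp=st.floats(0.01, 2.0),
    seed=st.integers(0, 500),
)
@settings(max_examples=40, deadline=None)
def test_sp_monotonicity_never_escalates_points(sp, seed):
    """Widening limits (Sp > 0) cannot convert a normal point to
    warning/alarm on the identical stream."""
    rng = np.random.default_rng(seed)
    stream = rng.normal(0, 1, 60)
    base = ControlChart("p", sp=0.0)
    wide = ControlChart("p", sp=sp)
    for i, v in enumerate(stream):
        update_chart(base, v, DAY0 + dt.timedelta(days=i))
        update_chart(wide, v, DAY0 + dt.timedelta(days=i))
    for p0, p1 in zip(base.monitored_points(), wide.monitored_points()):
        assert (p1.i_level or 0) <= (p0.i_level or 0)
        assert (p1.mr_level or 0) <= (p0.mr_level or 0)
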