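"""Ingest pipeline, status rollup, reporting, persistence and the CLI."""

import datetime as dt

import numpy as np
import pytest
from click.testing import CliRunner

from linacpdm import (add_comment, default_error_suite, ingest_day, load_state,
                      new_machine_state, rebaseline_parameter, render_report,
                      save_state, simulate_text_snapshot, simulate_trajectory,
                      status_report, write_text_log, write_trajectory_log)
from linacpdm.cli import main as cli_main
from linacpdm.errors import ValidationError
from linacpdm.simulate import ErrorSpec, day_seed, inject_error

DAY0 = dt.date(2026, 1, 5)
MACHINE = "TB01"
SCALE = 8


def _write_day(directory, plan, machine_model, day, seed=99, machine_id=MACHINE,
               mutate_tlog=None):
    date = DAY0 + dt.timedelta(days=day)
    ss = day_seed(seed, day)
    tlog = simulate_trajectory(plan, machine_model, machine_id, date, ss)
    if mutate_tlog is not None:
        tlog = mutate_tlog(tlog)
    ttxt = simulate_text_snapshot(machine_model, machine_id, date, ss,
                                  day_index=day)
    tlog_path = directory / f"{date}.tlog.csv"
    ttxt_path = directory / f"{date}.ttxt"
    write_trajectory_log(tlog, tlog_path)
    write_text_log(ttxt, ttxt_path)
    return tlog_path, ttxt_path


@pytest.fixture(scope="module")
def monitored_state(registry, compact, tmp_path_factory):
    """A machine with T=10 baseline days plus 6 monitored days, one of which
    carries an injected jaw offset big enough to alarm."""
    plan, config, machine_model = compact
    logs = tmp_path_factory.mktemp("logs")
    state = new_machine_state(MACHINE, registry=registry, config=config, T=10)

    def jaw_fault(tlog):
        return inject_error(tlog, ErrorSpec(target="jaw_x1", mode="add_shift",
                                            magnitude=0.3))

    for day in range(16):
        mutate = jaw_fault if day >= 13 else None
        tlog_path, ttxt_path = _write_day(logs, plan, machine_model, day,
                                          mutate_tlog=mutate)
        ingest_day(state, tlog_path, ttxt_path)
    return state


class TestIngest:
    def test_monitoring_starts_after_baseline(self, registry, compact, tmp_path):
        plan, config, machine_model = compact
        state = new_machine_state(MACHINE, registry=registry, config=config, T=10)
        for day in range(11):
            paths = _write_day(tmp_path, plan, machine_model, day)
            ingest_day(state, *paths)
        chart = state.chart("gantry/speed_segment_1")
        assert chart.has_limits
        assert len(chart.monitored_points()) == 1
        report = status_report(state)
        assert set(report.group_colors.values()) <= {"green", "orange", "red"}

    def test_reingest_same_date_is_idempotent(self, registry, compact, tmp_path):
        plan, config, machine_model = compact
        state = new_machine_state(MACHINE, registry=registry, config=config, T=5)
        paths = []
        for day in range(6):
            paths.append(_write_day(tmp_path, plan, machine_model, day))
            ingest_day(state, *paths[-1])
        values_before = {pid: [p.value for p in c.points]
                         for pid, c in state.charts.items()}
        ingest_day(state, *paths[-1])  # same date again
        assert len(state.samples) == 6
        values_after = {pid: [p.value for p in c.points]
                        for pid, c in state.charts.items()}
        assert values_after == values_before

    def test_mismatched_machine_id_rejected(self, registry, compact, tmp_path):
        plan, config, machine_model = compact
        state = new_machine_state("OTHER", registry=registry, config=config)
        paths = _write_day(tmp_path, plan, machine_model, 0)
        with pytest.raises(ValidationError, match="machine id"):
            ingest_day(state, *paths)
        assert not state.samples  # state untouched

    def test_parse_failure_leaves_state_unchanged(self, registry, compact,
                                                  tmp_path):
        plan, config, machine_model = compact
        state = new_machine_state(MACHINE, registry=registry, config=config)
        tlog_path, ttxt_path = _write_day(tmp_path, plan, machine_model, 0)
        ttxt_path.write_text("garbage\n")
        with pytest.raises(Exception):
            ingest_day(state, tlog_path, ttxt_path)
        assert not state.samples


class TestStatusReport:
    def test_alarmed_jaw_turns_collimation_red_and_hot_listed(self,
                                                              monitored_state):
        report = status_report(monitored_state)
        assert report.group_colors["Collimation"] == "red"
        assert "jaw_x1/position" in report.hot_list

    def test_hot_list_is_exactly_the_alarmed_parameters(self, monitored_state):
        report = status_report(monitored_state)
        alarmed = {pid for pid, c in report.parameter_counts.items()
                   if c.status == "alarm"}
        assert set(report.hot_list) == alarmed

    def test_rollup_is_pure(self, monitored_state):
        a = status_report(monitored_state)
        b = status_report(monitored_state)
        assert a.group_colors == b.group_colors
        assert a.hot_list == b.hot_list

    def test_baseline_only_state_is_all_green(self, registry, compact, tmp_path):
        plan, config, machine_model = compact
        state = new_machine_state(MACHINE, registry=registry, config=config, T=10)
        paths = _write_day(tmp_path, plan, machine_model, 0)
        ingest_day(state, *paths)
        report = status_report(state)
        assert set(report.group_colors.values()) == {"green"}
        assert report.hot_list == ()

    def test_current_counts_cover_last_ten_points(self, monitored_state):
        counts = status_report(monitored_state).parameter_counts["jaw_x1/position"]
        assert counts.current_beyond_limits == 3
        assert counts.total_beyond_limits == 3
        assert counts.current_alarms >= 1


class TestRenderReport:
    def test_alarmed_parameter_section_shows_limits_and_flags(self,
                                                              monitored_state,
                                                              tmp_path):
        report = status_report(monitored_state)
        path = render_report(monitored_state, report, tmp_path / "report.txt")
        text = path.read_text()
        assert "jaw_x1/position" in text
        assert "UCL" in text and "LCL" in text
        assert ">=3s" in text
        assert "RED" in text

    def test_regeneration_is_byte_identical(self, monitored_state, tmp_path):
        report = status_report(monitored_state)
        a = render_report(monitored_state, report, tmp_path / "a.txt").read_text()
        b = render_report(monitored_state, report, tmp_path / "b.txt").read_text()
        assert a == b

    def test_comments_appear_in_report(self, monitored_state, tmp_path):
        add_comment(monitored_state, "jaw_x1/position", DAY0,
                    "jaw motor serviced")
        add_comment(monitored_state, "jaw_x1/position", DAY0, "second note")
        report = status_report(monitored_state)
        text = render_report(monitored_state, report,
                             tmp_path / "c.txt").read_text()
        assert "jaw motor serviced" in text
        first = text.index("jaw motor serviced")
        assert "second note" in text[first:]

    def test_html_rendering(self, monitored_state, tmp_path):
        report = status_report(monitored_state)
        path = render_report(monitored_state, report, tmp_path / "r.html",
                             html=True)
        assert path.read_text().startswith("<!DOCTYPE html>")

    def test_unknown_comment_target_rejected(self, monitored_state):
        with pytest.raises(KeyError):
            add_comment(monitored_state, "nope", DAY0, "x")


class TestRebaselineAndPersistence:
    def test_rebaseline_then_save_load_round_trip(self, registry, compact,
                                                  tmp_path):
        plan, config, machine_model = compact
        state = new_machine_state(MACHINE, registry=registry, config=config, T=5)
        (tmp_path / "logs").mkdir(exist_ok=True)
        for day in range(9):
            paths = _write_day(tmp_path / "logs", plan, machine_model, day)
            ingest_day(state, *paths)
        rebaseline_parameter(state, "pfn_voltage", 5)
        add_comment(state, "pfn_voltage", DAY0, "limits refreshed")
        save_state(state, tmp_path / "machine")
        restored = load_state(tmp_path / "machine")
        assert restored.machine_id == state.machine_id
        assert set(restored.samples) == set(state.samples)
        chart0 = state.chart("pfn_voltage")
        chart1 = restored.chart("pfn_voltage")
        assert chart1.i_limits.ucl == pytest.approx(chart0.i_limits.ucl)
        assert chart1.grand_mean == pytest.approx(chart0.grand_mean)
        assert restored.comments["pfn_voltage"] == state.comments["pfn_voltage"]
        # statuses replay identically
        assert {pid: c.status for pid, c in restored.charts.items()} == \
               {pid: c.status for pid, c in state.charts.items()}


class TestCli:
    def test_init_ingest_status_report_cycle(self, compact, tmp_path):
        plan, config, machine_model = compact
        runner = CliRunner()
        root = str(tmp_path / "root")
        result = runner.invoke(cli_main, ["init", "--machine", MACHINE,
                                          "--root", root, "--scale", str(SCALE)])
        assert result.exit_code == 0, result.output
        paths = _write_day(tmp_path, plan, machine_model, 0)
        result = runner.invoke(cli_main, ["ingest", "--machine", MACHINE,
                                          "--root", root, "--tlog", str(paths[0]),
                                          "--ttxt", str(paths[1])])
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, ["status", "--machine", MACHINE,
                                          "--root", root])
        assert result.exit_code == 0  # all green
        result = runner.invoke(cli_main, ["report", "--machine", MACHINE,
                                          "--root", root, "--out",
                                          str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / f"{MACHINE}-report.txt").exists()

    def test_simulate_command_writes_log_pairs(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "days"
        result = runner.invoke(cli_main, ["simulate", "--days", "2", "--seed",
                                          "5", "--out", str(out), "--scale",
                                          str(SCALE)])
        assert result.exit_code == 0, result.output
        assert len(list(out.glob("*.tlog.csv"))) == 2
        assert len(list(out.glob("*.ttxt"))) == 2

    def test_detect_study_command_is_deterministic(self, tmp_path):
        runner = CliRunner()
        args = ["detect-study", "--seed", "3", "--baseline-days", "5",
                "--monitor-days", "3", "--scale", str(SCALE)]
        result = runner.invoke(cli_main, args + ["--out",
                                                 str(tmp_path / "a.csv")])
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, args + ["--out",
                                                 str(tmp_path / "b.csv")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "a.csv").read_text() == (tmp_path / "b.csv").read_text()
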