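import datetime as dt

import pytest

from linacpdm import (build_default_registry, build_reference_traces,
                      default_delivery_plan, default_feature_config,
                      default_machine_model, extract_daily_sample,
                      simulate_text_snapshot, simulate_trajectory)

DAY0 = dt.date(2026, 1, 5)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def plan():
    """Full-scale delivery plan (4500 snapshots at 20 ms)."""
    return default_delivery_plan()


@pytest.fixture(scope="session")
def config():
    return default_feature_config()


@pytest.fixture(scope="session")
def machine():
    return default_machine_model()


@pytest.fixture(scope="session")
def noiseless_machine():
    return default_machine_model(noiseless=True)


@pytest.fixture(scope="session")
def noiseless_day(plan, noiseless_machine):
    """One noise-free log pair from the default plan."""
    tlog = simulate_trajectory(plan, noiseless_machine, "TB01", DAY0, seed=0)
    ttxt = simulate_text_snapshot(noiseless_machine, "TB01", DAY0, seed=0)
    return tlog, ttxt


@pytest.fixture(scope="session")
def noiseless_sample(noiseless_day, registry, config):
    tlog, ttxt = noiseless_day
    refs = build_reference_traces(tlog, config)
    sample = extract_daily_sample(tlog, ttxt, registry, refs, config)
    return sample, refs


# Compact (time-compressed) pipeline for multi-day orchestration tests.
SCALE = 8


@pytest.fixture(scope="session")
def compact():
    """(plan, config, machine) compressed 8x for fast multi-day tests."""
    return (default_delivery_plan(SCALE), default_feature_config(SCALE),
            default_machine_model())
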