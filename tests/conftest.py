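"""Shared expensive simulation fixtures (session-scoped, deterministic)."""

from __future__ import annotations

import pytest

from dynasep import run
from dynasep.fixtures import make_fixtures, run_msd_ensemble


@pytest.fixture(scope="session")
def tasep_runs():
    """Unit-step-limit runs, one per TASEP phase (MC, LD, HD)."""
    return {name: run(cfg) for name, cfg in make_fixtures("tasep").items()}


@pytest.fixture(scope="session")
def mc_high_run():
    """1D maximal-current run under high load (alpha = beta = 0.95)."""
    return run(make_fixtures("mc_high")["mc"])


@pytest.fixture(scope="session")
def mc_low_run():
    """1D maximal-current run under low load."""
    return run(make_fixtures("mc_low")["mc"])


@pytest.fixture(scope="session")
def ld_osc_run():
    """Quasi-2D low-load LD run with entrance-side oscillations."""
    return run(make_fixtures("ld_osc")["ld"])


@pytest.fixture(scope="session")
def hd_low_run():
    """Quasi-2D low-load HD run (bulk near 1 - beta)."""
    return run(make_fixtures("hd_low")["hd"])


@pytest.fixture(scope="session")
def msd_trajectories():
    """Ensemble of single-motor trajectories on the empty 500x4 cylinder."""
    return run_msd_ensemble(make_fixtures("single_msd")["runs"])


@pytest.fixture(scope="session")
def dwell_free_trajectories():
    """Class-A (first entrant) trajectories in an uncrowded filling system."""
    return run_msd_ensemble(make_fixtures("dwell")["free_A"])


@pytest.fixture(scope="session")
def dwell_congested_trajectories():
    """Late-entrant trajectories in a jammed high-density state."""
    return run_msd_ensemble(make_fixtures("dwell")["congested_C"])
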