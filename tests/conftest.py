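"""Shared fixtures: the expensive wildtype runs are computed once per session."""

from __future__ import annotations

import pytest

from startbycc import build_model
from startbycc.simulate import SimulationConfig, simulate, steady_cycle


@pytest.fixture(scope="session")
def wt_model():
    return build_model()


@pytest.fixture(scope="session")
def glucose_config():
    return SimulationConfig(t_end=300.0, mdt=90.0, lineage="daughter")


@pytest.fixture(scope="session")
def wt_traj(wt_model, glucose_config):
    """Wildtype daughter lineage over 300 min in glucose."""
    return simulate(wt_model, glucose_config)


@pytest.fixture(scope="session")
def wt_steady(wt_model, glucose_config):
    """Converged wildtype cycle metrics (division-map fixed point)."""
    sc = steady_cycle(wt_model, glucose_config)
    assert hasattr(sc, "cycle_time"), "wildtype must converge"
    return sc


@pytest.fixture(scope="session")
def wt_report(glucose_config):
    from startbycc.phenotype import characterize

    return characterize("wildtype", glucose_config)


@pytest.fixture(scope="session")
def screen_reports(glucose_config, wt_report):
    """Full built-in catalog screen; shared by battery and concordance tests."""
    from startbycc.mutants import builtin_catalog, run_catalog

    return run_catalog(builtin_catalog(), glucose_config, wildtype=wt_report)
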