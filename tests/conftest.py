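"""Shared fixtures.

The day-60 simulation fixtures are session-scoped because several tests
inspect different aspects of the same runs; they use the production solver
settings of the invasion model (dx = 0.01 cm, dt = 1e-3 day) and a slightly
coarsened proliferation mesh (51 nodes, tau = 5e-3 day) whose day-60
metrics differ from the fine-mesh solution by well under 0.1%.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirlung import invasion, params, proliferation, scenarios, sensitivity

DAILY = np.arange(0.0, 61.0, 1.0)


@pytest.fixture()
def inv_p() -> params.ParameterSet:
    return params.default_parameter_set("invasion")


@pytest.fixture()
def prolif_p() -> params.ParameterSet:
    return params.default_parameter_set("proliferation", normal_cell_rates="derived")


def _invasion_run(scenario: str | None) -> invasion.InvasionResult:
    p = params.default_parameter_set("invasion")
    if scenario is not None:
        p = scenarios.apply(p, scenarios.builtin_scenario(scenario))
    return invasion.run_invasion(p, t_end=60.0, record_times=DAILY)


@pytest.fixture(scope="session")
def control_run() -> invasion.InvasionResult:
    return _invasion_run(None)


@pytest.fixture(scope="session")
def anti_m1_run() -> invasion.InvasionResult:
    return _invasion_run("anti_m1")


@pytest.fixture(scope="session")
def anti_m1_m2_run() -> invasion.InvasionResult:
    return _invasion_run("anti_m1_m2")


@pytest.fixture(scope="session")
def mutation_runs() -> dict[str, invasion.InvasionResult]:
    return {name: _invasion_run(name) for name in ("mut_EGFR", "mut_MAPK", "mut_AKT")}


@pytest.fixture(scope="session")
def refined_control_run() -> invasion.InvasionResult:
    """Control invasion run with dx and dt both halved."""
    p = params.default_parameter_set("invasion")
    return invasion.run_invasion(p, grid=invasion.make_grid(0.005), t_end=60.0,
                                 dt=5e-4, record_times=np.array([0.0, 60.0]))


@pytest.fixture(scope="session")
def chi_sweep_table():
    """Three-point chi sweep under the EGFR mutation, both arms."""
    p = params.default_parameter_set("invasion")
    return scenarios.chi_sweep(p, chi_values=[3e-4, 3e-3, 3e-2],
                               scenario=scenarios.builtin_scenario("mut_EGFR"))


@pytest.fixture(scope="session")
def prolif_run() -> proliferation.ProliferationResult:
    """Free-boundary run with the text-derived normal-cell rates."""
    p = params.default_parameter_set("proliferation", normal_cell_rates="derived")
    return proliferation.run_proliferation(p, t_end=60.0, tau=5e-3, n_nodes=51)


@pytest.fixture(scope="session")
def prolif_run_table() -> proliferation.ProliferationResult:
    """Free-boundary run with the tabulated normal-cell rates (coarse)."""
    p = params.default_parameter_set("proliferation", normal_cell_rates="table")
    return proliferation.run_proliferation(p, t_end=60.0, tau=2e-2,
                                           record_times=np.array([0.0, 60.0]),
                                           n_nodes=31)


@pytest.fixture(scope="session")
def sens_result() -> sensitivity.SensitivityResult:
    """Scaled-down LHS/PRCC study (n = 100) of the day-60 tumor radius."""
    p = params.default_parameter_set("proliferation", normal_cell_rates="derived")
    design = sensitivity.default_design(p, n=100, seed=1)
    return sensitivity.run_sensitivity(p, design)
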