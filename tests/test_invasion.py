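"""1-D invasion solver: initialization, conservation/fixed-point behavior,
front and mass metrics, short-horizon grid convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlung import invasion, kinetics, scenarios
from mirlung.invasion import (
    InvasionGrid,
    advance,
    front_position,
    initialize_invasion,
    linear_mass,
    make_grid,
    run_invasion,
)
from mirlung.params import default_parameter_set


@pytest.fixture()
def p():
    return default_parameter_set("invasion")


@pytest.fixture()
def grid():
    return make_grid(0.02)


def test_grid_construction():
    g = make_grid(0.01)
    assert g.nodes[0] == 0.0 and g.nodes[-1] == 2.0
    assert g.spacing == pytest.approx(0.01)
    with pytest.raises(ValueError):
        InvasionGrid(np.array([0.0, 0.5, 0.4, 2.0]))
    with pytest.raises(ValueError):
        InvasionGrid(np.array([0.1, 0.5, 2.0]))


def test_initialization(p, grid):
    st0 = initialize_invasion(p, grid)
    C = st0.fields["C"]
    assert C[0] == pytest.approx(0.4)
    assert np.all(C[1:] == 0.0)
    assert st0.fields["m1"][0] == pytest.approx(p.steady.m_10)
    assert st0.fields["m1i"][0] == pytest.approx(p.steady.gamma * p.steady.m_10)
    assert st0.fields["E"][0] == 0.0  # proteins start at zero everywhere
    assert front_position(C, grid, C_ref=p.steady.C_0) == 0.0
    # boundary node contributes only half a cell of mass
    assert linear_mass(C, grid) == pytest.approx(0.4 * grid.spacing / 2)


def test_steady_profile_is_a_fixed_point(p, grid):
    """A spatially constant steady-state profile matching the Dirichlet
    values is unchanged by a time step (all reactions and fluxes vanish)."""
    st0 = initialize_invasion(p, grid)
    s = kinetics.steady_point_state(p)
    for name in invasion.FIELDS:
        st0.fields[name] = np.full(grid.n, getattr(s, name))
    st1 = advance(st0, p, dt=1e-3)
    for name in invasion.FIELDS:
        scale = max(abs(float(st0.fields[name][0])), 1e-300)
        assert np.max(np.abs(st1.fields[name] - st0.fields[name])) < 1e-9 * scale, name


def test_pulse_unchanged_with_transport_and_kinetics_off(p, grid):
    """With chi = 0, D_C = 0 and growth/death zeroed an isolated C pulse
    does not move or change."""
    p.chi = 0.0
    p.D_C = 0.0
    p.lam_C1 = p.lam_C2 = 0.0
    p.d_C = p.d_D = 0.0
    st0 = initialize_invasion(p, grid)
    st0.fields["C"] = np.zeros(grid.n)
    st0.fields["C"][40:45] = 0.2
    st0.fields["C"][0] = p.steady.C_0
    state = st0
    for _ in range(20):
        state = advance(state, p, dt=1e-3)
    # interior pulse is exactly preserved (m1i/m2i also carry D_C = 0)
    assert np.allclose(state.fields["C"][1:], st0.fields["C"][1:], atol=1e-12)


def test_front_position_cases(grid):
    C0 = 0.4
    assert front_position(np.zeros(grid.n), grid, C_ref=C0) == 0.0
    step = np.where(grid.nodes <= 0.5, C0, 0.0)
    f = front_position(step, grid, C_ref=C0)
    assert abs(f - 0.5) <= grid.spacing
    with pytest.raises(ValueError):
        front_position(step, grid, threshold_fraction=1.5)


@given(st.floats(0.0, 0.2))
@settings(max_examples=20, deadline=None)
def test_front_is_monotone_under_pointwise_increase(bump):
    grid = make_grid(0.02)
    x = grid.nodes
    base = 0.4 * np.exp(-3.0 * x)
    higher = base + bump * np.exp(-x)
    f0 = front_position(base, grid, C_ref=0.4)
    f1 = front_position(higher, grid, C_ref=0.4)
    assert f1 >= f0


def test_linear_mass_quadrature(grid):
    assert linear_mass(np.full(grid.n, 0.3), grid) == pytest.approx(0.6)
    assert linear_mass(np.zeros(grid.n), grid) == 0.0
    with pytest.raises(ValueError):
        linear_mass(np.full(grid.n, -1.0), grid)
    # trapezoid error falls as dx^2 on a smooth profile
    exact = (1 - np.cos(2.0)) / 1.0
    errs = []
    for dx in (0.02, 0.01):
        g = make_grid(dx)
        errs.append(abs(linear_mass(np.sin(g.nodes), g) - exact))
    assert errs[1] < errs[0] / 3.5


def test_short_horizon_grid_convergence(p):
    """Production grid vs refined grid at day 5: metrics agree within 1%."""
    coarse = run_invasion(p, grid=make_grid(0.01), t_end=5.0, dt=1e-3,
                          record_times=np.array([0.0, 5.0]))
    fine = run_invasion(p, grid=make_grid(0.005), t_end=5.0, dt=2.5e-4,
                        record_times=np.array([0.0, 5.0]))
    assert coarse.front_position[-1] == pytest.approx(fine.front_position[-1], rel=0.01)
    assert coarse.linear_mass_C[-1] == pytest.approx(fine.linear_mass_C[-1], rel=0.01)


def test_run_zero_horizon_matches_initialization(p, grid):
    res = run_invasion(p, grid=grid, t_end=0.0, record_times=np.array([0.0]))
    assert res.times.tolist() == [0.0]
    assert res.front_position[0] == 0.0
    assert res.linear_mass_C[0] == pytest.approx(0.4 * grid.spacing / 2)


def test_short_run_nonnegative_and_front_monotone(p, grid):
    res = run_invasion(p, grid=grid, t_end=8.0, dt=2e-3,
                       record_times=np.arange(0.0, 9.0),
                       snapshot_times=(4.0, 8.0))
    assert np.all(np.diff(res.front_position) >= -1e-12)
    assert np.all(res.linear_mass_C >= 0.0)
    for snap in res.snapshots.values():
        for name, arr in snap.items():
            assert np.all(arr >= 0.0), name


def test_anti_mir_slows_front_short_horizon(p, grid):
    treated_p = scenarios.apply(p, scenarios.builtin_scenario("anti_m1"))
    rec = np.array([0.0, 15.0])
    control = run_invasion(p, grid=grid, t_end=15.0, dt=2e-3, record_times=rec)
    treated = run_invasion(treated_p, grid=grid, t_end=15.0, dt=2e-3, record_times=rec)
    assert treated.front_position[-1] < control.front_position[-1]
    assert treated.linear_mass_C[-1] < control.linear_mass_C[-1]


def test_mass_metric_pool_switch(p, grid):
    rec = np.array([0.0, 5.0])
    with_cellular = run_invasion(p, grid=grid, t_end=5.0, dt=2e-3, record_times=rec,
                                 mass_includes_cellular=True)
    exosomal_only = run_invasion(p, grid=grid, t_end=5.0, dt=2e-3, record_times=rec,
                                 mass_includes_cellular=False)
    assert with_cellular.linear_mass_m1[-1] > exosomal_only.linear_mass_m1[-1]


def test_invalid_arguments(p, grid):
    with pytest.raises(ValueError):
        run_invasion(p, grid=grid, t_end=-1.0)
    with pytest.raises(ValueError):
        advance(initialize_invasion(p, grid), p, dt=0.0)
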