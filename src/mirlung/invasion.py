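"""1-D tumor-front invasion model on x in [0, 2] cm.

A solid tumor occupies x < 0 and its planar front invades the strip [0, 2].
Exosomes, both miR pools and cancer cells diffuse; cancer cells additionally
undergo directed migration down their own density gradient via the nonlinear
conservative flux chi * C * dC/dx (competition for space).  The intracellular
proteins have no spatial operator and evolve pointwise.

Boundary conditions: Dirichlet values at x = 0 (the tumor bulk holds E_C, m1,
m2, C -- and the cellular miR pools -- at their steady states) and no-flux at
x = 2.  Initial conditions are zero everywhere.

Numerics: uniform grid (default dx = 0.01 cm), semi-implicit time stepping --
linear diffusion implicit (banded solves), reactions and the chi-flux
explicit (default dt = 1e-3 day, automatically halved if a step produces
significantly negative densities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from . import kinetics
from .params import ParameterSet

__all__ = [
    "InvasionGrid",
    "InvasionState",
    "InvasionResult",
    "make_grid",
    "initialize_invasion",
    "advance",
    "run_invasion",
    "front_position",
    "linear_mass",
]

logger = logging.getLogger(__name__)

#: fields carried on the grid, in storage order
FIELDS = ("E", "M", "A", "T", "P", "Ap", "E_C", "m1", "m2", "m1i", "m2i", "C")
_DIFFUSIVE = ("E_C", "m1", "m2", "m1i", "m2i", "C")
DOMAIN_LENGTH = 2.0


@dataclass
class InvasionGrid:
    """Uniform grid of node positions on [0, 2] cm."""

    nodes: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.nodes, dtype=float)
        if x[0] != 0.0 or x[-1] != DOMAIN_LENGTH or np.any(np.diff(x) <= 0):
            raise ValueError("grid nodes must increase strictly from 0 to 2 cm")
        self.nodes = x

    @property
    def spacing(self) -> float:
        return float(self.nodes[1] - self.nodes[0])

    @property
    def n(self) -> int:
        return len(self.nodes)


def make_grid(dx: float = 0.01) -> InvasionGrid:
    n = int(round(DOMAIN_LENGTH / dx)) + 1
    return InvasionGrid(np.linspace(0.0, DOMAIN_LENGTH, n))


@dataclass
class InvasionState:
    """Spatial profiles of all 12 fields at one time."""

    time: float
    fields: dict[str, np.ndarray]
    grid: InvasionGrid

    def copy(self) -> "InvasionState":
        return InvasionState(self.time, {k: v.copy() for k, v in self.fields.items()},
                             self.grid)


@dataclass
class InvasionResult:
    """Time series of invasion summary metrics (plus optional snapshots)."""

    times: np.ndarray
    front_position: np.ndarray
    linear_mass_C: np.ndarray
    linear_mass_m1: np.ndarray
    linear_mass_m2: np.ndarray
    snapshots: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)
    final_state: InvasionState | None = None

    def at(self, day: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.times - day)))
        if abs(self.times[i] - day) > 0.5:
            raise ValueError(f"day {day} was not recorded")
        return {
            "time": float(self.times[i]),
            "front": float(self.front_position[i]),
            "mass_C": float(self.linear_mass_C[i]),
            "mass_m1": float(self.linear_mass_m1[i]),
            "mass_m2": float(self.linear_mass_m2[i]),
        }


def _dirichlet_values(p: ParameterSet) -> dict[str, float]:
    ss = p.steady
    return {
        "E_C": ss.E_C0, "m1": ss.m_10, "m2": ss.m_20,
        "m1i": ss.gamma * ss.m_10, "m2i": ss.gamma * ss.m_20,
        "C": ss.C_0,
    }


def initialize_invasion(p: ParameterSet, grid: InvasionGrid) -> InvasionState:
    """Zero fields on (0, 2]; Dirichlet steady-state values at x = 0 for the
    transported species.  Proteins start at zero everywhere (they build up as
    the C/C_0 factor turns on)."""
    fields = {name: np.zeros(grid.n) for name in FIELDS}
    for name, value in _dirichlet_values(p).items():
        fields[name][0] = value
    return InvasionState(0.0, fields, grid)


class NumericalFailure(RuntimeError):
    """A time step produced significantly negative densities; retry with a
    smaller dt."""


def _banded_matrix(n: int, mu: float, dirichlet: bool) -> np.ndarray:
    """Banded (ab) form of I - mu*L for the 1-D Laplacian with a Dirichlet
    row at node 0 (or symmetric no-flux) and no-flux at node n-1."""
    ab = np.zeros((3, n))
    ab[0, 1:] = -mu                 # superdiagonal
    ab[1, :] = 1.0 + 2.0 * mu       # diagonal
    ab[2, :-1] = -mu                # subdiagonal
    if dirichlet:
        ab[1, 0] = 1.0
        ab[0, 1] = 0.0
    else:  # no-flux left: ghost mirror
        ab[0, 1] = -2.0 * mu
    ab[2, -2] = -2.0 * mu           # no-flux right
    return ab


class _DiffusionSolver:
    """Caches the banded factors of the implicit diffusion operators."""

    def __init__(self, p: ParameterSet, dx: float, dt: float, n: int):
        self.dt = dt
        self.ab = {}
        for name in _DIFFUSIVE:
            D = getattr(p, {"E_C": "D_Ec", "m1": "D_m1", "m2": "D_m2",
                            "m1i": "D_C", "m2i": "D_C", "C": "D_C"}[name])
            self.ab[name] = _banded_matrix(n, D * dt / dx**2, dirichlet=True)

    def solve(self, name: str, rhs: np.ndarray) -> np.ndarray:
        return solve_banded((1, 1), self.ab[name], rhs)


def _chi_flux_divergence(C: np.ndarray, chi: float, dx: float) -> np.ndarray:
    """Conservative d/dx(chi * C * dC/dx) with fluxes at half-nodes; zero
    flux through both ends (the x=0 node is overwritten by Dirichlet)."""
    flux = chi * 0.5 * (C[1:] + C[:-1]) * np.diff(C) / dx
    div = np.zeros_like(C)
    div[1:-1] = np.diff(flux) / dx
    div[0] = flux[0] / dx
    div[-1] = -flux[-1] / dx
    return div


def _clip_negatives(fields: dict[str, np.ndarray], state_time: float) -> None:
    """Round-off negatives are clipped to zero; larger ones are a failure."""
    for name, arr in fields.items():
        neg = arr < 0
        if not np.any(neg):
            continue
        scale = max(float(arr.max()), 1e-16)
        worst = float(arr[neg].min())
        if worst < -1e-6 * scale:
            raise NumericalFailure(
                f"{name} reached {worst:.3e} (scale {scale:.3e}) at t={state_time:.4f};"
                " reduce dt")
        logger.debug("clipped %d round-off negatives in %s at t=%.4f",
                     int(neg.sum()), name, state_time)
        arr[neg] = 0.0


def advance(state: InvasionState, p: ParameterSet, dt: float,
            solver: _DiffusionSolver | None = None) -> InvasionState:
    """One semi-implicit time step.

    Explicit: protein ODEs, all reaction terms, the chi-flux.  Implicit:
    linear diffusion of E_C, m1, m2, m1i, m2i, C.  Dirichlet at x = 0 for the
    transported fields, no-flux at x = 2.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = state.grid
    if solver is None or solver.dt != dt:
        solver = _DiffusionSolver(p, grid.spacing, dt, grid.n)
    f = state.fields
    s = kinetics.PointState(**{k: f[k] for k in FIELDS})
    rates = kinetics.all_rates(s, p, phase="invasion", check=False)

    new = {}
    for name in ("E", "M", "A", "T", "P", "Ap"):
        new[name] = f[name] + dt * getattr(rates, name)
    bc = _dirichlet_values(p)
    for name in _DIFFUSIVE:
        rhs = f[name] + dt * getattr(rates, name)
        if name == "C":
            rhs = rhs + dt * _chi_flux_divergence(f["C"], p.chi, grid.spacing)
        rhs[0] = bc[name]
        new[name] = solver.solve(name, rhs)
    _clip_negatives(new, state.time + dt)
    return InvasionState(state.time + dt, new, grid)


def front_position(C_profile: np.ndarray, grid: InvasionGrid,
                   threshold_fraction: float = 0.1,
                   C_ref: float | None = None) -> float:
    """Largest x with C >= threshold_fraction * C_ref (linear interpolation
    between nodes); 0 if the threshold is nowhere reached.

    ``C_ref`` defaults to the x=0 boundary value C(0) of the profile.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    C = np.asarray(C_profile, dtype=float)
    x = grid.nodes
    thr = threshold_fraction * (float(C[0]) if C_ref is None else C_ref)
    if thr <= 0:
        return 0.0
    above = np.nonzero(C >= thr)[0]
    if len(above) == 0:
        return 0.0
    i = above[-1]
    if i == 0:
        # only the Dirichlet boundary node is above threshold: the front has
        # not yet advanced into the domain
        return 0.0
    if i == len(C) - 1:
        return float(x[-1])
    # interpolate between the last node above and the next node below
    c0, c1 = C[i], C[i + 1]
    if c0 == c1:
        return float(x[i])
    return float(x[i] + (c0 - thr) / (c0 - c1) * (x[i + 1] - x[i]))


def linear_mass(profile: np.ndarray, grid: InvasionGrid) -> float:
    """Trapezoidal integral of a 1-D density profile over [0, 2] (g/cm^2)."""
    if np.any(np.asarray(profile) < 0):
        raise ValueError("profile must be nonnegative")
    return float(np.trapezoid(profile, grid.nodes))


def run_invasion(
    p: ParameterSet,
    grid: InvasionGrid | None = None,
    t_end: float = 60.0,
    dt: float = 1e-3,
    record_times: np.ndarray | None = None,
    snapshot_times: tuple[float, ...] = (),
    threshold_fraction: float = 0.1,
    mass_includes_cellular: bool = True,
    max_halvings: int = 6,
) -> InvasionResult:
    """Run the invasion model to ``t_end`` days, recording front position and
    linear masses at ``record_times`` (default: every day).

    ``mass_includes_cellular`` controls whether the total miR masses include
    the cellular pools (m1 + m1i) or only the exosomal ones.  The front
    threshold is ``threshold_fraction * C_0``.  On numerical failure the time
    step is halved (up to ``max_halvings`` times) and the run continues.
    """
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    grid = grid or make_grid()
    if record_times is None:
        record_times = np.arange(0.0, t_end + 1e-9, 1.0)
    record_times = np.asarray(record_times, dtype=float)
    snapshot_set = sorted(snapshot_times)
    state = initialize_invasion(p, grid)
    C0 = p.steady.C_0

    times, fronts, mC, m1m, m2m = [], [], [], [], []
    snapshots: dict[float, dict[str, np.ndarray]] = {}

    def record(st: InvasionState) -> None:
        times.append(st.time)
        fronts.append(front_position(st.fields["C"], grid, threshold_fraction, C_ref=C0))
        mC.append(linear_mass(st.fields["C"], grid))
        pm1 = st.fields["m1"] + st.fields["m1i"] if mass_includes_cellular else st.fields["m1"]
        pm2 = st.fields["m2"] + st.fields["m2i"] if mass_includes_cellular else st.fields["m2"]
        m1m.append(linear_mass(pm1, grid))
        m2m.append(linear_mass(pm2, grid))

    rec_iter = iter(record_times)
    next_rec = next(rec_iter, None)
    snap_iter = iter(snapshot_set)
    next_snap = next(snap_iter, None)
    if next_rec is not None and next_rec <= 1e-12:
        record(state)
        next_rec = next(rec_iter, None)
    if next_snap is not None and next_snap <= 1e-12:
        snapshots[0.0] = {k: v.copy() for k, v in state.fields.items()}
        next_snap = next(snap_iter, None)

    solver = _DiffusionSolver(p, grid.spacing, dt, grid.n)
    halvings = 0
    while state.time < t_end - 1e-12:
        step = min(dt, t_end - state.time)
        if next_rec is not None:
            step = min(step, next_rec - state.time + 1e-15)
        if next_snap is not None:
            step = min(step, next_snap - state.time + 1e-15)
        try:
            if solver.dt != step:
                solver = _DiffusionSolver(p, grid.spacing, step, grid.n)
            state = advance(state, p, step, solver)
        except NumericalFailure:
            halvings += 1
            if halvings > max_halvings:
                raise
            dt /= 2.0
            logger.warning("halving dt to %.2e day after instability", dt)
            continue
        if next_rec is not None and state.time >= next_rec - 1e-9:
            record(state)
            next_rec = next(rec_iter, None)
        if next_snap is not None and state.time >= next_snap - 1e-9:
            snapshots[float(next_snap)] = {k: v.copy() for k, v in state.fields.items()}
            next_snap = next(snap_iter, None)

    return InvasionResult(
        times=np.asarray(times),
        front_position=np.asarray(fronts),
        linear_mass_C=np.asarray(mC),
        linear_mass_m1=np.asarray(m1m),
        linear_mass_m2=np.asarray(m2m),
        snapshots=snapshots,
        final_state=state,
    )
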