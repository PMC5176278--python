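"""Spherically symmetric free-boundary tumor proliferation model.

A small spherical tumor of radius R(t) grows from R(0) = 0.01 cm.  Inside the
tumor the combined density of cancer (C) and normal (N) cells is constant,
C + N = theta = 0.6 g/cm^3; net cell production therefore drives a radial
bulk velocity u(r,t),

    u(r,t) = (1/(theta r^2)) * Int_0^r xi^2 [ growth(N) + growth(C)
                                              - death(N) - death(C) ] dxi,

and the free boundary moves with the cells, dR/dt = u(R,t).

Numerics: a moving mesh whose nodes are advected by u (Lagrangian frame, so
the advective derivative is absorbed into the node motion and the remaining
transport term is the dilution -(div u) X), fully implicit time stepping with
damped Picard iteration on the nonlinear couplings, nonuniform-grid
3-point difference formulas for the spherical Laplacian, symmetry at r = 0
and no-flux at r = R.  Proteins (no spatial operator) advance pointwise at
each node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.linalg import solve_banded

from . import kinetics
from .params import ParameterSet

__all__ = [
    "RadialMesh",
    "ProliferationState",
    "ProliferationResult",
    "EQ20_INITIAL",
    "initialize_proliferation",
    "velocity_field",
    "advance_moving_mesh",
    "run_proliferation",
]

logger = logging.getLogger(__name__)

FIELDS = ("E", "M", "A", "T", "P", "Ap", "E_C", "m1", "m2", "m1i", "m2i", "C", "N")
_SPATIAL = ("E_C", "m1", "m2", "m1i", "m2i", "C", "N")
_PROTEINS = ("E", "M", "A", "T", "P", "Ap")

#: initial interior concentrations (g/cm^3): growth inhibitors start above
#: their steady states, promoters below; cell densities sum to < theta so the
#: tumor initially compresses toward the constraint
EQ20_INITIAL = {
    "E": 6.7044e-4,
    "M": 7.14e-6,
    "A": 7.396e-7,
    "T": 1.0206e-4,
    "P": 2.2748e-7,
    "Ap": 3.4648e-5,
    "E_C": 3.6e-12,
    "m1": 2.8e-15,
    "m2": 1.4e-15,
    "C": 0.35,
    "N": 0.25,
}

R_INITIAL = 0.01  # cm


@dataclass
class RadialMesh:
    """Strictly increasing node radii from 0 to the current tumor radius."""

    nodes: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.nodes, dtype=float)
        if r[0] != 0.0 or np.any(np.diff(r) <= 0):
            raise ValueError("mesh nodes must increase strictly from 0")
        self.nodes = r

    @property
    def radius(self) -> float:
        return float(self.nodes[-1])

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class ProliferationState:
    time: float
    mesh: RadialMesh
    fields: dict[str, np.ndarray]
    velocity: np.ndarray | None = None
    last_residual: float = 0.0

    def copy(self) -> "ProliferationState":
        return ProliferationState(
            self.time, RadialMesh(self.mesh.nodes.copy()),
            {k: v.copy() for k, v in self.fields.items()},
            None if self.velocity is None else self.velocity.copy(),
            self.last_residual,
        )


@dataclass
class ProliferationResult:
    """Time series of the free-boundary run: radius, volume, volume-weighted
    averages of every variable, and total miR / cancer masses (g)."""

    times: np.ndarray
    radius_cm: np.ndarray
    volume_cm3: np.ndarray
    averages: dict[str, np.ndarray]
    total_mass_m1: np.ndarray
    total_mass_m2: np.ndarray
    total_mass_C: np.ndarray
    max_CN_deviation: float = 0.0
    max_residual: float = 0.0
    final_state: ProliferationState | None = None

    def at(self, day: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.times - day)))
        if abs(self.times[i] - day) > 0.5:
            raise ValueError(f"day {day} was not recorded")
        out = {"time": float(self.times[i]), "radius": float(self.radius_cm[i]),
               "volume": float(self.volume_cm3[i]),
               "mass_m1": float(self.total_mass_m1[i]),
               "mass_m2": float(self.total_mass_m2[i]),
               "mass_C": float(self.total_mass_C[i])}
        out.update({f"avg_{k}": float(v[i]) for k, v in self.averages.items()})
        return out


def initialize_proliferation(p: ParameterSet, n_nodes: int = 101) -> ProliferationState:
    """Uniform initial profiles on a uniform mesh of ``n_nodes`` nodes.

    The cellular miR pools (absent from the tabulated initial conditions) are
    started at gamma times their exosomal counterparts, the same
    cellular:exosomal ratio used for the steady state.
    """
    if p.phase != "proliferation":
        raise ValueError("initialize_proliferation requires a proliferation-phase ParameterSet")
    r = np.linspace(0.0, R_INITIAL, n_nodes)
    g = p.steady.gamma
    fields = {k: np.full(n_nodes, v) for k, v in EQ20_INITIAL.items()}
    fields["m1i"] = np.full(n_nodes, g * EQ20_INITIAL["m1"])
    fields["m2i"] = np.full(n_nodes, g * EQ20_INITIAL["m2"])
    return ProliferationState(0.0, RadialMesh(r), fields)


def _net_cell_source(f: dict[str, np.ndarray], p: ParameterSet) -> np.ndarray:
    """Net volumetric cell production (g cm^-3 day^-1): growth of C and N
    minus all death terms -- the source of the velocity field."""
    return (
        kinetics.growth_rate(f["M"], f["A"], f["C"], f["N"], p, "proliferation", check=False)
        + kinetics.normal_growth_rate(f["N"], f["C"], p, check=False)
        - kinetics.death_rate(f["C"], f["Ap"], p, "cancer", check=False)
        - kinetics.death_rate(f["N"], f["Ap"], p, "normal", check=False)
    )


def velocity_field(state: ProliferationState, p: ParameterSet,
                   source: np.ndarray | None = None) -> np.ndarray:
    """Radial velocity u(r) from the incompressibility constraint, by
    trapezoidal quadrature of the cell-source integral; u(0) = 0."""
    r = state.mesh.nodes
    s = _net_cell_source(state.fields, p) if source is None else source
    integrand = r * r * s
    integral = np.concatenate(([0.0], np.cumsum(
        0.5 * (integrand[1:] + integrand[:-1]) * np.diff(r))))
    u = np.zeros_like(r)
    u[1:] = integral[1:] / (p.steady.theta * r[1:] ** 2)
    return u


def _laplacian_bands(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """3-point nonuniform-grid spherical Laplacian f_rr + (2/r) f_r as
    (lower, diag, upper) coefficient arrays.  Symmetry at r=0
    (Delta f(0) = 6 (f_1 - f_0)/h^2), mirrored ghost no-flux at r=R."""
    n = len(r)
    lo, di, up = np.zeros(n), np.zeros(n), np.zeros(n)
    hm = r[1:-1] - r[:-2]
    hp = r[2:] - r[1:-1]
    denom = hm * hp * (hm + hp)
    # second derivative part
    a_lo = 2.0 * hp / denom
    a_up = 2.0 * hm / denom
    # first derivative part, times 2/r
    two_r = 2.0 / r[1:-1]
    b_lo = -two_r * hp * hp / denom
    b_up = two_r * hm * hm / denom
    lo[1:-1] = a_lo + b_lo
    up[1:-1] = a_up + b_up
    di[1:-1] = -(lo[1:-1] + up[1:-1])
    h0 = r[1] - r[0]
    up[0] = 6.0 / h0**2
    di[0] = -up[0]
    hN = r[-1] - r[-2]
    lo[-1] = 2.0 / hN**2
    di[-1] = -lo[-1]
    return lo, di, up


def _decay_coefficients(f: dict[str, np.ndarray], p: ParameterSet) -> dict[str, np.ndarray]:
    """Per-field linear self-decay rates treated implicitly in the solve."""
    apopt = f["Ap"] / (p.K_Ap + f["Ap"])
    return {
        "E_C": p.d_Ec * f["C"] / (p.K_C + f["C"]),
        "m1": p.d_m1, "m2": p.d_m2, "m1i": p.d_m1, "m2i": p.d_m2,
        "C": p.d_D * apopt + p.d_C,
        "N": p.d_DN * apopt + p.d_N,
    }


def _productions(f: dict[str, np.ndarray], p: ParameterSet) -> dict[str, np.ndarray]:
    """Per-field production terms (everything except the implicit decay)."""
    uptake = f["C"] / (p.K_C + f["C"])
    return {
        "E_C": p.lam_Ec * f["C"],
        "m1": p.lam_m1 * f["E_C"] * uptake,
        "m2": p.lam_m2 * f["E_C"] * uptake,
        "m1i": p.lam_m1i * f["C"],
        "m2i": p.lam_m2i * f["C"],
        "C": kinetics.growth_rate(f["M"], f["A"], f["C"], f["N"], p,
                                  "proliferation", check=False),
        "N": kinetics.normal_growth_rate(f["N"], f["C"], p, check=False),
    }


def _advance_proteins(f_old: dict[str, np.ndarray], f_cur: dict[str, np.ndarray],
                      p: ParameterSet, tau: float) -> dict[str, np.ndarray]:
    """Implicit pointwise update of the six protein ODEs, productions
    evaluated at the current Picard iterate."""
    scale = f_cur["C"] / p.steady.C_0
    prod = {
        "E": p.lam_E / (1.0 + f_cur["M"] / p.K_ME),
        "M": p.lam_M * f_cur["E"] / (1.0 + f_cur["T"] / p.K_TM),
        "A": (p.lam_A * f_cur["E"] / (1.0 + f_cur["P"] / p.K_PA)
              / (1.0 + f_cur["T"] / p.K_TA)
              * (1.0 + p.lam_MA * f_cur["M"] / (p.K_MA + f_cur["M"]))),
        "T": p.lam_T / (1.0 + 0.5 * (f_cur["m1"] + f_cur["m1i"]) / p.K_mT),
        "P": p.lam_P / (1.0 + (f_cur["m1"] + f_cur["m1i"]) / p.K_mP),
        "Ap": p.lam_Ap / (1.0 + (f_cur["m2"] + f_cur["m2i"]) / p.K_m2),
    }
    deg = {"E": p.d_E, "M": p.d_M, "A": p.d_A, "T": p.d_T, "P": p.d_P, "Ap": p.d_Ap}
    return {k: (f_old[k] + tau * scale * prod[k]) / (1.0 + tau * scale * deg[k])
            for k in _PROTEINS}


class ConvergenceFailure(RuntimeError):
    """The implicit solve did not converge within the iteration cap; retry
    with a smaller time step."""


def advance_moving_mesh(
    state: ProliferationState,
    p: ParameterSet,
    tau: float,
    *,
    max_iter: int = 50,
    rtol: float = 5e-13,
    force_zero_velocity: bool = False,
) -> ProliferationState:
    """One fully implicit step of the free-boundary problem.

    Picard iteration: velocity and mesh, protein update, then one
    tridiagonal solve per spatial field with the dilution term -(div u) X and
    the linear self-decay implicit and the remaining couplings lagged.
    Convergence is measured as the largest relative change of any field
    between iterates; the returned state carries the residual estimate.

    ``force_zero_velocity`` freezes the mesh and suppresses dilution -- used
    for verification against a method-of-lines reference.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    r_old = state.mesh.nodes
    f_old = state.fields
    scales = {k: max(float(np.max(np.abs(v))), 1e-300) for k, v in f_old.items()}

    f_cur = {k: v.copy() for k, v in f_old.items()}
    r_new = r_old
    last_change = np.inf
    prev_change = np.inf
    for it in range(max_iter):
        if force_zero_velocity:
            u = np.zeros_like(r_old)
            divu = np.zeros_like(r_old)
            r_new = r_old
        else:
            src = _net_cell_source(f_cur, p)
            u = velocity_field(ProliferationState(state.time, RadialMesh(r_old), f_cur), p, src)
            divu = src / p.steady.theta
            r_new = r_old + tau * u
            if np.any(np.diff(r_new) <= 0):
                raise ConvergenceFailure("mesh nodes crossed; reduce tau")

        f_next = _advance_proteins(f_old, f_cur, p, tau)
        lo, di, up = _laplacian_bands(r_new)
        decay = _decay_coefficients(f_cur, p)
        prod = _productions(f_cur, p)
        n = len(r_new)
        ab = np.zeros((3, n))
        for name in _SPATIAL:
            D = getattr(p, {"E_C": "D_Ec", "m1": "D_m1", "m2": "D_m2",
                            "m1i": "D_C", "m2i": "D_C",
                            "C": "D_C", "N": "D_N"}[name])
            ab[0, 1:] = -tau * D * up[:-1]
            ab[1, :] = 1.0 + tau * (divu + decay[name]) - tau * D * di
            ab[2, :-1] = -tau * D * lo[1:]
            f_next[name] = solve_banded((1, 1), ab, f_old[name] + tau * prod[name])

        change = max(
            float(np.max(np.abs(f_next[k] - f_cur[k]))) / scales[k] for k in FIELDS
        )
        f_cur = f_next
        last_change = change
        # converged, or stagnating on a round-off plateau well below the
        # residual contract
        if change < rtol or (change < 1e-10 and change >= prev_change):
            break
        prev_change = change
    else:
        raise ConvergenceFailure(
            f"implicit solve did not reach rtol={rtol} in {max_iter} iterations "
            f"(last change {last_change:.2e}); reduce tau")

    for name, arr in f_cur.items():
        neg = arr < 0
        if np.any(neg):
            worst = float(arr[neg].min())
            if worst < -1e-6 * scales[name]:
                raise ConvergenceFailure(f"{name} reached {worst:.3e}; reduce tau")
            arr[neg] = 0.0

    new = ProliferationState(state.time + tau, RadialMesh(r_new), f_cur, u,
                             last_residual=_residual(f_old, f_cur, r_new, divu, p, tau))
    min_dr = float(np.min(np.diff(r_new)))
    if min_dr < 1e-4 * new.mesh.radius:
        logger.info("remeshing at t=%.3f (min spacing %.2e)", new.time, min_dr)
        _remesh_uniform(new)
    return new


def _residual(f_old, f_new, r, divu, p: ParameterSet, tau: float) -> float:
    """Max absolute residual of the discrete spatial-field equations at the
    converged iterate (normalized by each field's scale)."""
    lo, di, up = _laplacian_bands(r)
    decay = _decay_coefficients(f_new, p)
    prod = _productions(f_new, p)
    worst = 0.0
    for name in _SPATIAL:
        D = getattr(p, {"E_C": "D_Ec", "m1": "D_m1", "m2": "D_m2",
                        "m1i": "D_C", "m2i": "D_C", "C": "D_C", "N": "D_N"}[name])
        X = f_new[name]
        lap = di * X
        lap[:-1] += up[:-1] * X[1:]
        lap[1:] += lo[1:] * X[:-1]
        res = (X - f_old[name]) / tau - (D * lap - (divu + decay[name]) * X + prod[name])
        scale = max(float(np.max(np.abs(X))), 1e-300)
        worst = max(worst, float(np.max(np.abs(res))) * tau / scale)
    return worst


def _remesh_uniform(state: ProliferationState) -> None:
    """Re-interpolate all fields onto a fresh uniform mesh (monotone cubic)."""
    r = state.mesh.nodes
    r_new = np.linspace(0.0, r[-1], len(r))
    for name, arr in state.fields.items():
        state.fields[name] = PchipInterpolator(r, arr)(r_new)
    if state.velocity is not None:
        state.velocity = PchipInterpolator(r, state.velocity)(r_new)
    state.mesh = RadialMesh(r_new)


def _volume_average(f: np.ndarray, r: np.ndarray) -> float:
    R = r[-1]
    return float(3.0 / R**3 * np.trapezoid(r * r * f, r))


def _total_mass(f: np.ndarray, r: np.ndarray) -> float:
    return float(4.0 * np.pi * np.trapezoid(r * r * f, r))


def run_proliferation(
    p: ParameterSet,
    t_end: float = 60.0,
    tau: float = 1e-3,
    record_times: np.ndarray | None = None,
    n_nodes: int = 101,
    max_halvings: int = 6,
    picard_rtol: float = 5e-13,
) -> ProliferationResult:
    """Run the free-boundary model to ``t_end`` days.

    Records, at each requested time: R(t), tumor volume (4/3 pi R^3),
    volume-weighted averages (3/R^3) Int r^2 f dr of all 13 variables, and
    total masses Int 4 pi r^2 (m + m_i) dr of both miRs and of C.
    """
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    if record_times is None:
        record_times = np.arange(0.0, t_end + 1e-9, 1.0)
    record_times = np.asarray(record_times, dtype=float)
    state = initialize_proliferation(p, n_nodes)

    times, radii, volumes = [], [], []
    averages: dict[str, list[float]] = {k: [] for k in FIELDS}
    mm1, mm2, mmC = [], [], []
    max_dev = 0.0
    max_res = 0.0

    def record(st: ProliferationState) -> None:
        r = st.mesh.nodes
        times.append(st.time)
        radii.append(st.mesh.radius)
        volumes.append(4.0 / 3.0 * np.pi * st.mesh.radius**3)
        for k in FIELDS:
            averages[k].append(_volume_average(st.fields[k], r))
        mm1.append(_total_mass(st.fields["m1"] + st.fields["m1i"], r))
        mm2.append(_total_mass(st.fields["m2"] + st.fields["m2i"], r))
        mmC.append(_total_mass(st.fields["C"], r))

    rec_iter = iter(record_times)
    next_rec = next(rec_iter, None)
    if next_rec is not None and next_rec <= 1e-12:
        record(state)
        next_rec = next(rec_iter, None)

    halvings = 0
    while state.time < t_end - 1e-12:
        step = min(tau, t_end - state.time)
        if next_rec is not None:
            step = min(step, next_rec - state.time + 1e-15)
        try:
            state = advance_moving_mesh(state, p, step, rtol=picard_rtol)
        except ConvergenceFailure:
            halvings += 1
            if halvings > max_halvings:
                raise
            tau /= 2.0
            logger.warning("halving tau to %.2e day", tau)
            continue
        max_res = max(max_res, state.last_residual)
        dev = float(np.max(np.abs(state.fields["C"] + state.fields["N"] - p.steady.theta)))
        max_dev = max(max_dev, dev)
        if next_rec is not None and state.time >= next_rec - 1e-9:
            record(state)
            next_rec = next(rec_iter, None)

    return ProliferationResult(
        times=np.asarray(times),
        radius_cm=np.asarray(radii),
        volume_cm3=np.asarray(volumes),
        averages={k: np.asarray(v) for k, v in averages.items()},
        total_mass_m1=np.asarray(mm1),
        total_mass_m2=np.asarray(mm2),
        total_mass_C=np.asarray(mmC),
        max_CN_deviation=max_dev,
        max_residual=max_res,
        final_state=state,
    )
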