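"""Local (non-spatial) reaction terms of the signaling / miR / cell network.

All evaluators are pure and stateless; they accept scalars or numpy arrays
(one value per grid node) and are shared by the invasion and proliferation
solvers as well as by the sensitivity driver.

The network: EGF-EGFR (E) drives MAPK (M) and AKT (A); TKI (T) resists both
pathway activations and is itself blocked by miR-21; PTEN (P) resists AKT and
is blocked by miR-21/205; the Apaf-1-caspase-9 apoptosome (Ap) drives
damage-induced apoptosis and its expression is blocked by miR-155.  Cancer
cells (C) shed exosomes (E_C) which carry the exosomal miR pools (m1, m2);
the cellular pools (m1i, m2i) are produced by the cells directly.  Protein
kinetics are scaled by C/C_0 so that signaling only runs where cancer cells
are present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .params import ParameterSet

__all__ = [
    "PointState",
    "PointRates",
    "protein_rhs",
    "exosome_reaction",
    "mir_reaction",
    "growth_rate",
    "normal_growth_rate",
    "death_rate",
    "steady_point_state",
]

Arr = Union[float, np.ndarray]

_STATE_FIELDS = ("E", "M", "A", "T", "P", "Ap", "E_C",
                 "m1", "m2", "m1i", "m2i", "C", "N")


@dataclass
class PointState:
    """Concentrations (g/cm^3) of all model variables at one location.

    ``N`` (normal healthy cells) is only meaningful in the proliferation
    phase and defaults to 0.
    """

    E: Arr = 0.0
    M: Arr = 0.0
    A: Arr = 0.0
    T: Arr = 0.0
    P: Arr = 0.0
    Ap: Arr = 0.0
    E_C: Arr = 0.0
    m1: Arr = 0.0
    m2: Arr = 0.0
    m1i: Arr = 0.0
    m2i: Arr = 0.0
    C: Arr = 0.0
    N: Arr = 0.0


@dataclass
class PointRates:
    """Reaction rates (g cm^-3 day^-1), one entry per PointState field."""

    E: Arr = 0.0
    M: Arr = 0.0
    A: Arr = 0.0
    T: Arr = 0.0
    P: Arr = 0.0
    Ap: Arr = 0.0
    E_C: Arr = 0.0
    m1: Arr = 0.0
    m2: Arr = 0.0
    m1i: Arr = 0.0
    m2i: Arr = 0.0
    C: Arr = 0.0
    N: Arr = 0.0


def steady_point_state(p: ParameterSet) -> PointState:
    """The tabulated steady state (cellular miR pools at gamma * exosomal)."""
    ss = p.steady
    return PointState(
        E=ss.E_0, M=ss.M_0, A=ss.A_0, T=ss.T_0, P=ss.P_0, Ap=ss.Ap_0,
        E_C=ss.E_C0, m1=ss.m_10, m2=ss.m_20,
        m1i=ss.gamma * ss.m_10, m2i=ss.gamma * ss.m_20,
        C=ss.C_0, N=ss.N_0,
    )


def _check_nonneg(**kwargs: Arr) -> None:
    for name, val in kwargs.items():
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"negative concentration in {name}")


def protein_rhs(s: PointState, p: ParameterSet, *, check: bool = True) -> PointRates:
    """Right-hand sides of the six intracellular protein equations.

    Each bracketed production-minus-degradation term is multiplied by C/C_0.
    The TKI equation sees only half of the pooled miR-21/205 signal (miR-21
    proper is a fraction of the pooled variable); PTEN sees the full m1 pool
    and the apoptosome the full m2 pool.  AKT activation carries the Ras
    branch enhancement (1 + lam_MA * M/(K_MA + M)).
    """
    if check:
        _check_nonneg(E=s.E, M=s.M, A=s.A, T=s.T, P=s.P, Ap=s.Ap,
                      m1=s.m1, m2=s.m2, m1i=s.m1i, m2i=s.m2i, C=s.C)
    f = s.C / p.steady.C_0
    dE = (p.lam_E / (1.0 + s.M / p.K_ME) - p.d_E * s.E) * f
    dM = (p.lam_M * s.E / (1.0 + s.T / p.K_TM) - p.d_M * s.M) * f
    dA = (p.lam_A * s.E / (1.0 + s.P / p.K_PA) / (1.0 + s.T / p.K_TA)
          * (1.0 + p.lam_MA * s.M / (p.K_MA + s.M)) - p.d_A * s.A) * f
    dT = (p.lam_T / (1.0 + 0.5 * (s.m1 + s.m1i) / p.K_mT) - p.d_T * s.T) * f
    dP = (p.lam_P / (1.0 + (s.m1 + s.m1i) / p.K_mP) - p.d_P * s.P) * f
    dAp = (p.lam_Ap / (1.0 + (s.m2 + s.m2i) / p.K_m2) - p.d_Ap * s.Ap) * f
    return PointRates(E=dE, M=dM, A=dA, T=dT, P=dP, Ap=dAp)


def exosome_reaction(E_C: Arr, C: Arr, p: ParameterSet, *, check: bool = True) -> Arr:
    """Shedding minus cell-contact degradation of cancer-derived exosomes."""
    if check:
        _check_nonneg(E_C=E_C, C=C)
    return p.lam_Ec * C - p.d_Ec * E_C * C / (p.K_C + C)


_MIR_SPECIES = {
    "m1": ("lam_m1", "d_m1", "exosomal"),
    "m2": ("lam_m2", "d_m2", "exosomal"),
    "m1i": ("lam_m1i", "d_m1", "cellular"),
    "m2i": ("lam_m2i", "d_m2", "cellular"),
}


def mir_reaction(m: Arr, driver: Arr, C: Arr, p: ParameterSet, species: str,
                 *, check: bool = True) -> Arr:
    """Reaction term for a miR pool.

    Exosomal pools (``m1``, ``m2``) are released at lam_mX * E_C * C/(K_C+C)
    (``driver`` is the exosome concentration); cellular pools (``m1i``,
    ``m2i``) are produced by cancer cells at lam_mXi * C (``driver`` unused).
    All decay first-order.
    """
    if species not in _MIR_SPECIES:
        raise ValueError(f"unknown miR species {species!r}")
    if check:
        _check_nonneg(m=m, C=C)
    lam_name, d_name, pool = _MIR_SPECIES[species]
    lam, d = getattr(p, lam_name), getattr(p, d_name)
    if pool == "exosomal":
        if check:
            _check_nonneg(driver=driver)
        return lam * driver * C / (p.K_C + C) - d * m
    return lam * C - d * m


def growth_rate(M: Arr, A: Arr, C: Arr, N: Arr, p: ParameterSet,
                phase: str = "invasion", *, check: bool = True) -> Arr:
    """Logistic MAPK/AKT-driven growth of cancer cells.

    In the proliferation phase the logistic term includes the competition
    with normal cells, eps*N; in the invasion phase N is ignored.
    """
    if check:
        _check_nonneg(M=M, A=A, C=C, N=N)
    if phase == "invasion":
        N = 0.0
    crowd = 1.0 - (C + p.eps * N) / p.steady.C_M
    return (p.lam_C1 * M / (p.K_M + M) + p.lam_C2 * A / (p.K_A + A)) * C * crowd


def normal_growth_rate(N: Arr, C: Arr, p: ParameterSet, *, check: bool = True) -> Arr:
    """Logistic growth of normal healthy cells competing with cancer cells."""
    if check:
        _check_nonneg(N=N, C=C)
    return p.lam_N * N * (1.0 - (N + p.eps * C) / p.steady.C_M)


def death_rate(C: Arr, Ap: Arr, p: ParameterSet, cell: str = "cancer",
               *, check: bool = True) -> Arr:
    """Apoptosome-mediated plus natural death of cancer or normal cells."""
    if cell == "cancer":
        dD, d0 = p.d_D, p.d_C
    elif cell == "normal":
        dD, d0 = p.d_DN, p.d_N
    else:
        raise ValueError(f"unknown cell type {cell!r}")
    if check:
        _check_nonneg(C=C, Ap=Ap)
    return dD * C * Ap / (p.K_Ap + Ap) + d0 * C


def all_rates(s: PointState, p: ParameterSet, phase: str = "invasion",
              *, check: bool = True) -> PointRates:
    """Full reaction vector (no spatial operators) -- the method-of-lines
    right-hand side used by reference integrations and the solvers' tests."""
    r = protein_rhs(s, p, check=check)
    r.E_C = exosome_reaction(s.E_C, s.C, p, check=check)
    r.m1 = mir_reaction(s.m1, s.E_C, s.C, p, "m1", check=check)
    r.m2 = mir_reaction(s.m2, s.E_C, s.C, p, "m2", check=check)
    r.m1i = mir_reaction(s.m1i, None, s.C, p, "m1i", check=check)
    r.m2i = mir_reaction(s.m2i, None, s.C, p, "m2i", check=check)
    r.C = (growth_rate(s.M, s.A, s.C, s.N, p, phase, check=check)
           - death_rate(s.C, s.Ap, p, "cancer", check=check))
    if phase == "proliferation":
        r.N = (normal_growth_rate(s.N, s.C, p, check=check)
               - death_rate(s.N, s.Ap, p, "normal", check=check))
    return r
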