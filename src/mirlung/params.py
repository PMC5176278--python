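"""Model parameters: literature constants, unit conversions and rate derivations.

Every kinetic rate of the model is obtained from a small set of literature
constants (half-lives, molar concentrations, molecular weights, copy numbers)
by exact closed-form inversion of the steady-state conditions of the reaction
network.  This module performs those conversions and inversions, assembles the
two phase-specific default parameter sets (tumor *invasion* on a 1-D strip and
spherical free-boundary *proliferation*), validates the internal identities,
and (de)serializes parameter sets to flat YAML/JSON mappings.

Units
-----
Concentrations and densities are g/cm^3, time is days, lengths are cm.
Diffusivities are cm^2/day and the directed-migration coefficient ``chi`` is
cm^5 g^-1 day^-1.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "AVOGADRO",
    "LiteratureConstant",
    "SteadyStateTable",
    "ParameterSet",
    "degradation_rate_from_half_life",
    "molar_to_mass_concentration",
    "copies_to_mass_concentration",
    "literature_steady_state",
    "default_degradation_rates",
    "derive_production_rates",
    "default_parameter_set",
    "printed_table_values",
    "validate",
]

AVOGADRO = 6.022e23

#: proliferation of NSCLC cells at steady state, day^-1 (lam_C1/2 + lam_C2/2)
LAM_C = 0.46

_CONSTANT_KINDS = (
    "half_life_hours",
    "molar_concentration_nM",
    "molecular_weight_kDa",
    "copies_per_cell",
    "mass_concentration_g_per_cm3",
    "dimensionless",
)


@dataclass(frozen=True)
class LiteratureConstant:
    """A single literature-sourced constant with its kind and value."""

    name: str
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in _CONSTANT_KINDS:
            raise ValueError(f"unknown constant kind {self.kind!r}")
        if self.kind == "dimensionless":
            if self.value < 0:
                raise ValueError(f"{self.name}: dimensionless value must be >= 0")
        elif self.value <= 0:
            raise ValueError(f"{self.name}: {self.kind} value must be > 0")


def degradation_rate_from_half_life(t_half: float) -> float:
    """First-order degradation rate ln2 / t_half (t_half in days)."""
    if t_half <= 0:
        raise ValueError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def molar_to_mass_concentration(molar_nM: float, mw_kDa: float) -> float:
    """Convert a molar concentration (nM) of a species of given molecular
    weight (kDa) to a mass concentration in g/cm^3.

    1 nM = 1e-12 mol/cm^3 and 1 kDa = 1e3 g/mol, hence the factor 1e-9.
    """
    if molar_nM <= 0 or mw_kDa <= 0:
        raise ValueError("molar concentration and molecular weight must be > 0")
    return molar_nM * mw_kDa * 1e-9


def copies_to_mass_concentration(
    copies: float, mw_kDa: float, cell_volume: float
) -> float:
    """Mass concentration (g/cm^3) of ``copies`` molecules of ``mw_kDa`` kDa
    in a cell of volume ``cell_volume`` cm^3 (1 Da = 1 g/mol)."""
    if copies <= 0 or mw_kDa <= 0 or cell_volume <= 0:
        raise ValueError("copies, molecular weight and cell volume must be > 0")
    return copies / AVOGADRO * mw_kDa * 1e3 / cell_volume


@dataclass
class SteadyStateTable:
    """Steady-state concentrations (g/cm^3) of every model species, plus the
    cellular:exosomal miR ratio ``gamma`` and the total cell density ``theta``
    of the proliferation phase."""

    E_0: float
    M_0: float
    P_30: float
    A_0: float
    T_0: float
    P_0: float
    Ap_0: float
    E_C0: float
    m_10: float
    m_20: float
    C_0: float
    N_0: float
    C_M: float
    gamma: float = 10.0
    theta: float = 0.6

    def concentration_fields(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "E_0", "M_0", "P_30", "A_0", "T_0", "P_0", "Ap_0",
                "E_C0", "m_10", "m_20", "C_0", "N_0", "C_M",
            )
        }


def literature_steady_state() -> SteadyStateTable:
    """Build the steady-state table from the underlying literature constants.

    EGF-EGFR comes from a receptor copy number (2.5e6 receptors of 170 kDa in
    a 1e-9 cm^3 cell); MAPK is represented by Ras (0.4 uM, 21 kDa); PI3K, AKT
    and PTEN from their molar concentrations; TKI from the proportionality
    T_0/E_0 = P_0/P_30; the apoptosome from Apaf-1 (0.2 uM, 142 kDa).  The
    exosome density and the miR concentrations are direct mass estimates.
    """
    E_0 = copies_to_mass_concentration(2.5e6, 170.0, 1e-9)
    M_0 = molar_to_mass_concentration(400.0, 21.0)     # Ras, 0.4 uM
    P_30 = molar_to_mass_concentration(8.0, 195.0)
    A_0 = molar_to_mass_concentration(15.1, 62.0)
    P_0 = molar_to_mass_concentration(4.0, 47.0)
    T_0 = P_0 * E_0 / P_30
    Ap_0 = molar_to_mass_concentration(200.0, 142.0)   # Apaf-1, 0.2 uM
    # exosomal miR-21(+205) from 0.2 amol/uL = 2e-4 nM of a 7 kDa RNA,
    # doubled because two miRs are pooled; cellular pool is gamma-fold higher
    m1i_0 = 2.0 * molar_to_mass_concentration(2e-4, 7.0)
    gamma = 10.0
    return SteadyStateTable(
        E_0=E_0,
        M_0=M_0,
        P_30=P_30,
        A_0=A_0,
        T_0=T_0,
        P_0=P_0,
        Ap_0=Ap_0,
        E_C0=3.6e-10,
        m_10=m1i_0 / gamma,
        m_20=m1i_0 / gamma / 2.0,
        C_0=0.4,
        N_0=0.14,
        C_M=0.8,
        gamma=gamma,
        theta=0.6,
    )


def default_degradation_rates(normal_cell_rates: str = "table") -> dict[str, float]:
    """Degradation/death rates (day^-1) from half-lives and the steady-state
    partition of cancer-cell death (d_D = 0.9 lam_C, d_C = 0.05 lam_C).

    ``normal_cell_rates`` selects the normal-cell constants: ``"table"`` uses
    the tabulated d_N = 0.023; ``"derived"`` uses d_N = 1.1 d_C = 0.0253.
    """
    if normal_cell_rates not in ("table", "derived"):
        raise ValueError(f"unknown normal_cell_rates {normal_cell_rates!r}")
    d_C = 0.05 * LAM_C
    d_D = 0.9 * LAM_C
    return {
        "d_E": degradation_rate_from_half_life(20.0 / 24.0),   # EGFR t1/2 20 h
        "d_M": degradation_rate_from_half_life(1.0),           # MAPK 24 h
        "d_A": degradation_rate_from_half_life(1.0),           # AKT 24 h
        "d_T": degradation_rate_from_half_life(2.0),           # TKI 48 h
        "d_P": degradation_rate_from_half_life(0.03125),       # PTEN 45 min
        "d_Ap": degradation_rate_from_half_life(0.25),         # apoptosome 6 h
        "d_Ec": 21.8,                                          # fitted
        "d_m1": degradation_rate_from_half_life(1.25),         # miR 30 h
        "d_m2": degradation_rate_from_half_life(1.25),
        "d_C": d_C,
        "d_D": d_D,
        "d_N": 0.023 if normal_cell_rates == "table" else 1.1 * d_C,
        "d_DN": 1.1 * d_D,
    }


_PRODUCTION_KEYS = (
    "lam_E", "lam_M", "lam_A", "lam_T", "lam_P", "lam_Ap",
    "lam_Ec", "lam_m1", "lam_m2", "lam_m1i", "lam_m2i",
    "lam_C1", "lam_C2",
)


def derive_production_rates(
    ss: SteadyStateTable,
    degradations: Mapping[str, float],
    lam_C: float = LAM_C,
    lam_MA: float = 0.5,
) -> dict[str, float]:
    """Invert the zero-RHS steady-state conditions of the reaction network for
    every production rate.

    The inversions assume the steady-state half-saturation convention
    (K_X = X_0 for signaling proteins, K_mX = m_X0/5 for the miR inhibitions),
    under which each inhibition factor takes a fixed rational value at the
    steady state -- e.g. the TKI equation sees 1 + (1/2)(1+gamma) m_10/(m_10/5)
    = 28.5 with gamma = 10.
    """
    d = degradations
    for name in ("E_0", "M_0", "A_0", "T_0", "P_0", "Ap_0", "E_C0", "m_10", "m_20", "C_0"):
        if getattr(ss, name) <= 0:
            raise ValueError(f"steady state {name} must be > 0 to invert rates")
    g = ss.gamma
    mir1_factor = 1.0 + (1.0 + g) * ss.m_10 / (ss.m_10 / 5.0)          # = 56
    mir1_half = 1.0 + 0.5 * (1.0 + g) * ss.m_10 / (ss.m_10 / 5.0)      # = 28.5
    mir2_factor = 1.0 + (1.0 + g) * ss.m_20 / (ss.m_20 / 5.0)          # = 56
    # AKT: 1/(1+P_0/K_PA) * 1/(1+T_0/K_TA) * (1 + lam_MA/2) = (1/4)(1+lam_MA/2)
    akt_factor = 0.25 * (1.0 + lam_MA / 2.0)
    rates = {
        "lam_E": 2.0 * d["d_E"] * ss.E_0,
        "lam_M": 2.0 * d["d_M"] * ss.M_0 / ss.E_0,
        "lam_A": d["d_A"] * ss.A_0 / ss.E_0 / akt_factor,
        "lam_T": mir1_half * d["d_T"] * ss.T_0,
        "lam_P": mir1_factor * d["d_P"] * ss.P_0,
        "lam_Ap": mir2_factor * d["d_Ap"] * ss.Ap_0,
        "lam_Ec": d["d_Ec"] * ss.E_C0 / (2.0 * ss.C_0),
        "lam_m1": 2.0 * d["d_m1"] * ss.m_10 / ss.E_C0,
        "lam_m2": 2.0 * d["d_m2"] * ss.m_20 / ss.E_C0,
        "lam_m1i": d["d_m1"] * g * ss.m_10 / ss.C_0,
        "lam_m2i": d["d_m2"] * g * ss.m_20 / ss.C_0,
        "lam_C1": (4.0 / 3.0) * lam_C,
        "lam_C2": (2.0 / 3.0) * lam_C,
        "d_D": 0.9 * lam_C,
        "d_C": 0.05 * lam_C,
    }
    return rates


_RATE_FIELDS = [
    # diffusivities / migration
    "D_Ec", "D_m1", "D_m2", "D_C", "D_N", "chi",
    # production rates
    "lam_E", "lam_M", "lam_A", "lam_MA", "lam_T", "lam_P", "lam_Ap",
    "lam_Ec", "lam_m1", "lam_m2", "lam_m1i", "lam_m2i",
    "lam_C1", "lam_C2", "lam_N", "eps",
    # degradation / death rates
    "d_E", "d_M", "d_A", "d_T", "d_P", "d_Ap", "d_Ec",
    "d_m1", "d_m2", "d_C", "d_D", "d_N", "d_DN",
    # half-saturations
    "K_ME", "K_TM", "K_TA", "K_PA", "K_mT", "K_mP", "K_m2",
    "K_MA", "K_C", "K_M", "K_A", "K_Ap",
]


@dataclass
class ParameterSet:
    """Complete parameter set for one model phase.

    ``steady`` carries the steady-state table of the phase; ``C0_derivation``
    is the cancer-cell density at which the cell-density-linked rates
    (lam_Ec, lam_m1i, lam_m2i, K_C) were derived -- it stays at the invasion
    value 0.4 g/cm^3 in both phases, because the proliferation phase only
    re-targets the steady densities, not the tabulated rates.
    ``modified`` records symbols touched by scenario modifiers so that
    :func:`validate` skips the corresponding derived-rate identities.
    """

    D_Ec: float
    D_m1: float
    D_m2: float
    D_C: float
    D_N: float
    chi: float
    lam_E: float
    lam_M: float
    lam_A: float
    lam_MA: float
    lam_T: float
    lam_P: float
    lam_Ap: float
    lam_Ec: float
    lam_m1: float
    lam_m2: float
    lam_m1i: float
    lam_m2i: float
    lam_C1: float
    lam_C2: float
    lam_N: float
    eps: float
    d_E: float
    d_M: float
    d_A: float
    d_T: float
    d_P: float
    d_Ap: float
    d_Ec: float
    d_m1: float
    d_m2: float
    d_C: float
    d_D: float
    d_N: float
    d_DN: float
    K_ME: float
    K_TM: float
    K_TA: float
    K_PA: float
    K_mT: float
    K_mP: float
    K_m2: float
    K_MA: float
    K_C: float
    K_M: float
    K_A: float
    K_Ap: float
    steady: SteadyStateTable
    phase: str = "invasion"
    C0_derivation: float = 0.4
    modified: set = field(default_factory=set)

    def copy(self) -> "ParameterSet":
        new = dataclasses.replace(self, steady=dataclasses.replace(self.steady))
        new.modified = set(self.modified)
        return new

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in _RATE_FIELDS}
        out.update({f"steady.{k}": v for k, v in dataclasses.asdict(self.steady).items()})
        out["phase"] = self.phase
        out["C0_derivation"] = self.C0_derivation
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ParameterSet":
        ss = SteadyStateTable(**{
            k.split(".", 1)[1]: float(v)
            for k, v in mapping.items()
            if k.startswith("steady.")
        })
        kwargs = {k: float(mapping[k]) for k in _RATE_FIELDS}
        return cls(
            steady=ss,
            phase=str(mapping.get("phase", "invasion")),
            C0_derivation=float(mapping.get("C0_derivation", 0.4)),
            **kwargs,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_parameter_set(
    phase: str = "invasion",
    *,
    normal_cell_rates: str = "table",
    chi: float | None = None,
) -> ParameterSet:
    """Default parameter set for one of the two model phases.

    invasion
        C_0 = 0.4 g/cm^3, chi = 3e-2 cm^5/g/day (the value all the comparative
        invasion simulations use).
    proliferation
        C_0 = 0.46, N_0 = 0.14, theta = 0.6 g/cm^3; lam_C1 and lam_C2 scaled
        by 1.4 because proliferating cells divide faster than invading ones.

    ``normal_cell_rates`` selects the normal-cell growth/death constants:
    ``"table"`` (lam_N = 0.092, d_N = 0.023) or ``"derived"``
    (lam_N = 0.8 lam_C = 0.368, d_N = 1.1 d_C = 0.0253).
    """
    if phase not in ("invasion", "proliferation"):
        raise ValueError(f"unknown phase {phase!r}; expected 'invasion' or 'proliferation'")
    ss = literature_steady_state()
    deg = default_degradation_rates(normal_cell_rates)
    lam_MA = 0.5
    prod = derive_production_rates(ss, deg, LAM_C, lam_MA)
    lam_N = 0.092 if normal_cell_rates == "table" else 0.8 * LAM_C

    D_C = 8.64e-7
    D_m = (24.0 / 7.0) ** (1.0 / 3.0) * 8.64e-2  # VEGF-scaled by MW^(1/3)
    p = ParameterSet(
        # Stokes-Einstein scaling of D_C by the cell:exosome diameter ratio
        # (10 um : 70 nm), as tabulated
        D_Ec=1.23e-4,
        D_m1=D_m,
        D_m2=D_m,
        D_C=D_C,
        D_N=D_C,
        chi=3e-2 if chi is None else chi,
        lam_MA=lam_MA,
        lam_N=lam_N,
        eps=0.1,
        K_ME=ss.M_0,
        K_TM=ss.T_0,
        K_TA=ss.T_0,
        K_PA=ss.P_0,
        K_mT=ss.m_10 / 5.0,
        K_mP=ss.m_10 / 5.0,
        K_m2=ss.m_20 / 5.0,
        K_MA=ss.M_0,
        K_C=ss.C_0,
        K_M=ss.M_0,
        K_A=ss.A_0,
        K_Ap=ss.Ap_0,
        steady=ss,
        phase=phase,
        C0_derivation=ss.C_0,
        **{k: prod[k] for k in _PRODUCTION_KEYS},
        **deg,
    )
    if phase == "proliferation":
        p.lam_C1 *= 1.4
        p.lam_C2 *= 1.4
        p.steady.C_0 = 0.46
        p.steady.N_0 = 0.14
        p.steady.theta = 0.6
    return p


def printed_table_values() -> dict[str, float]:
    """The bundled printed (4-significant-figure) parameter record as a flat
    mapping, including ``steady.``-prefixed concentrations."""
    from importlib.resources import files

    text = files("mirlung").joinpath("data/printed_tables.yaml").read_text()
    return {k: float(v) for k, v in yaml.safe_load(text).items()}


def _relerr(a: float, b: float) -> float:
    return abs(a - b) / max(abs(b), 1e-300)


def validate(p: ParameterSet, rtol: float = 1e-3) -> list[str]:
    """Return a list of invariant violations (empty list means valid).

    Checks positivity of every rate and concentration, the chi range, the
    half-saturation conventions, and all derived-rate identities to relative
    tolerance ``rtol`` (identities involving scenario-modified symbols are
    skipped).
    """
    v: list[str] = []
    for name in _RATE_FIELDS:
        if not getattr(p, name) > 0:
            v.append(f"{name}: must be > 0")
    for name, val in p.steady.concentration_fields().items():
        if not val > 0:
            v.append(f"steady.{name}: must be > 0")
    if p.steady.gamma <= 0 or p.steady.theta <= 0:
        v.append("steady.gamma/theta: must be > 0")
    if p.phase == "proliferation":
        if _relerr(p.steady.C_0 + p.steady.N_0, p.steady.theta) > rtol:
            v.append("steady: C_0 + N_0 must equal theta in the proliferation phase")
    if p.steady.C_0 > p.steady.C_M:
        v.append("steady: C_0 must not exceed the carrying capacity C_M")
    if "chi" not in p.modified and not (3e-4 <= p.chi <= 3e-2):
        v.append("chi: outside the modelled range [3e-4, 3e-2] cm^5/g/day")

    ss = p.steady
    d = {k: getattr(p, k) for k in _RATE_FIELDS}
    scale = 1.4 if p.phase == "proliferation" else 1.0
    lam_C = (p.lam_C1 + p.lam_C2) / 2.0 / scale
    g = ss.gamma
    identities = {
        "lam_E": ("lam_E = 2 d_E E_0", p.lam_E, 2 * p.d_E * ss.E_0, {"d_E"}),
        "lam_M": ("lam_M = 2 d_M M_0/E_0", p.lam_M, 2 * p.d_M * ss.M_0 / ss.E_0, {"d_M"}),
        "lam_A": ("lam_A = (16/5) d_A A_0/E_0 at lam_MA = 1/2",
                  p.lam_A, p.d_A * ss.A_0 / ss.E_0 / (0.25 * (1 + p.lam_MA / 2)),
                  {"d_A", "lam_MA"}),
        "lam_T": ("lam_T = 28.5 d_T T_0", p.lam_T, 28.5 * p.d_T * ss.T_0, {"d_T"}),
        "lam_P": ("lam_P = 56 d_P P_0", p.lam_P, 56 * p.d_P * ss.P_0, {"d_P"}),
        "lam_Ap": ("lam_Ap = 56 d_Ap Ap_0", p.lam_Ap, 56 * p.d_Ap * ss.Ap_0, {"d_Ap"}),
        "lam_Ec": ("lam_Ec = d_Ec E_C0/(2 C_0)", p.lam_Ec,
                   p.d_Ec * ss.E_C0 / (2 * p.C0_derivation), {"d_Ec"}),
        "lam_m1": ("lam_m1 = 2 d_m1 m_10/E_C0", p.lam_m1,
                   2 * p.d_m1 * ss.m_10 / ss.E_C0, {"d_m1"}),
        "lam_m2": ("lam_m2 = 2 d_m2 m_20/E_C0", p.lam_m2,
                   2 * p.d_m2 * ss.m_20 / ss.E_C0, {"d_m2"}),
        "lam_m1i": ("lam_m1i = d_m1 gamma m_10/C_0", p.lam_m1i,
                    p.d_m1 * g * ss.m_10 / p.C0_derivation, {"d_m1"}),
        "lam_m2i": ("lam_m2i = d_m2 gamma m_20/C_0", p.lam_m2i,
                    p.d_m2 * g * ss.m_20 / p.C0_derivation, {"d_m2"}),
        "d_D": ("d_D = 0.9 lam_C", p.d_D, 0.9 * lam_C, {"lam_C1", "lam_C2"}),
        "d_C": ("d_C = 0.05 lam_C", p.d_C, 0.05 * lam_C, {"lam_C1", "lam_C2"}),
        "d_DN": ("d_DN = 1.1 d_D", p.d_DN, 1.1 * p.d_D, {"d_D"}),
        "lam_C1": ("lam_C1 = 2 lam_C2", p.lam_C1, 2 * p.lam_C2, {"lam_C2"}),
    }
    for sym, (label, lhs, rhs, extra) in identities.items():
        if p.modified & ({sym} | extra):
            continue
        if rhs > 0 and lhs > 0 and _relerr(lhs, rhs) > rtol:
            v.append(f"{sym}: identity {label} violated ({lhs:.6g} vs {rhs:.6g})")

    ksets = {
        "K_mT": ss.m_10 / 5, "K_mP": ss.m_10 / 5, "K_m2": ss.m_20 / 5,
        "K_ME": ss.M_0, "K_MA": ss.M_0, "K_M": ss.M_0,
        "K_TM": ss.T_0, "K_TA": ss.T_0, "K_PA": ss.P_0,
        "K_A": ss.A_0, "K_Ap": ss.Ap_0, "K_C": p.C0_derivation,
    }
    for sym, expected in ksets.items():
        if sym in p.modified:
            continue
        if getattr(p, sym) > 0 and _relerr(getattr(p, sym), expected) > rtol:
            v.append(f"{sym}: steady-state half-saturation convention violated")
    return v
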