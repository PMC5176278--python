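"""Mutation, anti-miR and chemotherapy scenarios as parameter modifiers.

A scenario is a multiplicative modification of named parameters.  Oncogenic
mutations raise a production rate (EGFR 1.3x, MAPK 1.6x, AKT 1.8x, or the
milder dual combinations); anti-miR drugs halve the production of the
targeted miR in both its exosomal and cellular pools; the chemotherapy
surrogates act on division (paclitaxel), on EGFR production (gefitinib) or
on apoptosis rates (cisplatin).  Modifiers compose multiplicatively and
commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from . import invasion as inv
from .params import ParameterSet, _RATE_FIELDS
from .invasion import InvasionResult
from .proliferation import ProliferationResult

__all__ = [
    "ScenarioModifiers",
    "EfficacyReport",
    "builtin_scenario",
    "scenario_catalogue",
    "apply",
    "efficacy",
    "chi_sweep",
]


@dataclass
class ScenarioModifiers:
    """Multiplicative parameter modifications with a human-readable label."""

    factors: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        for sym, f in self.factors.items():
            if sym not in _RATE_FIELDS:
                raise ValueError(f"unknown parameter symbol {sym!r}")
            if not f > 0:
                raise ValueError(f"factor for {sym} must be > 0, got {f}")

    def compose(self, other: "ScenarioModifiers") -> "ScenarioModifiers":
        factors = dict(self.factors)
        for sym, f in other.factors.items():
            factors[sym] = factors.get(sym, 1.0) * f
        label = " + ".join(x for x in (self.label, other.label) if x)
        return ScenarioModifiers(factors, label)

    def __mul__(self, other: "ScenarioModifiers") -> "ScenarioModifiers":
        return self.compose(other)


# anti-miR drugs antagonize the targeted miR in every compartment, so they
# scale the production of both the exosomal and the cellular pool.
# Chemotherapy factors are net multipliers of the proliferation-phase rates
# (paclitaxel turns the 1.4-fold division scaling into 1.3-fold; gefitinib
# turns the 3-fold EGFR-mutant production into 1.5-fold).
_CATALOGUE: dict[str, ScenarioModifiers] = {
    "control": ScenarioModifiers({}, "control"),
    "mut_EGFR": ScenarioModifiers({"lam_E": 1.3}, "EGFR mutation"),
    "mut_MAPK": ScenarioModifiers({"lam_M": 1.6}, "MAPK mutation"),
    "mut_AKT": ScenarioModifiers({"lam_A": 1.8}, "AKT mutation"),
    "mut_EGFR_MAPK": ScenarioModifiers({"lam_E": 1.15, "lam_M": 1.3},
                                       "EGFR+MAPK mutations"),
    "mut_EGFR_AKT": ScenarioModifiers({"lam_E": 1.15, "lam_A": 1.4},
                                      "EGFR+AKT mutations"),
    "mut_MAPK_AKT": ScenarioModifiers({"lam_M": 1.3, "lam_A": 1.4},
                                      "MAPK+AKT mutations"),
    "anti_m1": ScenarioModifiers({"lam_m1": 0.5, "lam_m1i": 0.5}, "anti-miR-21"),
    "anti_m2": ScenarioModifiers({"lam_m2": 0.5, "lam_m2i": 0.5}, "anti-miR-155"),
    "anti_m1_m2": ScenarioModifiers(
        {"lam_m1": 0.5, "lam_m1i": 0.5, "lam_m2": 0.5, "lam_m2i": 0.5},
        "anti-miR-21 + anti-miR-155"),
    "EGFRx3": ScenarioModifiers({"lam_E": 3.0}, "strong EGFR mutation"),
    "PTX": ScenarioModifiers({"lam_C1": 1.3 / 1.4, "lam_C2": 1.3 / 1.4},
                             "paclitaxel"),
    "gefitinib": ScenarioModifiers({"lam_E": 1.5 / 3.0}, "gefitinib"),
    "anti_m2_mild": ScenarioModifiers({"lam_m2": 1 / 1.2, "lam_m2i": 1 / 1.2},
                                      "mild anti-miR-155"),
    "cisplatin": ScenarioModifiers({"d_C": 1.1, "d_D": 1.1}, "cisplatin"),
}


def scenario_catalogue() -> dict[str, ScenarioModifiers]:
    """All builtin scenarios by name."""
    return dict(_CATALOGUE)


def builtin_scenario(name: str) -> ScenarioModifiers:
    try:
        mods = _CATALOGUE[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(_CATALOGUE))}"
        ) from None
    return ScenarioModifiers(dict(mods.factors), mods.label)


def apply(p: ParameterSet, mods: ScenarioModifiers) -> ParameterSet:
    """Return a copy of ``p`` with the modifier factors applied.  Modified
    symbols are recorded so that derived-identity validation skips them."""
    q = p.copy()
    for sym, f in mods.factors.items():
        setattr(q, sym, getattr(q, sym) * f)
        q.modified.add(sym)
    return q


AnyResult = Union[InvasionResult, ProliferationResult]


@dataclass
class EfficacyReport:
    """Fractional day-``day`` reduction of extent (phi_R: front position or
    radius) and of tumor mass (phi_M: linear mass or total cancer mass)."""

    phi_R: float
    phi_M: float
    day: float
    control: dict[str, float] = field(default_factory=dict)
    treated: dict[str, float] = field(default_factory=dict)


def _extent_and_mass(rec: Mapping[str, float]) -> tuple[float, float]:
    if "front" in rec:
        return rec["front"], rec["mass_C"]
    return rec["radius"], rec["mass_C"]


def efficacy(control: AnyResult, treated: AnyResult, day: float = 60.0) -> EfficacyReport:
    """phi = (control - treated)/control for tumor extent and mass at ``day``."""
    c = control.at(day)
    t = treated.at(day)
    Rc, Mc = _extent_and_mass(c)
    Rt, Mt = _extent_and_mass(t)
    if Rc <= 0 or Mc <= 0:
        raise ValueError("control run has zero extent or mass at the requested day")
    return EfficacyReport(phi_R=(Rc - Rt) / Rc, phi_M=(Mc - Mt) / Mc,
                          day=day, control=c, treated=t)


def chi_sweep(
    p: ParameterSet,
    chi_values: Iterable[float] | None = None,
    scenario: ScenarioModifiers | None = None,
    t_end: float = 60.0,
    treatment: ScenarioModifiers | None = None,
    grid: "inv.InvasionGrid | None" = None,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Day-``t_end`` front position R_chi and linear mass M_chi of the
    invasion model across a range of directed-migration coefficients, for an
    untreated arm and a treated arm (default anti-miR-21 + anti-miR-155),
    with the resulting drug efficacies phi_R and phi_M.
    """
    if chi_values is None:
        chi_values = np.geomspace(3e-4, 3e-2, 8)
    chi_values = np.asarray(list(chi_values), dtype=float)
    if np.any(chi_values < 3e-4) or np.any(chi_values > 3e-2):
        import warnings
        warnings.warn("chi values outside the modelled range [3e-4, 3e-2]")
    if treatment is None:
        treatment = builtin_scenario("anti_m1_m2")
    base = apply(p, scenario) if scenario is not None else p.copy()

    rows = []
    rec = np.array([0.0, t_end])
    for chi in chi_values:
        p_chi = base.copy()
        p_chi.chi = float(chi)
        p_chi.modified.add("chi")
        untreated = inv.run_invasion(p_chi, grid=grid, t_end=t_end, dt=dt, record_times=rec)
        treated = inv.run_invasion(apply(p_chi, treatment), grid=grid, t_end=t_end,
                                   dt=dt, record_times=rec)
        eff = efficacy(untreated, treated, day=t_end)
        rows.append({
            "chi": float(chi),
            "R_chi": eff.control["front"],
            "M_chi": eff.control["mass_C"],
            "R_chi_m": eff.treated["front"],
            "M_chi_m": eff.treated["mass_C"],
            "phi_R": eff.phi_R,
            "phi_M": eff.phi_M,
        })
    return pd.DataFrame(rows)
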