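"""Unit conversions, rate derivations and parameter-set validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlung import params
from mirlung.params import (
    LiteratureConstant,
    copies_to_mass_concentration,
    default_degradation_rates,
    default_parameter_set,
    degradation_rate_from_half_life,
    derive_production_rates,
    literature_steady_state,
    molar_to_mass_concentration,
    printed_table_values,
    validate,
)

RTOL_PRINTED = 1e-3  # absorbs 4-significant-figure rounding of printed values


@pytest.mark.parametrize(
    "t_half, expected",
    [(1.0, 0.6931), (0.03125, 22.1807), (20.0 / 24.0, 0.8318), (2.0, 0.3466)],
)
def test_degradation_rate_matches_printed(t_half, expected):
    assert degradation_rate_from_half_life(t_half) == pytest.approx(expected, rel=RTOL_PRINTED)


@given(st.floats(1e-6, 1e6))
@settings(max_examples=25, deadline=None)
def test_degradation_rate_halflife_identity(t_half):
    assert degradation_rate_from_half_life(t_half) * t_half == pytest.approx(math.log(2))


@pytest.mark.parametrize(
    "molar, mw, expected",
    [(400.0, 21.0, 8.4e-6), (15.1, 62.0, 9.362e-7), (1.0, 1.0, 1e-9)],
)
def test_molar_to_mass_examples(molar, mw, expected):
    assert molar_to_mass_concentration(molar, mw) == pytest.approx(expected, rel=1e-12)


def test_copies_to_mass_examples():
    assert copies_to_mass_concentration(2.5e6, 170.0, 1e-9) == pytest.approx(
        7.0573e-4, rel=RTOL_PRINTED)
    # one mole of a 1 Da species in 1 cm^3 is 1 g/cm^3
    assert copies_to_mass_concentration(params.AVOGADRO, 1e-3, 1.0) == pytest.approx(1.0)


@given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3), st.floats(0.1, 10.0))
@settings(max_examples=25, deadline=None)
def test_conversions_are_linear(a, b, scale):
    assert molar_to_mass_concentration(a * scale, b) == pytest.approx(
        scale * molar_to_mass_concentration(a, b))
    assert copies_to_mass_concentration(a * scale, b, 1e-9) == pytest.approx(
        scale * copies_to_mass_concentration(a, b, 1e-9))


@pytest.mark.parametrize("func, args", [
    (degradation_rate_from_half_life, (0.0,)),
    (degradation_rate_from_half_life, (-1.0,)),
    (molar_to_mass_concentration, (0.0, 21.0)),
    (molar_to_mass_concentration, (400.0, -1.0)),
    (copies_to_mass_concentration, (0.0, 170.0, 1e-9)),
    (copies_to_mass_concentration, (1e6, 170.0, 0.0)),
])
def test_nonpositive_inputs_rejected(func, args):
    with pytest.raises(ValueError):
        func(*args)


def test_literature_constant_kind_invariants():
    with pytest.raises(ValueError):
        LiteratureConstant("x", "half_life_hours", 0.0)
    with pytest.raises(ValueError):
        LiteratureConstant("x", "no_such_kind", 1.0)
    assert LiteratureConstant("eps", "dimensionless", 0.0).value == 0.0


def test_all_derived_rates_match_printed_tables():
    """Every derivation reproduces the printed record to 4 significant figures."""
    printed = printed_table_values()
    flat = default_parameter_set("invasion").to_dict()
    for key, value in printed.items():
        assert flat[key] == pytest.approx(value, rel=RTOL_PRINTED), key


def test_derive_production_rates_closed_forms():
    ss = literature_steady_state()
    deg = default_degradation_rates()
    rates = derive_production_rates(ss, deg)
    assert rates["lam_T"] == pytest.approx(28.5 * deg["d_T"] * ss.T_0)
    assert rates["lam_T"] == pytest.approx(8.4013e-4, rel=RTOL_PRINTED)
    assert rates["lam_Ap"] == pytest.approx(4.4095e-3, rel=RTOL_PRINTED)
    assert rates["lam_m1i"] == pytest.approx(deg["d_m1"] * ss.gamma * ss.m_10 / ss.C_0)


def test_derive_production_rates_rejects_zero_steady_state():
    ss = literature_steady_state()
    ss.E_C0 = 0.0
    with pytest.raises(ValueError):
        derive_production_rates(ss, default_degradation_rates())


def test_default_parameter_set_phases():
    inv = default_parameter_set("invasion")
    assert inv.d_Ec == pytest.approx(21.8)
    assert inv.chi == pytest.approx(3e-2)
    assert inv.steady.C_0 == pytest.approx(0.4)
    pro = default_parameter_set("proliferation")
    assert pro.steady.C_0 + pro.steady.N_0 == pytest.approx(pro.steady.theta)
    assert pro.lam_C1 / inv.lam_C1 == pytest.approx(1.4)
    assert pro.lam_C2 / inv.lam_C2 == pytest.approx(1.4)
    with pytest.raises(ValueError):
        default_parameter_set("metastasis")


def test_normal_cell_rate_variants():
    table = default_parameter_set("proliferation", normal_cell_rates="table")
    derived = default_parameter_set("proliferation", normal_cell_rates="derived")
    assert table.lam_N == pytest.approx(0.092)
    assert table.d_N == pytest.approx(0.023)
    assert derived.lam_N == pytest.approx(0.368)
    assert derived.d_N == pytest.approx(0.0253)


@pytest.mark.parametrize("phase", ["invasion", "proliferation"])
def test_default_sets_validate_clean(phase):
    assert validate(default_parameter_set(phase)) == []


def test_validate_flags_negated_rate():
    p = default_parameter_set("invasion")
    p.lam_E = -p.lam_E
    violations = validate(p)
    assert any(v.startswith("lam_E") for v in violations)


def test_validate_flags_broken_derived_identity():
    p = default_parameter_set("invasion")
    p.d_D = 0.5  # breaks d_D = 0.9 lam_C
    assert any("d_D" in v and "identity" in v for v in validate(p))


def test_validate_skips_identities_of_modified_symbols():
    p = default_parameter_set("invasion")
    p.lam_m1 *= 0.5
    p.modified.add("lam_m1")
    assert validate(p) == []


def test_validate_flags_chi_outside_range():
    p = default_parameter_set("invasion", chi=1.0)
    assert any(v.startswith("chi") for v in validate(p))


def test_serialization_roundtrip(tmp_path):
    p = default_parameter_set("proliferation")
    y = tmp_path / "p.yaml"
    j = tmp_path / "p.json"
    p.to_yaml(y)
    p.to_json(j)
    numeric = {k: v for k, v in p.to_dict().items() if not isinstance(v, str)}
    for q in (params.ParameterSet.from_yaml(y), params.ParameterSet.from_json(j)):
        assert q.phase == "proliferation"
        got = {k: v for k, v in q.to_dict().items() if not isinstance(v, str)}
        assert got == pytest.approx(numeric)
        assert validate(q) == []
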