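"""Monod/inhibition/threshold kinetics, maintenance, growth, rate coupling."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from messim import kinetics as kin
from messim.kinetics import KineticParams
from messim.thermo import (
    ReactionStoichiometry,
    ThermoParams,
    compute_metabolic_yields,
    element_charge_imbalance,
)

#: Independent term-by-term evaluation of the butyrate elongation rate at
#: C_Ac = 2 C_Ac_t = 246, C_MH = 0.1 (= K_MH), all other terms non-limiting.
Q_BUT_ORACLE = 0.007323518934724973

SATURATING = {"CO2": 1e5, "NH4": 1e5, "MH": 1e5, "Ac": 0.0, "But": 0.0, "Cap": 0.0}


def default_yields(state=None):
    thermo = ThermoParams()
    return compute_metabolic_yields(
        thermo, state if state is not None else thermo.reference_state
    )


class TestElementaryTerms:
    @pytest.mark.parametrize("C, K, expected", [
        (0.0, 3.8, 0.0),
        (3.8, 3.8, 0.5),
        (0.05, 0.05, 0.5),
    ])
    def test_saturation(self, C, K, expected):
        assert kin.saturation_term(C, K) == pytest.approx(expected)

    def test_saturation_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            kin.saturation_term(-1.0, 3.8)

    @pytest.mark.parametrize("C, C_star, expected", [
        (0.0, 800.0, 1.0),
        (800.0, 800.0, 0.0),
        (400.0, 800.0, 0.5),
        (1000.0, 800.0, 0.0),  # clamped above critical
    ])
    def test_inhibition(self, C, C_star, expected):
        assert kin.inhibition_term(C, C_star) == pytest.approx(expected)

    def test_threshold_midpoints(self):
        w, _ = kin.threshold_switches(123.0, 123.0)
        _, Z = kin.threshold_switches(1.1 * 123.0, 123.0)
        assert w == pytest.approx(0.5)
        assert Z == pytest.approx(0.5)

    def test_switch_at_zero_concentration(self):
        w, _ = kin.threshold_switches(0.0, 123.0)
        assert w == pytest.approx(1.0 / (1.0 + math.exp(10.0)), rel=1e-9)
        assert w == pytest.approx(4.54e-5, rel=0.01)

    @settings(max_examples=40, deadline=None)
    @given(
        C=st.floats(0.0, 2000.0),
        K=st.floats(1e-3, 100.0),
        C_star=st.floats(1.0, 1000.0),
        C_t=st.floats(1.0, 500.0),
    )
    def test_all_terms_bounded_unit_interval(self, C, K, C_star, C_t):
        assert 0.0 <= kin.saturation_term(C, K) < 1.0
        assert 0.0 <= kin.inhibition_term(C, C_star) <= 1.0
        w, Z = kin.threshold_switches(C, C_t)
        assert 0.0 <= w <= 1.0 and 0.0 <= Z <= 1.0


class TestUptakeAndElongation:
    def test_saturating_substrates_reach_max(self, kparams):
        assert kin.specific_uptake_co2(SATURATING, kparams) == pytest.approx(
            kparams.q_co2_max, rel=1e-4
        )

    def test_no_co2_no_uptake(self, kparams):
        assert kin.specific_uptake_co2(dict(SATURATING, CO2=0.0), kparams) == 0.0

    def test_half_saturation_in_co2(self, kparams):
        q = kin.specific_uptake_co2(dict(SATURATING, CO2=kparams.K_co2), kparams)
        assert q == pytest.approx(0.5 * kparams.q_co2_max, rel=1e-4)

    def test_uptake_bounded_by_max(self, kparams):
        q = kin.specific_uptake_co2(
            {"CO2": 5.0, "NH4": 1.0, "MH": 10.0, "Ac": 100.0, "But": 10.0, "Cap": 5.0},
            kparams,
        )
        assert kparams.q_co2_max <= q <= 0.0

    def test_elongation_suppressed_below_threshold(self, kparams):
        conc = dict(SATURATING, Ac=30.0)  # far below C_ac_t = 123
        q_but, q_cap = kin.specific_elongation_rates(conc, kparams)
        assert q_but < 1e-3 * kparams.q_but_max
        assert q_cap < 1e-3 * kparams.q_cap_max

    def test_elongation_saturates_far_above_threshold(self, kparams):
        conc = dict(SATURATING, Ac=1e4, But=0.0)
        q_but, _ = kin.specific_elongation_rates(conc, kparams)
        # inhibition is active at such acetate levels; compare against it
        inhib = kin.inhibition_term(1e4, kparams.C_ac_star)
        assert inhib == 0.0 and q_but == 0.0
        conc = dict(SATURATING, Ac=600.0)
        q_but, _ = kin.specific_elongation_rates(conc, kparams)
        expected_ceiling = kparams.q_but_max * kin.inhibition_term(600.0, kparams.C_ac_star)
        assert q_but == pytest.approx(expected_ceiling, rel=0.01)

    def test_butyrate_rate_matches_term_by_term_oracle(self, kparams):
        conc = {"Ac": 246.0, "MH": 0.1, "But": 0.0, "Cap": 0.0}
        q_but, _ = kin.specific_elongation_rates(conc, kparams)
        assert q_but == pytest.approx(Q_BUT_ORACLE, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(ac=st.floats(0.0, 700.0))
    def test_butyrate_rate_nondecreasing_in_acetate_below_inhibition(self, ac):
        p = KineticParams(C_ac_star=1e8)  # isolate the saturation structure
        lo, _ = kin.specific_elongation_rates(dict(SATURATING, Ac=ac), p)
        hi, _ = kin.specific_elongation_rates(dict(SATURATING, Ac=ac + 5.0), p)
        assert hi >= lo - 1e-12


class TestMaintenanceAndGrowth:
    def test_reference_temperature_factor_is_one(self):
        m_t0 = kin.maintenance_coefficient(-43.0, 298.0, 298.0)
        assert m_t0 == pytest.approx(3.3 / -43.0)

    def test_temperature_factor_at_working_temperature(self):
        m = kin.maintenance_coefficient(-43.0, 305.0, 298.0)
        factor = m / (3.3 / -43.0)
        assert factor == pytest.approx(1.9025434114581743, rel=1e-9)
        assert factor == pytest.approx(1.9, abs=0.01)

    def test_inverse_proportional_to_catabolic_energy(self):
        assert kin.maintenance_coefficient(-86.0, 305.0) == pytest.approx(
            0.5 * kin.maintenance_coefficient(-43.0, 305.0)
        )

    def test_endergonic_catabolism_rejected(self):
        with pytest.raises(ValueError):
            kin.maintenance_coefficient(1.0, 305.0)

    def test_growth_zero_at_maintenance_only(self):
        assert kin.growth_rate(-0.1, -0.1, -20.0) == 0.0

    def test_growth_positive_when_uptake_exceeds_maintenance(self):
        mu = kin.growth_rate(-0.2, -0.1, -20.0)
        assert mu == pytest.approx(0.005)
        assert kin.growth_rate(-0.05, -0.1, -20.0) < 0.0  # decay

    def test_growth_requires_negative_yield(self):
        with pytest.raises(ValueError):
            kin.growth_rate(-0.2, -0.1, 20.0)


class TestSpeciesRates:
    def make_rates(self, conc=None, C_X=10.0):
        stoich = ReactionStoichiometry()
        yields = default_yields()
        p = KineticParams()
        state = dict(SATURATING, **(conc or {}))
        m = kin.maintenance_coefficient(yields.dG_cat, 305.0)
        q_co2 = kin.specific_uptake_co2(state, p)
        q_but, q_cap = kin.specific_elongation_rates(state, p)
        mu = kin.growth_rate(q_co2, m, yields.y_met["CO2"])
        return kin.species_rates(q_co2, q_but, q_cap, mu, m, yields, stoich, C_X)

    def test_zero_biomass_zero_volumetric_rates(self):
        _, r = self.make_rates(C_X=0.0)
        assert all(v == 0.0 for v in r.values())

    def test_all_zero_without_growth_maintenance_elongation(self):
        stoich = ReactionStoichiometry()
        yields = default_yields()
        q, r = kin.species_rates(0.0, 0.0, 0.0, 0.0, 0.0, yields, stoich, 5.0)
        assert all(abs(v) < 1e-15 for v in q.values())

    @pytest.mark.parametrize("conc", [
        {},  # saturating, no products
        {"Ac": 200.0, "But": 40.0, "Cap": 5.0},
        {"CO2": 2.0, "NH4": 0.1, "MH": 0.5, "Ac": 500.0, "But": 100.0, "Cap": 50.0},
    ])
    def test_carbon_conservation_identity(self, conc):
        """r_CO2 + r_X + 2 r_Ac + 4 r_But + 6 r_Cap = 0 at any state."""
        _, r = self.make_rates(conc)
        carbon = (r["CO2"] + r["X"] + 2 * r["Ac"] + 4 * r["But"] + 6 * r["Cap"])
        scale = max(abs(v) for v in r.values()) or 1.0
        assert abs(carbon) <= 1e-9 * scale

    def test_full_rate_vector_conserves_elements_and_charge(self):
        q, _ = self.make_rates({"Ac": 150.0, "But": 30.0})
        thermo = ThermoParams()
        residual = element_charge_imbalance(q, thermo.full_table())
        scale = max(abs(v) for v in q.values())
        for key, value in residual.items():
            assert abs(value) <= 1e-9 * scale, f"{key}: {value}"

    def test_mediator_antisymmetry(self):
        q, _ = self.make_rates({"Ac": 150.0, "But": 30.0})
        assert q["MH"] == pytest.approx(-q["M+"], rel=1e-12)

    def test_mediator_electron_bookkeeping(self):
        """MH consumption carries half the degree-of-reduction flux of products.

        Degree of reduction (electrons per mole, relative to CO2/NH4+/H2O):
        acetate 8, butyrate 20, caproate 32, biomass 4.2 per C-mol.
        """
        q, _ = self.make_rates({"Ac": 150.0, "But": 30.0})
        electron_flux = (8 * q["Ac"] + 20 * q["But"] + 32 * q["Cap"] + 4.2 * q["X"])
        assert -q["MH"] * 2 == pytest.approx(electron_flux, rel=1e-9)

    def test_metabolism_halts_at_critical_concentrations(self, kparams):
        """All products at C*: every rate including growth-linked uptake is zero."""
        state = dict(
            SATURATING,
            Ac=kparams.C_ac_star, But=kparams.C_but_star, Cap=kparams.C_cap_star,
        )
        q_co2 = kin.specific_uptake_co2(state, kparams)
        q_but, q_cap = kin.specific_elongation_rates(state, kparams)
        assert q_co2 == 0.0 and q_but == 0.0 and q_cap == 0.0
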