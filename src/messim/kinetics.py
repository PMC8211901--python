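"""Microbial kinetics: uptake, growth, maintenance, elongation, inhibition.

Sign convention: consumption rates and consumption yields are negative,
production positive.  The maximum CO2 uptake rate is therefore stored as the
negative number printed for it (-0.307 mol_CO2/mol_X/h by default), and the
maintenance coefficient m_CO2 is negative as well.

The specific CO2 uptake rate is a triple hyperbolic (Monod) product over the
carbon source, nitrogen source and reduced mediator, multiplied by linear
product-inhibition terms for each carboxylate:

    q_CO2 = q_CO2_max * M(CO2) M(NH4) M(MH) * I(Ac) I(But) I(Cap)

Chain elongation switches on only above threshold acetate (and butyrate)
concentrations; smooth sigmoidal gates w_i and Z_i (midpoints C_t and 1.1 C_t,
steepness 10/C_t) shift and gate the hyperbolic terms so rates rise smoothly
through the threshold and never go negative below it.

Growth follows a Herbert-Pirt decomposition: CO2 uptake in excess of the
maintenance demand is converted to biomass through the thermodynamic yield
Y_CO2^Met; maintenance runs pure catabolism; elongation stoichiometry is added
on top.  Maintenance is a Gibbs-energy demand (Tijhuis-style, 3.3 kJ/mol_X/h
scale with a 69.4 kJ/mol activation energy) divided by the catabolic reaction
energy at reactor conditions, so it grows with temperature and shrinks when
catabolism is more exergonic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .constants import R_KJ
from .thermo import MetabolicYields, ReactionStoichiometry

__all__ = [
    "KineticParams",
    "saturation_term",
    "inhibition_term",
    "threshold_switches",
    "specific_uptake_co2",
    "specific_elongation_rates",
    "maintenance_coefficient",
    "growth_rate",
    "species_rates",
]


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants (concentrations in mol/m^3, rates in mol/mol_X/h).

    The three maximum rates and the two elongation thresholds are the free
    parameters of the model; defaults are the fitted values.
    """

    q_co2_max: float = -0.307
    q_but_max: float = 2.12e-2
    q_cap_max: float = 4.64e-3
    K_co2: float = 3.8
    K_nh4: float = 0.05
    K_mh: float = 0.1
    K_ac: float = 0.27
    K_but: float = 0.076
    C_ac_t: float = 123.0
    C_but_t: float = 43.0
    C_ac_star: float = 800.0
    C_but_star: float = 285.0
    C_cap_star: float = 170.0
    #: Tijhuis-style maintenance energy scale, kJ/mol_X/h.
    m_gibbs: float = 3.3
    #: Maintenance activation energy, kJ/mol.
    Ea_maint: float = 69.4

    def __post_init__(self) -> None:
        for name in ("K_co2", "K_nh4", "K_mh", "K_ac", "K_but"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("C_ac_star", "C_but_star", "C_cap_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.C_ac_t < 0 or self.C_but_t < 0:
            raise ValueError("thresholds must be >= 0")
        if self.q_co2_max >= 0:
            raise ValueError("q_co2_max is an uptake rate and must be negative")
        if self.q_but_max <= 0 or self.q_cap_max <= 0:
            raise ValueError("elongation maximum rates must be positive")

    def with_theta(self, theta) -> "KineticParams":
        """Copy with the five free parameters replaced.

        ``theta`` = (q_co2_max, q_but_max, q_cap_max, C_ac_t, C_but_t).
        """
        from dataclasses import replace

        return replace(
            self,
            q_co2_max=float(theta[0]),
            q_but_max=float(theta[1]),
            q_cap_max=float(theta[2]),
            C_ac_t=float(theta[3]),
            C_but_t=float(theta[4]),
        )


def saturation_term(C: float, K: float) -> float:
    """Hyperbolic (Monod) saturation term C/(K + C), in [0, 1)."""
    if K <= 0:
        raise ValueError("half-saturation constant must be positive")
    if C < 0:
        raise ValueError("concentration must be non-negative")
    return C / (K + C)


def inhibition_term(C: float, C_star: float) -> float:
    """Linear product inhibition max(0, 1 - C/C*), clamped at the critical level."""
    if C_star <= 0:
        raise ValueError("critical concentration must be positive")
    return max(0.0, 1.0 - max(C, 0.0) / C_star)


def threshold_switches(C: float, C_t: float) -> tuple[float, float]:
    """Sigmoidal threshold gates (w, Z) for chain elongation.

    w = 1/(1 + exp[A (C_t - C)]) shifts the effective substrate concentration;
    Z = 1/(1 + exp[A (1.1 C_t - C)]) gates the whole rate.  A = 10/C_t.
    Both increase monotonically with C and cross 0.5 at C_t and 1.1 C_t.
    """
    if C_t <= 0:
        raise ValueError("threshold must be positive")
    A = 10.0 / C_t
    w = 1.0 / (1.0 + math.exp(min(A * (C_t - C), 700.0)))
    Z = 1.0 / (1.0 + math.exp(min(A * (1.1 * C_t - C), 700.0)))
    return w, Z


def _product_inhibition(conc: Mapping[str, float], p: KineticParams) -> float:
    return (
        inhibition_term(conc.get("Ac", 0.0), p.C_ac_star)
        * inhibition_term(conc.get("But", 0.0), p.C_but_star)
        * inhibition_term(conc.get("Cap", 0.0), p.C_cap_star)
    )


def specific_uptake_co2(conc: Mapping[str, float], p: KineticParams) -> float:
    """Specific CO2 uptake rate q_CO2 (mol_CO2/mol_X/h, negative = uptake)."""
    return (
        p.q_co2_max
        * saturation_term(conc.get("CO2", 0.0), p.K_co2)
        * saturation_term(conc.get("NH4", 0.0), p.K_nh4)
        * saturation_term(conc.get("MH", 0.0), p.K_mh)
        * _product_inhibition(conc, p)
    )


def _shifted_saturation(C: float, C_t: float, K: float) -> tuple[float, float]:
    """Threshold-shifted Monod term (C - C_t w)/(K + C - C_t w) and its gate Z."""
    w, Z = threshold_switches(C, C_t)
    shifted = C - C_t * w
    term = shifted / (K + shifted) if shifted > 0.0 else 0.0
    return term, Z


def specific_elongation_rates(
    conc: Mapping[str, float], p: KineticParams
) -> tuple[float, float]:
    """Specific butyrate and caproate production rates (mol/mol_X/h, >= 0)."""
    C_ac = conc.get("Ac", 0.0)
    C_but = conc.get("But", 0.0)
    if C_ac < 0 or C_but < 0:
        raise ValueError("concentrations must be non-negative")
    mh = saturation_term(conc.get("MH", 0.0), p.K_mh)
    inhib = _product_inhibition(conc, p)
    ac_term, Z_ac = _shifted_saturation(C_ac, p.C_ac_t, p.K_ac)
    but_term, Z_but = _shifted_saturation(C_but, p.C_but_t, p.K_but)
    q_but = p.q_but_max * ac_term * Z_ac * mh * inhib
    q_cap = p.q_cap_max * ac_term * Z_ac * but_term * Z_but * mh * inhib
    return q_but, q_cap


def maintenance_coefficient(
    dG_cat: float, T: float, T0: float = 298.0, p: KineticParams | None = None
) -> float:
    """Maintenance coefficient on CO2, mol_CO2/mol_X/h (negative = uptake).

    The Gibbs-energy maintenance demand m_G = 3.3 exp[-(Ea/R)(1/T - 1/T0)]
    (kJ/mol_X/h) is paid by running catabolism; dividing by the signed
    catabolic reaction energy at reactor conditions (kJ per reaction, < 0 when
    exergonic) converts it into a CO2 flux and fixes the uptake sign.
    """
    if dG_cat >= 0:
        raise ValueError("catabolism must be exergonic (dG_cat < 0)")
    if p is None:
        p = KineticParams()
    temp_factor = math.exp(-(p.Ea_maint / R_KJ) * (1.0 / T - 1.0 / T0))
    return p.m_gibbs * temp_factor / dG_cat


def growth_rate(q_co2: float, m_co2: float, y_co2_met: float) -> float:
    """Specific growth rate mu = (q_CO2 - m_CO2)/Y_CO2^Met (1/h).

    With uptake rates negative and Y_CO2^Met < 0, mu > 0 exactly when CO2
    uptake exceeds the maintenance demand, and mu = 0 at q_CO2 = m_CO2.
    Negative mu (biomass loss when uptake cannot cover maintenance) is allowed.
    """
    if y_co2_met >= 0:
        raise ValueError("Y_CO2^Met must be negative (CO2 is consumed)")
    return (q_co2 - m_co2) / y_co2_met


def species_rates(
    q_co2: float,
    q_but_elong: float,
    q_cap_elong: float,
    mu: float,
    m_co2: float,
    yields: MetabolicYields,
    stoich: ReactionStoichiometry,
    C_X: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Specific (q_i) and volumetric (r_i = q_i C_X) rates for all species.

    Herbert-Pirt decomposition per species i:

        q_i = Y_i^Met mu + m_CO2 (Y_i^Cat / Y_CO2^Cat)
              + Y_i^But q_But^elong + Y_i^Cap q_Cap^elong

    (maintenance runs pure catabolism; m_CO2 < 0 makes the maintenance term
    consume CO2/MH and produce acetate).  Applied to CO2 the formula returns
    q_CO2 identically, so elemental C, H, O, N and charge are conserved across
    the full rate vector by construction.  Biomass: q_X = mu.
    """
    if C_X < 0:
        raise ValueError("biomass concentration must be non-negative")
    cat = stoich.catabolism
    but = stoich.butyrate_elongation
    cap = stoich.caproate_elongation
    y_met = yields.y_met
    species = set(y_met) | set(but) | set(cap)
    q: dict[str, float] = {}
    for sp in species:
        if sp == "X":
            continue
        q[sp] = (
            y_met.get(sp, 0.0) * mu
            + m_co2 * (cat.get(sp, 0.0) / cat["CO2"])
            + but.get(sp, 0.0) * q_but_elong
            + cap.get(sp, 0.0) * q_cap_elong
        )
    q["CO2"] = q_co2  # identical to the formula above by the growth-rate identity
    q["X"] = mu
    r = {sp: qi * C_X for sp, qi in q.items()}
    return q, r
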