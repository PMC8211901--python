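"""Thermodynamic growth stoichiometry of the black-box electro-autotroph.

The modelled organism reduces CO2 to acetate with reducing equivalents drawn
from an intracellular mediator couple MH/M+ (NADH/NAD+-like), grows on CO2 and
ammonium, and elongates acetate to n-butyrate and n-caproate.  Four reactions
describe the metabolism, all written per mole of their reference product:

* catabolism:          2 CO2 + 4 MH + 3 H+ -> Ac- + 4 M+ + 2 H2O
* anabolism:           CO2 + 2.1 MH + 0.2 NH4+ + 1.9 H+ -> X + 2.1 M+ + 1.5 H2O
* butyrate elongation: 2 Ac- + 2 MH + 3 H+ -> But- + 2 M+ + 2 H2O
* caproate elongation: Ac- + But- + 2 MH + 3 H+ -> Cap- + 2 M+ + 2 H2O

with biomass X = CH1.8O0.5N0.2.  A dissipation-energy balance sets how many
catabolic turnovers power one anabolic turnover (the catabolic multiplier
lambda_cat), from which the overall metabolic yield vector Y_i^Met follows.

Conventions (documented because the literature is not uniform):

* Solute activities are C/1 mol/L; water and biomass are at unit activity; the
  proton activity is 10**-pH with the catholyte pH fixed (default 5.8).
* The mediator standard potential is a biochemical-standard (pH 7) value.  Its
  standard-condition Gibbs energy is the oxidation half-reaction
  MH -> M+ + H+ + 2 e- with the proton moved from pH 7 to unit activity:
  dG_ox0 = n F E_M0' + R T0 ln(10) * 7, which evaluates to -21.85 kJ/mol for
  E_M0' = -0.32 V.  Formation energies dGf(M+) = 0 and dGf(MH) = -dG_ox0
  reproduce this in every reaction the mediator participates in.
* dG0(T) is used unchanged between T0 and T unless per-species enthalpies are
  supplied (the 7 K gap contributes well under the uncertainty of the table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple

from .constants import C_REF, FARADAY, R_KJ

__all__ = [
    "FormationEntry",
    "ReactionStoichiometry",
    "ThermoParams",
    "MediatorGibbs",
    "MetabolicYields",
    "load_formation_table",
    "mediator_delta_g",
    "adapt_gibbs",
    "catabolic_multiplier",
    "metabolic_stoichiometry",
    "compute_metabolic_yields",
    "element_charge_imbalance",
]

ELEMENTS = ("C", "H", "O", "N", "M")

#: Species whose activity follows its concentration (everything except water,
#: biomass and the pH-buffered proton).
_CONCENTRATION_SPECIES = frozenset({"CO2", "NH4", "Ac", "But", "Cap", "MH", "M+"})
_UNIT_ACTIVITY = frozenset({"H2O", "X"})


@dataclass(frozen=True)
class FormationEntry:
    """One row of the formation-energy table."""

    dGf0: float  # kJ/mol, biochemical standard (1 M, pH 0 protons, 298 K)
    charge: float
    composition: Mapping[str, float]  # element -> atoms per formula unit


def load_formation_table() -> dict[str, FormationEntry]:
    """Load the bundled formation-energy table (chemical species only).

    The mediator pair is *not* in the file; its formation energies are derived
    from the configured standard potential in :class:`ThermoParams`.
    """
    table: dict[str, FormationEntry] = {}
    path = resources.files("messim").joinpath("data/formation_gibbs.csv")
    with path.open() as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split(",")
                continue
            row = dict(zip(header, line.split(",")))
            comp = {el: float(row[el]) for el in ("C", "H", "O", "N")}
            table[row["species"]] = FormationEntry(
                dGf0=float(row["dGf0_kJ_mol"]),
                charge=float(row["charge"]),
                composition=comp,
            )
    return table


@dataclass(frozen=True)
class ReactionStoichiometry:
    """Signed stoichiometric coefficients of the four metabolic reactions.

    Each mapping is species -> mol per mol of the reaction's reference product
    (acetate, biomass, butyrate, caproate respectively); negative = consumed.
    """

    catabolism: Mapping[str, float] = field(
        default_factory=lambda: {
            "CO2": -2.0, "MH": -4.0, "H+": -3.0,
            "Ac": 1.0, "M+": 4.0, "H2O": 2.0,
        }
    )
    anabolism: Mapping[str, float] = field(
        default_factory=lambda: {
            "CO2": -1.0, "MH": -2.1, "NH4": -0.2, "H+": -1.9,
            "X": 1.0, "M+": 2.1, "H2O": 1.5,
        }
    )
    butyrate_elongation: Mapping[str, float] = field(
        default_factory=lambda: {
            "Ac": -2.0, "MH": -2.0, "H+": -3.0,
            "But": 1.0, "M+": 2.0, "H2O": 2.0,
        }
    )
    caproate_elongation: Mapping[str, float] = field(
        default_factory=lambda: {
            "Ac": -1.0, "But": -1.0, "MH": -2.0, "H+": -3.0,
            "Cap": 1.0, "M+": 2.0, "H2O": 2.0,
        }
    )

    def as_dict(self) -> dict[str, Mapping[str, float]]:
        return {
            "catabolism": self.catabolism,
            "anabolism": self.anabolism,
            "butyrate_elongation": self.butyrate_elongation,
            "caproate_elongation": self.caproate_elongation,
        }


class MediatorGibbs(NamedTuple):
    """Decomposition of the mediator-couple Gibbs energy (kJ/mol).

    ``total = potential_term + ph_term`` for the oxidation half-reaction
    MH -> M+ + H+ + n e- at standard conditions; ``ph_term`` moves the proton
    from the biochemical reference pH to unit activity.
    """

    total: float
    potential_term: float
    ph_term: float


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic inputs: formation energies, dissipation energy, mediator.

    ``dG_diss`` is the Gibbs energy dissipated per C-mol of biomass formed for
    chemoautotrophic CO2-reducing growth (kJ/mol_X).  ``E_M0`` is the
    biochemical-standard potential of the mediator couple (V vs SHE at pH
    ``bio_ref_pH``); ``n_e`` the electrons per mediator turnover.
    """

    formation: Mapping[str, FormationEntry] = field(default_factory=load_formation_table)
    dG_diss: float = 1076.0
    E_M0: float = -0.32
    n_e: int = 2
    T: float = 305.0
    T0: float = 298.0
    pH: float = 5.8
    bio_ref_pH: float = 7.0
    #: Composition (mol/m^3) at which the growth stoichiometry and the
    #: maintenance coefficient are evaluated for a simulation: the inoculation
    #: catholyte with CO2 at the sparged (p_CO2 = 0.3) saturation level and
    #: trace organics.  A fixed, strictly positive reference keeps the
    #: logarithmic corrections finite when a run starts from zero dissolved
    #: CO2 (where the catabolic driving force genuinely vanishes).
    reference_state: Mapping[str, float] = field(
        default_factory=lambda: {
            "CO2": 10.2, "NH4": 10.0, "Ac": 30.0, "But": 1.0, "Cap": 1.0,
            "MH": 10.0, "M+": 10.0,
        }
    )

    def __post_init__(self) -> None:
        if self.T <= 0 or self.T0 <= 0:
            raise ValueError("temperatures must be positive")
        if self.dG_diss <= 0:
            raise ValueError("dissipation energy must be positive")
        if self.n_e < 1:
            raise ValueError("n_e must be >= 1")

    @property
    def dG0_mediator(self) -> float:
        """Standard Gibbs energy of the M+/MH couple, kJ/mol (-21.85 default)."""
        return mediator_delta_g(self.E_M0, self.n_e, self).total

    def formation_energies(self) -> dict[str, float]:
        """dGf0 per species including the mediator pair (kJ/mol)."""
        out = {name: entry.dGf0 for name, entry in self.formation.items()}
        out["M+"] = 0.0
        out["MH"] = -self.dG0_mediator
        return out

    def full_table(self) -> dict[str, FormationEntry]:
        """Formation table extended with the mediator pseudo-species.

        The mediator core is tracked as a pseudo-element ``M`` so that element
        and charge balances close over reactions that turn the couple over.
        """
        table = dict(self.formation)
        table["M+"] = FormationEntry(0.0, 1.0, {"M": 1.0})
        table["MH"] = FormationEntry(-self.dG0_mediator, 0.0, {"M": 1.0, "H": 1.0})
        return table


def mediator_delta_g(E_M0: float, n: int, params: ThermoParams | None = None) -> MediatorGibbs:
    """Gibbs energy of the mediator couple from its standard redox potential.

    Returns the standard-condition Gibbs energy of the oxidation half-reaction
    MH -> M+ + H+ + n e- given a biochemical-standard potential ``E_M0``
    (defined at pH ``params.bio_ref_pH``):

        dG_ox0 = n F E_M0 + R T0 ln(10) * bio_ref_pH

    The defaults (E_M0 = -0.32 V, n = 2, pH 7, T0 = 298 K) give -21.85 kJ/mol.
    The pH-dependent correction is reported separately in the result.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = ThermoParams()
    potential = n * FARADAY * E_M0 / 1000.0
    ph_term = R_KJ * params.T0 * math.log(10.0) * params.bio_ref_pH
    return MediatorGibbs(potential + ph_term, potential, ph_term)


def _activity(species: str, concentrations: Mapping[str, float], pH: float) -> float:
    if species in _UNIT_ACTIVITY:
        return 1.0
    if species == "H+":
        return 10.0 ** (-pH)
    c = concentrations.get(species)
    if c is None or c <= 0.0:
        raise ValueError(
            f"non-positive or missing concentration for participating solute {species!r}"
        )
    return c / C_REF


def adapt_gibbs(
    reaction: Mapping[str, float],
    params: ThermoParams,
    concentrations: Mapping[str, float],
    temperature: float | None = None,
) -> float:
    """Reaction Gibbs energy at reactor conditions, kJ per reaction as written.

    ``dG = dG0 + R T sum_i nu_i ln(a_i)`` with activities a_i = C_i / 1 mol/L
    for solutes (``concentrations`` in mol/m^3), 10**-pH for the proton, and 1
    for water and biomass.  Reduces to the tabulated standard value when all
    activities are 1 and T = T0.
    """
    T = params.T if temperature is None else temperature
    if T <= 0:
        raise ValueError("temperature must be positive")
    dGf = params.formation_energies()
    dG0 = sum(nu * dGf[sp] for sp, nu in reaction.items())
    corr = sum(
        nu * math.log(_activity(sp, concentrations, params.pH))
        for sp, nu in reaction.items()
        if sp not in _UNIT_ACTIVITY
    )
    return dG0 + R_KJ * T * corr


def catabolic_multiplier(
    dG_diss: float,
    dG_an: float,
    dG_cat: float,
    dG_but: float,
    dG_cap: float,
    y_but_ac: float,
    y_cap_ac: float,
) -> float:
    """Catabolic multiplier lambda_cat.

    Number of catabolic turnovers required to pay for one anabolic turnover
    plus the elongation and dissipation energy demand:

        lambda_cat = (dG_diss + dG_an) / -(dG_cat + y_but_ac dG_but + y_cap_ac dG_cap)
    """
    denom = dG_cat + y_but_ac * dG_but + y_cap_ac * dG_cap
    if denom >= 0.0:
        raise ValueError("catabolism not exergonic at these conditions")
    lam = (dG_diss + dG_an) / (-denom)
    return max(lam, 0.0)


def metabolic_stoichiometry(
    lambda_cat: float, stoich: ReactionStoichiometry | None = None
) -> dict[str, float]:
    """Overall metabolic yield vector Y_i^Met = lambda_cat * Y_i^Cat + Y_i^An.

    Per mole of biomass formed (Y_X^Met = 1); elongation is accounted for
    separately in the rate equations.
    """
    if lambda_cat < 0:
        raise ValueError("lambda_cat must be >= 0")
    if stoich is None:
        stoich = ReactionStoichiometry()
    species = set(stoich.catabolism) | set(stoich.anabolism)
    return {
        sp: lambda_cat * stoich.catabolism.get(sp, 0.0) + stoich.anabolism.get(sp, 0.0)
        for sp in species
    }


@dataclass(frozen=True)
class MetabolicYields:
    """Growth stoichiometry at a given reactor state.

    ``y_met`` is per mole of biomass; the dG fields are per reaction as
    written at reactor conditions; ``y_but_ac``/``y_cap_ac`` are the
    formation-energy ratios weighting the elongation energies in lambda_cat.
    """

    lambda_cat: float
    y_met: Mapping[str, float]
    y_but_ac: float
    y_cap_ac: float
    dG_cat: float
    dG_an: float
    dG_but: float
    dG_cap: float


def compute_metabolic_yields(
    params: ThermoParams,
    concentrations: Mapping[str, float],
    stoich: ReactionStoichiometry | None = None,
) -> MetabolicYields:
    """Evaluate reaction energies at the given state and build the yield vector."""
    if stoich is None:
        stoich = ReactionStoichiometry()
    dG_cat = adapt_gibbs(stoich.catabolism, params, concentrations)
    dG_an = adapt_gibbs(stoich.anabolism, params, concentrations)
    dG_but = adapt_gibbs(stoich.butyrate_elongation, params, concentrations)
    dG_cap = adapt_gibbs(stoich.caproate_elongation, params, concentrations)
    dGf = params.formation_energies()
    y_but_ac = dGf["But"] / dGf["Ac"]
    y_cap_ac = dGf["Cap"] / dGf["Ac"]
    lam = catabolic_multiplier(
        params.dG_diss, dG_an, dG_cat, dG_but, dG_cap, y_but_ac, y_cap_ac
    )
    return MetabolicYields(
        lambda_cat=lam,
        y_met=metabolic_stoichiometry(lam, stoich),
        y_but_ac=y_but_ac,
        y_cap_ac=y_cap_ac,
        dG_cat=dG_cat,
        dG_an=dG_an,
        dG_but=dG_but,
        dG_cap=dG_cap,
    )


def element_charge_imbalance(
    reaction: Mapping[str, float], table: Mapping[str, FormationEntry]
) -> dict[str, float]:
    """Net element (C,H,O,N,M) and charge residuals of a reaction; 0 = balanced."""
    residual = {el: 0.0 for el in ELEMENTS}
    residual["charge"] = 0.0
    for sp, nu in reaction.items():
        entry = table[sp]
        for el, count in entry.composition.items():
            residual[el] += nu * count
        residual["charge"] += nu * entry.charge
    return residual
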