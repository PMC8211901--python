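# Methods

This note documents the model implemented in `messim`, the conventions and
numerical choices behind it, and what the bundled scenarios and synthetic
datasets do and do not represent.

## Scope and assumptions

The reactor is described as a loop of well-mixed domains; one domain holds
the cathode biofilm, at most one exchanges CO₂ with a gas phase. All
reactions occur in the biofilm, which is treated as a continuous, perfectly
mixed phase of one black-box organism: no species structure, no spatial
gradients, no detachment. pH, temperature and cathode potential are fixed;
catholyte and biofilm electrical resistances are neglected; compartment
volumes are constant. Hydrogen evolution and other side reactions are not
modelled — the raw model is 100% coulombically efficient by construction,
and experimentally reported electron recoveries can be applied to the
predicted organics as a post-hoc correction
(`reactor.apply_electron_recovery`).

## Thermodynamic growth stoichiometry

Reaction Gibbs energies are computed from a bundled table of
biochemical-standard formation energies (`data/formation_gibbs.csv`;
aqueous CO₂, NH₄⁺, water, the three carboxylates as their anions, biomass as
CH₁.₈O₀.₅N₀.₂ at −67 kJ/C-mol). The table is a replaceable input: any
mapping with the same schema can be passed to `ThermoParams`, and the
element/charge balance of every reaction is checked against it.

Conventions:

* activities are C / 1 mol/L for solutes, 1 for water and biomass, 10^−pH
  for the proton (catholyte pH 5.8);
* ΔG = ΔG⁰ + RT Σ ν ln a, with ΔG⁰ used unchanged between 298 and 305 K
  (the van't Hoff correction over 7 K is far below the uncertainty of the
  formation-energy table and would require per-species enthalpies);
* the mediator couple's standard potential (−0.32 V vs SHE, the NADH/NAD⁺
  biochemical-standard value) is converted to a couple Gibbs energy as the
  oxidation half-reaction MH → M⁺ + H⁺ + 2 e⁻ with the proton moved from
  the pH-7 reference to unit activity:
  ΔG_ox⁰ = nFE⁰′ + RT₀ ln(10)·7 = −21.85 kJ/mol. Formation energies
  ΔGf(M⁺) = 0 and ΔGf(MH) = +21.85 kJ/mol embed this in all four metabolic
  reactions. The pH term is reported separately by
  `thermo.mediator_delta_g` so the convention is auditable.

The elongation-energy weights are formation-energy ratios,
Y_Ac^But = ΔGf(But)/ΔGf(Ac) ≈ 0.955 and Y_Ac^Cap ≈ 0.909, exposed in
`MetabolicYields` for inspection.

**Reference-state evaluation.** λ_Cat, the yield vector and the maintenance
coefficient are evaluated once per simulation, at a fixed reference
composition (`ThermoParams.reference_state`, default: the inoculation
catholyte with CO₂ at the 0.3 atm saturation level, 30 mol/m³ acetate,
trace butyrate/caproate, the mediator pool split evenly). A per-timestep
evaluation is not well posed for this model: runs start from zero dissolved
CO₂, where catabolism is genuinely endergonic and the maintenance division
by ΔG_Cat is singular, and the resulting spike is an artefact of the
black-box energy balance rather than physiology. The functions
`thermo.adapt_gibbs` and `thermo.compute_metabolic_yields` accept arbitrary
compositions, so the sensitivity of the stoichiometry to this choice can be
explored directly. At the default reference state λ_Cat ≈ 11.91,
Y_CO2^Met ≈ −24.85 and m_CO2 ≈ −0.145 mol_CO2/mol_X/h.

## Electrochemistry

The Butler–Volmer rate uses concentrations in mol/m³ except the proton
term, which is the mol/L concentration 10^−pH; the published
k_e⁰ = 0.03 1/s is parameterised against that convention, so k_ef
effectively carries L/(mol s). This is applied identically in the ODE
right-hand side, the quasi-equilibrium solver and the derived current, and
is the one deliberate unit asymmetry in the package (everything else is
mol/m³, m³, hours).

At the default cathode potential the forward/backward coefficient ratio is
~10²⁹ and the mediator pool relaxes on a ~10⁻¹¹ h timescale. Two
integration modes handle this:

* `mediator_mode="ode"` — the full stiff system, integrated with BDF at
  rtol 1e-6 / atol 1e-9 (finite-difference Jacobian);
* `mediator_mode="qe"` — the electrochemical rate is equated to the
  instantaneous metabolic mediator consumption and C_M⁺ follows
  algebraically from the Butler–Volmer relation (two fixed-point sweeps,
  which converge because C_M⁺ ≪ pool at practical overpotentials); the
  mediator series is reconstructed on the output grid.

The two modes agree to ~10⁻⁷ relative on the bundled scenarios (tested),
and the qe mode is roughly twice as fast; fits default to it.

## Kinetics

Default parameters (mol/m³, mol/mol_X/h): K_CO2 = 3.8, K_NH4 = 0.05,
K_MH = 0.1, K_Ac = 0.27, K_But = 0.076; critical concentrations
C* = 800 / 285 / 170 for Ac/But/Cap; fitted maxima q_CO2^max = −0.307,
q_But^max = 2.12e-2, q_Cap^max = 4.64e-3; thresholds C_Ac^t = 123,
C_But^t = 43. Consumption is negative throughout, so conservation sums are
literal. Sigmoid gate constants are fixed at A = 10/C_t (steepness) and
T = 1.1 C_t (gate midpoint); they are shape parameters without biological
meaning.

Choices worth flagging:

* Maintenance is the Tijhuis-style Gibbs-energy demand
  3.3·exp[−(69.4/R)(1/T − 1/T₀)] kJ/mol_X/h divided by the signed catabolic
  reaction energy at the reference state — the division by ΔG_Cat < 0 makes
  m_CO2 an uptake (negative) automatically. Dividing instead by the energy
  per mole of CO₂ (half the reaction energy) would double the maintenance
  flow and suppress growth an order of magnitude below reported acetogen
  growth rates, so the per-reaction reading is used.
* μ = (q_CO2 − m_CO2)/Y_CO2^Met: μ = 0 exactly when uptake equals
  maintenance, and μ < 0 (biomass loss) when it cannot. The Herbert–Pirt
  split for other species is
  q_i = Y_i^Met μ + m_CO2 (Y_i^Cat/Y_CO2^Cat) + Y_i^But q_But + Y_i^Cap q_Cap
  — maintenance runs pure catabolism, so it consumes CO₂/MH and produces
  acetate. Applied to CO₂ this returns q_CO2 identically, which is what
  makes the full rate vector conserve C, H, O, N and charge exactly (a
  tested invariant).
* Product inhibition multiplies the CO₂ uptake and both elongation rates;
  maintenance is left uninhibited, as in the source equations.
  Consequently, at critical product concentrations all uptake and
  production stop but μ is slightly negative (maintenance decay), not zero.
* Inhibition terms are clamped at 0 above the critical concentration;
  without the clamp, transient overshoot of C* would produce negative
  (reversed) rates, which is unphysical.
* The diagnostic "maximum growth rate" time series is μ evaluated with
  every Monod term at 1 but inhibition at the current state. This makes
  μ_max time-varying as products accumulate, which is the quantity a
  culture's instantaneous growth capacity corresponds to; it is labelled
  `mu_max_h` in the derived series.

## Reactor mass balances

Per dilute species and domain:
dC/dt = (Q_R/V)(C_upstream − C) + feed/outflow + reaction + gas transfer,
with feed and outflow at the sampling-port bulk domain (measurements refer
to liquid leaving that compartment), reaction terms only in the biofilm and
kLa (K_H p_CO2 − C) only in the gas-exchange domain while sparging is on.
The dilution feed flow is D_RL · V_ref with V_ref the bulk liquid volume
(370 mL for the reference geometry); at HRT 14 d this reproduces the
reported 0.018 mL/min dilution flow. Biomass grows in the fixed biofilm
volume without outflow and without a packing limit; the mediator source
terms are antisymmetric, so C_MH + C_M⁺ is conserved to machine precision.

Henry coefficient: 34 mol/(m³ atm), back-calculated from the statement that
the equilibrium dissolved CO₂ concentration at 1 atm is 34 mmol/L;
configurable.

Numerical details: segments are integrated one at a time with
`scipy.solve_ivp` (BDF), instantaneous events (catholyte replacement:
dilute species reset to fresh medium, biofilm biomass and mediator pool
retained) applied between segments; output concentrations are clipped at 0
(solver excursions stay within −atol); a 10× tolerance refinement moves
headline outputs by <1% (tested).

## Bundled scenarios

`jourdin2019_ftr2` (fitting scenario) carries the printed geometry and
physics: bulk 370 mL, bubble column 280.9 mL, biocathode 25.5 mL,
recirculation 200 mL/min, kLa 2.5 1/h, p_CO2 0.3 atm, E_C −1.2 V, initial
biomass 5.2 mol/m³, mediator pool 20 mol/m³, initial acetate 30 mol/m³,
HRT stepped 4 → 8 → 14 d. Values the source does not print are
reconstructed and listed in `Scenario.reconstructed`: the HRT switch times
(day 30 and 90 over a 150 d horizon), the bulk split (185/185 mL), the feed
ammonium (10 mol/m³, 200× its half-saturation constant, so nitrogen is
non-limiting as reported), and the 50/50 initial mediator split (erased
within simulated minutes by the fast electrochemistry — tested via the
mode-agreement check).

The two validation scenarios (`jourdin2018_fedbatch`,
`marshall2013_batches`) are narrative reconstructions: period boundaries,
sparging duty cycles, recovery fractions and the Marshall two-domain
geometry are assumptions, flagged per scenario. They exercise every
schedule feature (fed-batch sparging windows, catholyte replacement,
continuous operation, per-segment recoveries) and reproduce the qualitative
findings — the Marshall reconstruction (pure CO₂, −0.59 V, sparse initial
colonization) yields ~23 mol/m³ biomass after 50 d and an acetate-only
product spectrum via the elongation thresholds — but their quantitative
outputs should not be read as predictions of the original experiments.

## Synthetic datasets and what the tests show

`generate_synthetic_dataset` simulates a scenario with known kinetic
parameters, samples the organics at the sampling port, and adds independent
Gaussian noise truncated at zero. The default observation design for
fitting studies is one sample per species every 3 days over the 150 d run
(≈ the reference experiment's cadence) with σ = 5 mol/m³ for the noisy
case. Parameter recovery under this design (all five parameters within 5%
noise-free, within 15% at σ = 5 from a ±20% perturbed start) shows the
estimator and the model's identifiability under the model's own
assumptions. It does not show that real MES data identify these parameters:
real observations carry structured error (mixed-culture dynamics, electron
losses, pH drift) that the noise model deliberately omits, and the
elongation thresholds are only identified if the data cross them.

Fits run at a 12 h output grid in quasi-equilibrium mode with Nelder–Mead
(adaptive simplex, log-space parameters, xatol 1e-3 ≈ 0.1% per parameter);
simulation failures inside the optimizer return a large penalty rather than
aborting the search.

## Known limitations

* No pH dynamics, no buffer chemistry, no intra-biofilm gradients or
  electromigration, no hydrogen evolution, single population: the model is
  a reactor-scale energy and mass balance, not a biofilm microstructure
  model.
* The characteristic CO₂ reaction time at late steady state computes to
  ~27 min for the fitting scenario (C_CO2/|r_CO2| in the biofilm), longer
  than the few minutes sometimes quoted for comparable systems; it is
  sensitive to the late-run biomass level, which in turn hinges on the
  maintenance coefficient — the least constrained quantity in the
  thermodynamic chain. The ratio to the 0.13 min convective residence time
  (≳200) still supports the well-mixed domain assumption, which is the
  purpose of the diagnostic.
* The mean of the μ_max diagnostic over the 150 d fitting run is
  0.091 1/d, at the lower end of typical reported acetogen growth rates;
  the same maintenance sensitivity applies.
* Electron-recovery adjustment scales predicted concentrations per segment;
  an alternative (scaling production increments) would differ where
  segments with different recoveries follow each other.
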