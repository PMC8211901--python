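"""Physical constants and unit conversion factors used throughout the package.

Internal unit conventions:

* concentrations: mol/m^3 (= mmol/L), except the proton activity, which is a
  dimensionless activity referenced to 1 mol/L (see :mod:`messim.electrochem`
  for the one place where a mol/L proton concentration enters a rate law);
* volumes: m^3; flows: m^3/h; time: hours inside the ODE system
  (electrochemical rate constants are tabulated per second and converted at
  assembly);
* energies: kJ/mol; potentials: V vs SHE.
"""

#: Faraday constant, C/mol.
FARADAY = 96485.34

#: Universal gas constant, J/(mol K).
R_J = 8.31

#: Universal gas constant, kJ/(mol K).
R_KJ = R_J / 1000.0

#: Reference concentration for solute activities, mol/m^3 (1 mol/L).
C_REF = 1000.0

#: Seconds per hour (electrochemistry is tabulated per second, the ODE runs in hours).
S_PER_H = 3600.0

#: mL/min -> m^3/h.
ML_MIN_TO_M3_H = 60.0 * 1e-6

#: Hours per day.
H_PER_D = 24.0
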