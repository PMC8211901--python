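# Biochemical-standard Gibbs energies of formation (298 K, 1 mol/L solutes, pH 0)
# used to evaluate reaction Gibbs energies of the black-box metabolism.
# Values follow the thermodynamic state-analysis convention for environmental
# biotechnology (aqueous species; biomass as the C-mol formula CH1.8O0.5N0.2).
# The table is a replaceable input: pass an alternative mapping to ThermoParams.
# columns: species, dGf0 in kJ/mol, charge, elemental composition (C,H,O,N)
species,dGf0_kJ_mol,charge,C,H,O,N
CO2,-386.02,0,1,0,2,0
NH4,-79.37,1,0,4,0,1
H+,0.0,1,0,1,0,0
H2O,-237.18,0,0,2,1,0
Ac,-369.41,-1,2,3,2,0
But,-352.63,-1,4,7,2,0
Cap,-335.85,-1,6,11,2,0
X,-67.0,0,1,1.8,0.5,0.2
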