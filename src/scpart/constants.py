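"""Physical constants (CODATA 2018) and unit conversion factors."""

#: Universal gas constant, J mol^-1 K^-1.
R_J = 8.314462618

#: Universal gas constant, kJ mol^-1 K^-1 (free energies are handled in kJ/mol).
R_KJ = 8.314462618e-3

#: Avogadro constant, mol^-1.
N_A = 6.02214076e23

#: Atomic mass unit, kg.
AMU_KG = 1.66053906660e-27

#: 1 nm^3 in liters.
NM3_TO_L = 1e-24

#: 1 nm^3 in m^3.
NM3_TO_M3 = 1e-27

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 303.15

#: Default SASA probe radius (water), nm.
DEFAULT_PROBE_RADIUS = 0.14
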