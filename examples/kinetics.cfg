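# Kinetic constants and temperature responses (defaults shown).
# CO2 constants in Pa, O2 in kPa, activation energies in kJ/mol.
gamma_star_25 = 4.275
kc_25 = 40.49
ko_25 = 27.84
o2 = 21.0
ha_gamma_star = 37.83
ha_kc = 79.43
ha_ko = 36.38
# fluorescence factors used for J_f = PhiII * Qin * absorptance * beta_psii
absorptance = 0.85
beta_psii = 0.5
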