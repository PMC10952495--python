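"""Physical constants used throughout (SI, CODATA 2018 where exact)."""

#: Gas constant, J mol^-1 K^-1 (value used in the fitted models)
R_J = 8.314
#: Gas constant, kJ mol^-1 K^-1
R_KJ = R_J / 1000.0
#: Boltzmann constant, J K^-1
KB = 1.380649e-23
#: Planck constant, J s
H_PLANCK = 6.62607015e-34
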