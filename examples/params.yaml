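# Pentagon food-web parameters at 17 degC.
# Rates/yields/sigma/Q10 are the published reference values; Y_BC and psi
# have no published value and the numbers below are illustrative choices
# (see docs/methods.md).
alpha_B: 0.08      # L nmol-P^-1 h^-1, prokaryote phosphate affinity
alpha_A: 0.04      # L nmol-P^-1 h^-1, autotroph phosphate affinity
alpha_H: 0.0015    # L nmol-P^-1 h^-1, HNF clearance on prokaryotes
alpha_C: 0.0005    # L nmol-P^-1 h^-1, ciliate clearance on flagellates
Y_H: 0.3           # nmol-P nmol-P^-1
Y_BC: 0.006        # nmol-P nmol-C^-1  (illustrative, must be configured)
sigma: 0.00043     # nmol-P cell^-1
Q10: 1.3
T_ref: 17.0
psi: 3.0           # nmol-C L^-1 h^-1  (illustrative, must be configured)
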