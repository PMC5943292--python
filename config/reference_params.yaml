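# Reference kinetic parameters for deGFP expression from an E. coli TXTL
# extract confined in water-in-oil droplets.  Rates in s^-1 unless noted;
# T_s is given in minutes and the surface-layer thickness in nanometres —
# the loader converts both on read.
k_R: 3.22e-3        # transcription rate, molecules um^-3 s^-1
k_on: 1.0           # surface attachment rate
k_off: 3.86e-3      # surface dissociation rate
gamma_R: 1.39e-3    # free-mRNA degradation rate
gamma_R_star: 1.39e-3  # surface-layer mRNA degradation rate
alpha: 9.02         # bulk translation rate
alpha_star: 1.96e-1 # surface-layer translation rate
T_s_min: 153        # saturation time, minutes
lambda_nm: 30       # surface-layer thickness, nm
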