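# Drift-gas constants used by the Langevin polarization-limit transfer.
# Dielectric constants are CRC-style values at 20 C and 1 atm; their ratio
# (D-1 terms) equals the ratio of the molecular polarizabilities
# (1.740 A^3 for N2, 1.569 A^3 for O2), which is what the correction uses.
name,mass_da,dielectric
N2,28.0134,1.000547
O2,31.9988,1.000494
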