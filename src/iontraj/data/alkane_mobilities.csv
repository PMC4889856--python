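# Experimental drift-tube mobilities of n-alkane ions (each clustered with
# one water molecule, ionized by electron abstraction) and trajectory-method
# values computed from DFT structures under three partial-charge schemes.
# All mobilities in cm^2 V^-1 s^-1.
species,n_carbons,reference,mulliken,mk,hirshfeld
hexane,6,1.92,1.67,1.84,1.83
heptane,7,1.81,1.52,1.72,1.72
octane,8,1.71,1.52,1.73,1.75
nonane,9,1.62,1.44,1.63,1.64
decane,10,1.53,1.48,1.56,1.56
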