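# Reference mobilities of the protonated water clusters (H3O+)(H2O)n that
# form the reactant-ion peak in positive-mode drift-tube IMS, together with
# trajectory-method values computed from DFT structures under three
# partial-charge schemes (Mulliken, Merz-Kollman-Singh, Hirshfeld).
# The reference column comes from an independent particle-tracing /
# reaction-simulation treatment that reproduced measured RIP spectra.
# All mobilities in cm^2 V^-1 s^-1.
species,n,reference,mulliken,mk,hirshfeld
H3O+,0,3.57,3.16,3.00,3.23
(H3O+)(H2O)1,1,2.76,2.71,2.65,2.75
(H3O+)(H2O)2,2,2.35,2.50,2.45,2.55
(H3O+)(H2O)3,3,1.97,2.38,2.26,2.37
(H3O+)(H2O)4,4,1.88,2.18,2.13,2.25
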