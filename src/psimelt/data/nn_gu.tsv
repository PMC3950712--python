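# G-U wobble nearest-neighbor free-energy increments, 1 M NaCl, 37 C.
# Source set: Chen et al. (2012) Biochemistry 51:3508 (revised G-U parameters, the set used by
# RNAstructure for the duplex-level predictions this table is reconstructed against).
# Provenance tags:
#   Chen2012-derived     single stack pinned by one terminal-extension prediction
#   reconstructed-sum    only the SUM of the two stacks sharing a duplex is constrained
#                        (CU/GG + UG/GC = -3.02; AU/UG + UU/GA = -1.25; UU/AG + UA/GU = -0.88)
# The revised scheme carries no separate terminal G-U penalty (entry kept explicit at 0).
kind	key	dG37_kcal_mol	provenance
stack	UC/GG	-1.81	Chen2012-derived
stack	GU/CG	-2.13	Chen2012-derived
stack	CU/GG	-1.51	reconstructed-sum
stack	UG/GC	-1.51	reconstructed-sum
stack	AU/UG	-0.62	reconstructed-sum
stack	UU/GA	-0.63	reconstructed-sum
stack	UU/AG	-0.44	reconstructed-sum
stack	UA/GU	-0.44	reconstructed-sum
terminal	GU	0.00	Chen2012-derived
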