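# Single-nucleotide dangling-end free-energy increments, 1 M NaCl, 37 C (Turner 2004 set;
# Serra & Turner compilation as distributed with ViennaRNA/RNAstructure).
# kind: dangle5 = unpaired base 5' of the adjacent pair on the same strand;
#       dangle3 = unpaired base 3' of the adjacent pair on the same strand.
# pair: adjacent base pair written top/bottom with the dangling base on the top strand.
kind	key	dG37_kcal_mol	provenance
dangle5	A@CG	-0.5	Turner2004
dangle5	C@CG	-0.3	Turner2004
dangle5	G@CG	-0.2	Turner2004
dangle5	U@CG	-0.1	Turner2004
dangle5	A@GC	-0.2	Turner2004
dangle5	C@GC	-0.3	Turner2004
dangle5	G@GC	0.0	Turner2004
dangle5	U@GC	0.0	Turner2004
dangle5	A@AU	-0.3	Turner2004
dangle5	C@AU	-0.3	Turner2004
dangle5	G@AU	-0.4	Turner2004
dangle5	U@AU	-0.2	Turner2004
dangle5	A@UA	-0.3	Turner2004
dangle5	C@UA	-0.1	Turner2004
dangle5	G@UA	-0.2	Turner2004
dangle5	U@UA	-0.2	Turner2004
dangle5	A@GU	-0.3	Turner2004
dangle5	C@GU	-0.3	Turner2004
dangle5	G@GU	-0.4	Turner2004
dangle5	U@GU	-0.2	Turner2004
dangle5	A@UG	-0.3	Turner2004
dangle5	C@UG	-0.1	Turner2004
dangle5	G@UG	-0.2	Turner2004
dangle5	U@UG	-0.2	Turner2004
dangle3	A@CG	-1.1	Turner2004
dangle3	C@CG	-0.4	Turner2004
dangle3	G@CG	-1.3	Turner2004
dangle3	U@CG	-0.6	Turner2004
dangle3	A@GC	-1.7	Turner2004
dangle3	C@GC	-0.8	Turner2004
dangle3	G@GC	-1.7	Turner2004
dangle3	U@GC	-1.2	Turner2004
dangle3	A@AU	-0.7	Turner2004
dangle3	C@AU	-0.1	Turner2004
dangle3	G@AU	-0.7	Turner2004
dangle3	U@AU	-0.1	Turner2004
dangle3	A@UA	-0.8	Turner2004
dangle3	C@UA	-0.5	Turner2004
dangle3	G@UA	-0.8	Turner2004
dangle3	U@UA	-0.6	Turner2004
dangle3	A@GU	-0.7	Turner2004
dangle3	C@GU	-0.1	Turner2004
dangle3	G@GU	-0.7	Turner2004
dangle3	U@GU	-0.1	Turner2004
dangle3	A@UG	-0.8	Turner2004
dangle3	C@UG	-0.5	Turner2004
dangle3	G@UG	-0.8	Turner2004
dangle3	U@UG	-0.6	Turner2004
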