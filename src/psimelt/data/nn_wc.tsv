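# Watson-Crick nearest-neighbor free-energy increments for RNA duplexes, 1 M NaCl, 37 C.
# Stack keys are written 5'XY3'/3'WZ5' as XY/WZ; each key is equivalent to its 180-degree rotation.
# Values: Xia et al. (1998) Biochemistry 37:14719 (Turner-rules WC set).
kind	key	dG37_kcal_mol	provenance
stack	AA/UU	-0.93	Xia1998
stack	AU/UA	-1.10	Xia1998
stack	UA/AU	-1.33	Xia1998
stack	CU/GA	-2.08	Xia1998
stack	CA/GU	-2.11	Xia1998
stack	GU/CA	-2.24	Xia1998
stack	GA/CU	-2.35	Xia1998
stack	CG/GC	-2.36	Xia1998
stack	GG/CC	-3.26	Xia1998
stack	GC/CG	-3.42	Xia1998
init	initiation	4.09	Xia1998
terminal	AU	0.45	Xia1998
terminal	GC	0.00	Xia1998
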