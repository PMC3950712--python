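# Printed free-energy increments (ddG37, kcal/mol) for adding a terminal nucleotide or pair
# to the core duplexes, with propagated sds as printed; Tm^-1-plot energies throughout.
# extended_system/extended_variant link each row to the duplex it extends in table1_duplexes.tsv.
# predicted: literature nearest-neighbor or single-measurement value printed alongside (magnitude
# sign as printed; empty where none was printed).
core	label	extended_system	extended_variant	ddG	ddG_sd	predicted
core1	5'U	dang5	u	-0.78	0.28	-0.1
core1	5'P	dang5	psi	-0.66	0.16
core1	5'U/3'A	term5_PA	u	-1.88	0.37	-1.9
core1	5'P/3'A	term5_PA	psi	-1.81	0.17	-2.18
core1	5'U/3'G	term5_PG	u	-1.78	0.39	-1.8
core1	5'P/3'G	term5_PG	psi	-1.53	0.19
core1	5'U/3'U	term5_PU	u	-0.86	0.23	-1.0
core1	5'P/3'U	term5_PU	psi	-1.41	0.17
core1	5'U/3'C	term5_PC	u	-1.12	0.16	-0.9
core1	5'P/3'C	term5_PC	psi	-0.81	0.21
core2	3'U	dang3	u	-0.97	0.31	-0.6
core2	3'P	dang3	psi	-0.97	0.29
core2	3'U/5'A	term3_PA	u	-2.18	0.37	-1.79
core2	3'P/5'A	term3_PA	psi	-2.10	0.45	-2.98
core2	3'U/5'G	term3_PG	u	-2.44	0.28	-2.15
core2	3'P/5'G	term3_PG	psi	-3.22	0.22
core2	3'U/5'U	term3_PU	u	-1.05	0.16	-1.0
core2	3'P/5'U	term3_PU	psi	-1.83	0.23
core2	3'U/5'C	term3_PC	u	-1.36	0.17	-1.2
core2	3'P/5'C	term3_PC	psi	-1.52	0.19
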