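# Printed free-energy effects (ddG37, kcal/mol) of replacing the central U with pseudouridine,
# i.e. dG37(Psi duplex) - dG37(U duplex), Tm^-1-plot energies; sds as printed.
# system links to table1_duplexes.tsv (psi and u variants of the same system).
# predicted: nearest-neighbor predicted difference where printed (Psi-A columns only).
system	motif	opposite	ddG	ddG_sd	predicted
mid_PA	5'GPC/3'CXG	A	-0.71	0.55	-1.2
mid_PG	5'GPC/3'CXG	G	-1.40	0.34
mid_PU	5'GPC/3'CXG	U	-0.77	0.14
mid_PC	5'GPC/3'CXG	C	-0.27	0.05
mid_CPG_A	5'CPG/3'GXC	A	-2.43	0.49	-0.8
mid_CPG_G	5'CPG/3'GXC	G	-0.43	0.14
mid_APU_A	5'APU/3'UXA	A	-0.27	0.27	-3.5
mid_APU_G	5'APU/3'UXA	G	-0.82	0.10
mid_UPA_A	5'UPA/3'AXU	A	-0.55	0.19	-1.5
mid_UPA_G	5'UPA/3'AXU	G	-0.84	0.07
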