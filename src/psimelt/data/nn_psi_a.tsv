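# Pseudouridine-adenosine nearest-neighbor free-energy increments (P = pseudouridine), 1 M NaCl, 37 C.
# Source set: Hudson, Bloomingdale & Znosko (2013) RNA 19:1474 (Psi-A parameters).
# Provenance tags:
#   Hudson2013-quoted       value quoted directly in the analysed study's Results text
#   Hudson2013-enhancement  value = Xia1998 U-A analog + quoted Psi enhancement (-1.70 / -1.81)
#   reconstructed-sum       only the SUM of the two stacks sharing a tag is constrained by the
#                           study's duplex-level predictions; the split is an even convention.
#                           (CP/GA + PG/AC = -4.90; UP/AA + PA/AU = -3.55)
kind	key	dG37_kcal_mol	provenance
stack	PC/AG	-2.49	Hudson2013-quoted
stack	GP/CA	-3.29	Hudson2013-quoted
stack	AP/UA	-2.80	Hudson2013-enhancement
stack	PU/AA	-2.74	Hudson2013-enhancement
stack	CP/GA	-2.45	reconstructed-sum
stack	PG/AC	-2.45	reconstructed-sum
stack	UP/AA	-1.78	reconstructed-sum
stack	PA/AU	-1.77	reconstructed-sum
terminal	PA	0.31	Hudson2013-quoted
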