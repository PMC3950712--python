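# Nearest-neighbor molar extinction coefficients at 260 nm (single-stranded RNA, 25 C),
# units M^-1 cm^-1. Dinucleoside-phosphate values of Cantor, Warshaw & Shapiro (1970);
# mononucleotide values from the same standard compilation.
# epsilon(strand) = sum_i 2*eps(N_i N_i+1) - sum_interior eps(N_i); pseudouridine (P) is
# assigned the coefficients of U (the study's stated approximation).
kind	key	eps_260
mono	A	15400
mono	C	7200
mono	G	11500
mono	U	9900
di	AA	27400
di	AC	21200
di	AG	25000
di	AU	24000
di	CA	21000
di	CC	14200
di	CG	17800
di	CU	16200
di	GA	25200
di	GC	17400
di	GG	21600
di	GU	21200
di	UA	24600
di	UC	17200
di	UG	20000
di	UU	19600
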