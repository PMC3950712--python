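# Measured thermodynamics of the 22 duplex systems (20 Psi test duplexes + 2 cores), 1 M NaCl, pH 7.
# Values are transcribed as printed, i.e. magnitudes: columns hold -dH (kcal/mol), -dS (eu),
# -dG37 (kcal/mol) and Tm at 1e-4 M total strand (C), for both estimation routes
# (avg_ = average of individual curve fits, plot_ = Tm^-1 vs ln(CT/4) regression).
# variant: psi = pseudouridine-containing duplex, u = isosequential U analog, core = unmodified core.
# pred_psi: Psi-A nearest-neighbor predicted -dG37 where printed; pred_wc: WC/G-U
# nearest-neighbor predicted -dG37 where printed. two_state: 0 marks the duplex whose melt
# showed two transitions (two-state analysis invalid).
system	variant	top	bottom	avg_mdh	avg_mdh_sd	avg_mds	avg_mds_sd	avg_mdg	avg_mdg_sd	avg_tm	plot_mdh	plot_mdh_sd	plot_mds	plot_mds_sd	plot_mdg	plot_mdg_sd	plot_tm	pred_psi	pred_wc	two_state
dang5	psi	PCAGUCAGU	-GUCAGUCA	78.5	2.8	216.8	8.5	11.23	0.14	56.8	71.7	1.4	195.8	4.3	10.92	0.06	57.2			1
dang5	u	UCAGUCAGU	-GUCAGUCA	76.3	4.1	210.2	12.7	11.06	0.21	56.6	75.8	5.1	208.7	15.8	11.04	0.24	56.6			1
dang3	psi	UCAGUCAGP	AGUCAGUC-	77.1	8.3	212.7	25.5	11.17	0.44	56.9	72.9	5.1	199.9	15.8	10.93	0.25	56.9			1
dang3	u	UCAGUCAGU	AGUCAGUC-	83.8	12.3	234.5	38.2	11.05	0.51	54.7	78.7	6.3	218.5	19.6	10.93	0.27	55.4			1
term5_PA	psi	PCAGUCAGU	AGUCAGUCA	76.0	3.4	207.3	10.6	11.64	0.13	59.9	84.3	2.0	233.0	6.1	12.07	0.11	58.8	12.33		1
term5_PA	u	UCAGUCAGU	AGUCAGUCA	92.6	8.1	257.6	24.7	12.68	0.50	59.1	83.7	5.6	230.7	17.3	12.14	0.34	59.3		12.5	1
mid_PA	psi	UCAGPCAGU	AGUCAGUCA	85.0	7.2	233.1	21.9	12.73	0.37	61.4	87.2	7.0	239.9	21.1	12.85	0.43	61.2	13.69		1
mid_PA	u	UCAGUCAGU	AGUCAGUCA	92.6	8.1	257.6	24.7	12.68	0.50	59.1	83.7	5.6	230.7	17.3	12.14	0.34	59.3		12.5	1
mid_CPG_A	psi	UCACPGAGU	AGUGACUCA	105.5	8.2	293.3	24.4	14.51	0.32	62.4	104.9	6.2	291.6	18.5	14.44	0.47	62.3	13.28		1
mid_CPG_A	u	UCACUGAGU	AGUGACUCA	85.4	8.5	236.5	12.1	12.07	0.22	58.5	84.6	2.8	234.1	8.4	12.01	0.14	58.5		12.5	1
mid_APU_A	psi	UCAAPUAGU	AGUUAAUCA	78.9	7.3	226.8	22.9	8.51	0.18	45.0	71.5	2.7	203.5	8.7	8.36	0.05	45.2	11.41		1
mid_APU_A	u	UCAAUUAGU	AGUUAAUCA	83.2	9.1	242.0	28.8	8.16	0.25	43.2	80.2	8.6	232.5	27.4	8.09	0.27	43.2		7.9	1
mid_UPA_A	psi	UCAUPAAGU	AGUAAUUCA	76.7	8.0	220.1	25.1	8.48	0.19	45.1	74.1	4.1	211.8	13.3	8.42	0.08	45.1	9.37		1
mid_UPA_A	u	UCAUUAAGU	AGUAAUUCA	80.1	5.9	232.7	19.2	7.87	0.07	42.3	84.3	9.2	246.5	29.9	7.87	0.17	42.0		7.9	1
term3_PA	psi	UCAGUCAGP	AGUCAGUCA	79.8	10.2	218.7	31.1	11.97	0.55	59.7	82.6	6.8	227.3	20.9	12.06	0.42	59.3	12.44		1
term3_PA	u	UCAGUCAGU	AGUCAGUCA	92.6	8.1	257.6	24.7	12.68	0.50	59.1	83.7	5.6	230.7	17.8	12.14	0.34	59.3		12.5	1
term5_PG	psi	PCAGUCAGU	GGUCAGUCA	77.7	4.5	213.5	13.7	11.51	0.28	58.2	83.5	2.4	231.3	7.3	11.79	0.12	57.8			1
term5_PG	u	UCAGUCAGU	GGUCAGUCA	89.4	7.8	248.2	23.7	12.42	0.46	58.9	83.3	6.5	229.6	19.7	12.04	0.36	59.0		12.5	1
mid_PG	psi	UCAGPCAGU	AGUCGGUCA	95.8	10.3	264.9	30.8	13.62	0.76	61.8	93.4	4.2	257.9	12.8	13.41	0.27	61.7			1
mid_PG	u	UCAGUCAGU	AGUCGGUCA	94.3	4.2	263.9	12.9	12.51	0.32	58.0	84.9	3.5	235.1	10.8	12.01	0.18	58.4		11.9	1
mid_CPG_G	psi	UCACPGAGU	AGUGGCUCA	82.2	6.6	227.2	19.9	11.77	0.42	58.1	79.5	2.3	218.8	7.3	11.61	0.12	58.2			1
mid_CPG_G	u	UCACUGAGU	AGUGGCUCA	105.9	7.0	301.3	20.8	12.49	0.66	55.5	76.8	1.8	211.5	5.6	11.18	0.08	57.0		11.4	0
mid_APU_G	psi	UCAAPUAGU	AGUUGAUCA	75.6	5.7	218.4	18.4	7.89	0.14	42.7	68.4	5.0	195.5	15.9	7.82	0.10	43.0			1
mid_APU_G	u	UCAAUUAGU	AGUUGAUCA	79.5	12.1	233.5	38.6	7.04	0.15	39.0	73.1	2.4	213.2	7.8	7.00	0.02	39.0		7.3	1
mid_UPA_G	psi	UCAUPAAGU	AGUAGUUCA	78.8	8.5	230.2	27.2	7.41	0.12	40.5	70.7	2.5	204.0	8.2	7.40	0.02	40.9			1
mid_UPA_G	u	UCAUUAAGU	AGUAGUUCA	71.4	1.1	209.4	3.8	6.41	0.14	36.5	62.9	3.2	181.6	10.5	6.56	0.07	37.1		6.7	1
term3_PG	psi	UCAGUCAGP	AGUCAGUCG	99.7	5.6	277.6	17.1	13.60	0.35	60.7	93.1	2.6	257.6	7.9	13.18	0.16	60.9			1
term3_PG	u	UCAGUCAGU	AGUCAGUCG	95.9	8.4	267.5	25.5	12.98	0.53	59.3	86.7	4.2	239.6	12.7	12.40	0.24	59.5		12.9	1
term5_PU	psi	PCAGUCAGU	UGUCAGUCA	87.4	6.8	243.4	20.8	11.95	0.36	57.5	82.3	1.7	227.7	5.2	11.67	0.09	57.7			1
term5_PU	u	UCAGUCAGU	UGUCAGUCA	78.6	6.2	217.3	19.1	11.24	0.32	56.7	76.7	4.0	211.5	12.2	11.12	0.18	56.7			1
mid_PU	psi	UCAGPCAGU	AGUCUGUCA	77.2	7.7	217.9	24.0	9.62	0.27	49.9	69.4	4.2	193.7	13.2	9.35	0.13	50.1			1
mid_PU	u	UCAGUCAGU	AGUCUGUCA	75.5	9.4	214.9	29.4	8.83	0.31	46.8	65.7	2.6	184.0	8.1	8.58	0.05	47.0			1
term3_PU	psi	UCAGUCAGP	AGUCAGUCU	83.4	5.1	231.2	15.7	11.70	0.27	57.5	85.7	4.1	238.2	12.6	11.79	0.22	57.3			1
term3_PU	u	UCAGUCAGU	AGUCAGUCU	78.7	3.1	218.0	9.5	11.10	0.15	56.1	76.9	1.2	212.6	3.6	11.01	0.05	56.2			1
term5_PC	psi	PCAGUCAGU	CGUCAGUCA	74.4	3.8	204.1	11.9	11.08	0.20	57.2	74.9	3.4	206.0	10.6	11.07	0.15	57.0			1
term5_PC	u	UCAGUCAGU	CGUCAGUCA	78.4	1.1	215.6	3.3	11.56	0.09	58.3	74.8	1.2	204.5	3.7	11.38	0.06	58.5			1
mid_PC	psi	UCAGPCAGU	AGUCCGUCA	69.6	5.3	197.2	17.0	8.41	0.10	45.6	67.2	1.5	189.8	4.7	8.34	0.02	45.6			1
mid_PC	u	UCAGUCAGU	AGUCCGUCA	77.6	12.3	223.7	38.5	8.23	0.32	43.9	69.8	3.1	199.1	9.8	8.07	0.05	44.0			1
term3_PC	psi	UCAGUCAGP	AGUCAGUCC	77.7	3.3	214.1	10.3	11.32	0.16	57.4	81.6	2.2	226.0	6.8	11.48	0.11	57.0			1
term3_PC	u	UCAGUCAGU	AGUCAGUCC	74.9	4.2	205.9	12.9	11.05	0.22	56.9	80.7	1.4	223.8	4.1	11.32	0.07	56.6			1
core1	core	CAGUCAGU	GUCAGUCA	71.0	3.5	196.6	11.0	10.04	0.14	53.1	77.6	4.0	217.1	12.4	10.26	0.15	52.7			1
core2	core	UCAGUCAG	AGUCAGUC	73.5	5.0	204.5	15.6	10.07	0.22	52.7	71.2	3.9	197.4	12.3	9.96	0.15	52.7			1
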