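line_id	donor	chromosome	a_mean	a_sd	r2_mean	r2_sd	seasons	detected_seasons
S1	W14	1	-0.18	0.02	28.6	7.0	abcd	ab
S2	W14	1	-0.17	0.10	29.4	11.8	abcd	acd
S3	W09	2	0.10	0.04	20.0	4.5	abcd	bd
S4	W08	2	0.11	0.06	18.9	10.9	abcd	bc
S5	W06	3	0.16	0.02	33.0	1.0	acd	cd
S6	W06	3	0.16	0.01	29.8	7.8	acd	acd
S7	W06	3	0.18	0.01	36.2	5.4	acd	cd
S8	W17	3	-0.10	0.01	19.2	5.8	abcd	ad
S9	W06	4	-0.14	0.01	25.8	7.0	acd	ad
S10	W06	4	-0.16	0.08	26.9	6.6	acd	ad
S11	W06	4	-0.20	0.13	32.9	13.8	acd	ad
S12	W11	5	0.15	0.02	28.0	1.5	abcd	bcd
S13	W01	5	0.14	0.01	28.7	2.2	bcd	cd
S14	W27	6	0.06	0.01	8.9	0.5	acd	ac
S15	W23	6	0.15	0.02	29.9	9.9	abcd	bd
S16	W06	7	-0.22	0.09	39.4	3.7	acd	ad
S17	W05	7	-0.24	0.08	39.9	8.9	abcd	abc
S18	W06	8	0.15	0.02	26.9	4.4	abcd	bc
S19	W06	8	0.17	0.03	33.6	1.3	abcd	cd
S20	W06	8	0.15	0.01	28.3	2.4	abcd	bcd
S21	W27	9	-0.21	0.01	34.2	6.0	abcd	ac
S22	W06	11	0.16	0.01	32.2	4.3	abcd	bd
S23	W06	11	0.15	0.03	30.3	9.8	abcd	cd
S24	W17	11	-0.19	0.07	34.1	9.7	acd	acd
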