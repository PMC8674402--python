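recomb_id	chromosome	het_start_bp	het_end_bp	marker_id	marker_pos_bp	n_progeny	r	p
S6_R1	3	2900000	3400000	P1	3000000	86	0.70	1.0e-06
S6_R2	3	2800000	3067300	P1	3000000	78	0.08	0.49
S6_R3	3	3067301	3600000	P8	3500000	81	0.56	5.0e-05
S6_R4	3	3400001	3800000	P13	3750000	70	0.05	0.68
S6_R5	3	3700000	4100000	P13	3750000	74	-0.03	0.80
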