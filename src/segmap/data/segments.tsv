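line_id	chromosome	core_start_marker	core_end_marker	max_start_marker	max_end_marker
S1	1	RM297	RM212	RM246	RM315
S2	1	RM237	RM212	RM5	RM315
S3	2	RM263	RM530	RM106	RM240
S4	2	RM263	RM166	PSM122	RM213
S5	3	RM489	PSM428	RM175	PSM429
S6	3	RM489	RM218	RM231	RM563
S7	3	RM545	RM218	RM489	RM563
S8	3	RM426	RM168	PSM127	RM186
S9	4	RM273	RM252	RM119	RM241
S10	4	RM273	RM252	PSM194	RM241
S11	4	PSM196	RM252	PSM358	RM241
S12	5	RM31	PSM386	RM480	End
S13	5	RM178	RM334	PSM384	End
S14	6	RM508	RM217	End	RM253
S15	6	RM508	RM121	End	RM136
S16	7	RM481	PSM143	RM481	PSM143
S17	7	RM2	RM10	PSM142	PSM353
S18	8	RM547	PSM393	PSM155	PSM393
S19	8	RM556	RM210	RM284	RM80
S20	8	RM515	OSR7	PSM394	RM447
S21	9	RM434	RM410	RM105	RM257
S22	11	PSM412	PSM414	PSM409	PSM414
S23	11	PSM175	RM536	PSM174	PSM415
S24	11	PSM365	PSM417	RM21	PSM460
S25	3	PSM430	PSM431	PSM433	PSM434
S26	3	PSM435	PSM436	PSM437	PSM438
S27	5	PSM387	End	PSM389	End
S28	7	PSM354	PSM355	PSM356	PSM357
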