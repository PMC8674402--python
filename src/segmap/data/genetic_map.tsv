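marker	chromosome	cM
RM5	1	105.6
RM237	1	110.0
RM246	1	123.1
RM297	1	126.0
RM212	1	136.0
RM315	1	139.8
PSM122	2	95.0
RM106	2	102.7
RM263	2	105.0
RM530	2	130.0
RM240	2	132.9
RM166	2	140.0
RM213	2	149.5
RM175	3	14.0
RM231	3	15.9
RM489	3	22.7
RM545	3	25.0
PSM428	3	28.0
PSM433	3	28.5
PSM430	3	29.3
PSM437	3	30.0
PSM429	3	30.1
PSM435	3	30.5
PSM431	3	35.0
PSM434	3	36.0
RM218	3	40.0
PSM436	3	42.0
PSM438	3	43.0
RM563	3	44.6
PSM127	3	108.6
RM426	3	112.0
RM168	3	122.0
RM186	3	125.0
PSM358	4	33.6
PSM196	4	40.0
PSM194	4	64.4
RM119	4	67.7
RM273	4	70.0
RM252	4	78.0
RM241	4	80.6
PSM384	5	99.9
RM178	5	105.0
RM480	5	113.9
RM31	5	115.0
PSM389	5	116.0
PSM387	5	116.5
RM334	5	118.0
PSM386	5	120.0
PSM388	5	121.0
PSM390	5	121.5
TEL5L	5	122.3
TEL6S	6	0.7
RM508	6	2.0
RM217	6	15.0
RM253	6	17.3
RM121	6	40.0
RM136	6	45.6
RM481	7	18.5
PSM143	7	28.5
PSM356	7	29.0
PSM354	7	30.0
PSM142	7	35.0
RM2	7	45.0
PSM355	7	55.8
PSM357	7	56.5
RM10	7	70.0
PSM353	7	80.4
PSM155	8	36.5
RM547	8	40.0
PSM393	8	43.0
PSM394	8	60.0
RM515	8	70.0
RM284	8	82.6
RM556	8	84.0
RM210	8	90.0
RM80	8	91.7
OSR7	8	93.0
RM447	8	96.4
RM105	9	48.0
RM434	9	52.0
RM410	9	62.0
RM257	9	65.1
PSM174	11	19.1
PSM175	11	25.0
PSM409	11	39.8
PSM412	11	45.0
RM536	11	50.0
PSM415	11	59.3
PSM414	11	68.6
RM21	11	81.9
PSM365	11	85.0
PSM417	11	95.0
PSM460	11	97.3
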