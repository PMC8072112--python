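sequence_id	mouse_id	is_allotransplant	parental_mouse_id	tissue	v_subgroup	v_call_imgt	v_call_vbase2	d_subgroup	d_call	j_call	shm_percent	mutation_status	colony_count	total_colonies	cdr3_aa	cdr3_length	pi_printed
r01	13	false		spleen	VH14	IGHV14-2*02	VHSM7.a2psi.88	D2	DSP2.9	JH4	1.1	UM	5	13	GRDDGYYYAMDY	12	3.93
r02	13	false		spleen	VH5	IGHV5-17*02	VH7183.a47.76	D3	DST4.3	JH4	2.1	M	3	13	AREGPRRDYYAMDY	14	6.16
r03	16	false		spleen	VH1	IGHV1-85*01	VHJ558.88.194	D1	DFL16.1	JH3	0.35	UM	6	10	ASYAFAY	7	5.57
r04	16	false		spleen	VH5	IGHV5-17*02	VH7183.a47.76	D2	DSP2.2	JH4	0.35	UM	3	10	ASRSTMIIMDY	11	5.88
r05	16	false		blood	VH5	IGHV5-17*02	VH7183.a47.76	D2	DSP2.2	JH4	0.35	UM	7	10	ASRSTMIIMDY	11	5.88
r06	16	false		blood	VH1	IGHV1-85*01	VHJ558.88.194	D1	DFL16.1	JH3	0.7	UM	3	10	ASYAFAY	7	5.57
r07	29	false		spleen	VH1	IGHV1-80*01	VHJ558.83.189	D2	DSP2.2	JH4	2.1	M	8	10	ASPSYDYPYYYAMDY	15	3.56
r08	40	false		spleen	VH5	IGHV5-17*02	VH7183.a47.76	D2	DSP2.6	JH4	0	UM	8	10	ATYYGYDRVYYYAMDY	16	4.21
r09	40	false		blood	VH5	IGHV5-17*02	VH7183.a47.76	D2	DSP2.6	JH4	0.35	UM	9	10	ATYYGYDRVYYYAMDY	16	4.21
r10	45	false		spleen	VH1	IGHV1-9*01	VHJ558.b9	D2	DSP2.2	JH3	0.7	UM	8	10	ARGDYDGEFAY	11	4.03
r11	50	false		spleen	VH1	IGHV1-74*04	V102	D2	DSP2.4	JH4	0.35	UM	10	10	ASGYDYAMDY	10	3.56
r12	51	false		spleen	VH1	IGHV1-9*01	VHJ558.b9	D4	DQ52	JH4	0.7	UM	10	10	ARGNWDFYYAMDY	13	4.21
r13	55	false		spleen	VH1	IGHV1-74*04	V102	D2	DSP2.4	JH4	0	UM	10	10	ASGYDYAMDY	10	3.56
r14	55	false		blood	VH5	IGHV5-17*02	VH7183.a47.76	D2	DSP2.9	JH4	0.35	UM	5	10	AVYVIYDGYYGAMDY	15	3.56
r15	55	false		blood	VH1	IGHV1-77*01	VHJ558.80.186	D1	DFL16.1e	JH2	1.4	UM	5	10	ARGGDY	6	5.88
r16	55 F1	true	55	node	VH1	IGHV1-77*01	VHJ558.80.186	D1	DFL16.1e	JH2	0.7	UM	9	10	ARGGDY	6	5.88
r17	65	false		spleen	VH5	IGHV5-17*02	VH7183.a47.76	D3	DST4.3	JH2	0	UM	2	9	ALGAGYFDY	9	3.8
r18	65	false		spleen	VH1	IGHV1-69*02	VH124	D2	DSP2.9	JH1	4.9	M	2	9	ARGNDGSYWYFDV	13	4.21
r19	65	false		spleen	VH3	IGHV3-5*02	VH36-60.a5.112	D3	DST4	JH4	1.0	UM	2	9	ARIRGGAMDY	10	8.79
r20	65	false		blood	VH14	IGHV14-2*02	VHSM7.a2psi.88	D2	DSP2.9	JH4	0.35	UM	3	10	GRDDGYYYAMDY	12	3.93
r21	65	false		blood	VH5	IGHV5-17*02	VH7183.a47.76	D3	DST4.3	JH2	0.7	UM	7	10	ALGAGYFDY	9	3.8
r22	72	false		spleen	VH14	IGHV14-2*02	VHSM7.a2psi.88	D2	DSP2.9	JH4	0.7	UM	4	14	GRDDGYYYAMDY	12	3.93
r23	72	false		spleen	VH1	IGHV1S130*01	Unknown	D2	DSP2.2	JH2	0.35	UM	4	14	ARVRNWDFEDY	11	4.56
r24	72 F1	true	72	spleen	VH1	IGHV1S130*01	Unknown	D2	DSP2.2	JH2	0	UM	7	10	ARVRNWDFEDY	11	4.56
r25	74	false		spleen	VH1	IGHV1S130*01	Unknown	D1	DFL16.1	JH2	0	UM	6	10	ASGPDFDY	8	3.56
r26	74	false		spleen	VH1	IGHV1-9*01	VHJ558.b9	D2	DSP2.4	JH4	0	UM	3	10	ARGGYYGYDGDYYAMDY	17	3.93
r27	74 F1	true	74	spleen	VH1	IGHV1-9*01	VHJ558.b9	D2	DSP2.4	JH4	0.7	UM	8	8	ARGGYYGYDGDYYAMDY	17	3.93
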