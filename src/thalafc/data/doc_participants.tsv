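id	gender	age	aetiology	months_post_injury	diagnosis	crs_r	task_response
P01	M	21	TBI	45	MCS+	11	positive
P02	M	57	TBI	14	MCS-	12	negative
P03	M	47	TBI	4	MCS+	10	negative
P04	M	36	TBI	34	UWS	8	negative
P05	M	17	Anoxic	46	UWS	11	negative
P06	F	38	Anoxic	9	MCS-	10	negative
P07	F	38	TBI	13	MCS+	11	positive
P08	M	29	TBI	68	MCS+	10	positive
P09	M	23	TBI	4	MCS+	7	positive
P10	F	70	Cerebral bleed	11	MCS+	9	negative
P11	F	30	Anoxic	6	MCS-	9	positive
P12	F	34	Anoxic	6	UWS	8	negative
P13	M	22	Anoxic	5	UWS	7	negative
P14	M	37	Anoxic	14	UWS	7	negative
P15	F	62	Anoxic	7	UWS	7	negative
P16	M	46	Anoxic	10	UWS	5	negative
P17	M	21	TBI	7	MCS+	11	negative
P18	M	67	TBI	14	MCS-	11	positive
P19	F	55	Hypoxic	Unknown	UWS	12	negative
P20	M	28	TBI	Unknown	MCS+	8	positive
P21	M	22	TBI	Unknown	MCS+	10	negative
P22	F	28	ADEM	Unknown	UWS	6	negative
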