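patient_id	diagnosis	age	smoking	icd10	pct_immune_infiltrate	blood_pct_loy	um_pct_loy	tumor_pct_loy
1	CRC	42	Yes	C20	10	0	0	0
2	CRC	48	No	C18.2	5	0	0	0
3	CRC	49	No	C18.3	10	0	0	0
4	CRC	59	Yes	C18.7	5	8	0	0
5	CRC	63	Yes	C18.7	1	11	7	6
6	CRC	71	Yes	C20	3	10	11	11
7	CRC	71	Yes	C18.0	10	13	0	11
8	CRC	72	Yes	C18.9	10	6	6	16
9	CRC	73	Yes	C18.2	3	10	0	0
10	CRC	74	Yes	C20	5	11	15	13
11	LM_CRC	42	Yes	C78.7	5	0	0	0
12	LM_CRC	43	No	C78.7	10	6	0	8
13	LM_CRC	62	Yes	C78.7	3	0	0	0
14	LM_CRC	67	Yes	C78.7	10	11	14	17
15	LM_CRC	67	Yes	C78.7	15	8	0	0
16	LM_CRC	70	Yes	C78.7	15	9	0	0
17	LM_CRC	71	No	C78.7	0	10	10	0
18	LM_CRC	73	No	C78.7	5	9	0	30
19	LM_CRC	73	No	C78.7	5	0	0	0
20	LM_CRC	78	Yes	C78.7	20	44	45	23
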