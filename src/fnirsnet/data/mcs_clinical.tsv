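id	group	mcs_subtype	gender	age	etiology	duration_months	auditory	visual	motor	oromotor	communication	arousal	crsr_total
P01	MCS	MCS-	F	49	Traumatic brain injury	7	1	1	5	1	0	2	10
P02	MCS	MCS-	F	79	Intracerebral infarction	1.5	1	3	5	2	0	2	13
P03	MCS	MCS-	M	31	Traumatic brain injury	12	2	3	2	2	0	2	11
P04	MCS	MCS+	M	70	Intracerebral infarction	1	3	1	5	3	1	2	15
P05	MCS	MCS+	M	53	Intracerebral hemorrhage	1	3	1	5	1	0	1	11
P06	MCS	MCS-	F	85	Traumatic brain injury	1.5	2	3	3	0	0	1	9
P07	MCS	MCS-	F	69	Intracerebral hemorrhage	1.5	1	3	2	1	0	1	8
P08	MCS	MCS-	M	70	Intracerebral infarction	1	2	3	2	1	0	1	8
P09	MCS	MCS-	M	53	Traumatic brain injury	11	2	3	5	1	0	1	12
P10	MCS	MCS-	M	86	Traumatic brain injury	3.5	0	0	3	0	0	1	4
P11	MCS	MCS-	F	82	Intracerebral hemorrhage	1	1	1	3	2	0	2	9
P12	MCS	MCS-	M	65	Intracerebral hemorrhage	1	0	0	3	0	0	1	4
P13	MCS	MCS-	F	54	Intracerebral hemorrhage	1	1	3	5	0	0	1	10
P14	MCS	MCS-	M	83	Intracerebral infarction	3	0	3	5	2	0	1	11
P15	MCS	MCS-	F	84	Intracerebral infarction	1.5	0	3	2	2	0	1	8
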