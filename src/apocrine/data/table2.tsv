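sample_id	cowden_disease	pten_germline_mutation	age_at_diagnosis	histologic_type	histologic_grade	apocrine_features	AR	ER	PR	ERBB2	GCDFP15	GGT1	PTEN
46	No	WT	60 y	IAC	2	Yes	2	0	0	0	2	2	2
96	No	WT	40 y	IDC	3	Yes	2	0	0	+++	2	2	2
113	Yes	c.209+5G > A	48 y	IAC	1	Yes	2	0	0	0	2	2	0
116	Yes	c.1007dupA p.Tyr336X	44 y	IDC	2	No	2	2	2	0	0	2	0
118	Yes	c.209+5G > A	35 y	IAC	2	Yes	2	0	0	0	2	2	0
S89	Yes	c.158_159insATAC p.val54TyrfsX10	44 y	IDC	2	No	2	2	2	0	0	0	0
S243	Yes	c.323T > C p.Leu108Pro	28 y	IDC	2	No	2	2	2	0	0	1	0
S295	yes	c.209+5G > A	44 y	IAC	2	Yes	2	0	0	0	2	2	0
S362	Yes	c.69dupA p.Asp24ArgfsX20	53 y	DCIS	low	No	2	2	2	0	0	1	0
S403	Yes	c.801+1delG	43 y	IDC	2	No	2	2	2	0	0	0	0
S574	Yes	c.491delA p.Lys164ArgfsX3	46 y	IDC	1	No	2	2	2	0	0	1	0
S681	Yes	c.830C > G p.Thr277Arg	27 y	IDC	3	Yes	2	2	1	+	1	1	0
S712	Yes	c.592delA p.Met198X	41 y	MPC	2	Yes	2	2	0	nd	0	1	0
S730	Yes	c.493G > A p.Gly165Arg	59 y	ILC	2	No	2	2	2	+	2	0	0
S732	Yes	c.510T > G p.Ser170Arg	46 y	IDC	2	Yes	2	2	2	0	1	1	1
S891	yes	c.209+5G > A	35 y	IAC	2	Yes	2	0	0	++	2	2	2
S912	Yes	c.632_633delGC p.Cys211X	34 y	IDC	2	No	2	2	2	0	1	1	0
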