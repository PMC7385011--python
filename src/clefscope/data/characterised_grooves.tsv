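seq_id	organism	A_o	V_o	r	h	l	A_c	V_c	dA	dV
Q5NAT0	Oryza sativa	905	616	8.49	2.72	106.62	597.64	616.00	307.36	0.00
Q8LJP6	Gossypium hirsutum	1272	705	10.06	2.22	126.40	776.11	705.00	495.89	0.00
Q93WY9	Nicotiana tabacum	778	537	7.87	2.76	98.85	525.46	537.00	252.54	0.00
Q9ZSP9	Solanum lycopersicum	1352	858	10.38	2.54	130.31	841.40	858.00	510.60	0.00
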