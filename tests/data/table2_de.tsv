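protein_id	gene	fold_change	p_value
Q13148	TADBP	4.07	0.0348
Q9UKM9	RALY	3.57	0.0209
P20073	ANXA7	3.29	0.0011
O00299	CLIC1	3.02	0.0212
P09525	ANXA4	2.98	0.0074
Q02878	RL6	2.87	0.0319
P26639	SYTC	2.61	0.0100
P50991	TCPD	2.39	0.0255
Q99729	ROAA	2.35	0.0248
O00410	IPO5	2.22	0.0010
P42704	LPPRC	2.06	0.0091
P14923	PLAK	2.05	0.0041
Q6FI13	H2A2A	0.48	0.0438
Q9NZL4	HPBP1	0.48	0.0067
P49368	TCPG	0.46	0.0336
P14618	KPYM	0.43	0.0258
P37837	TALDO	0.43	0.0089
P62987	UBA52	0.41	0.0272
P08238	HSP90AB1	0.40	0.0039
P14625	ENPL	0.38	0.0301
P29401	TKT	0.35	0.0004
P05783	K1C18	0.35	0.0149
P08727	K1C19	0.34	0.0327
P84103	SRSF3	0.33	0.0102
P16402	H13	0.32	0.0227
P04406	G3P	0.32	0.0088
P26641	EF1G	0.31	0.0123
O60218	AK1BA	0.29	0.0120
P07437	TBB5	0.27	0.0041
P62805	H4	0.26	0.0302
Q06830	PRDX1	0.26	0.0190
P07900	HSP90AA1	0.26	0.0069
P22626	ROA2	0.25	0.0281
P11142	HSPA8	0.25	0.0056
P08865	RSSA	0.25	0.0285
Q5VTE0	EF1A3	0.15	0.0061
P63261	ACTG	0.09	0.0030
P21359	NF1	0.07	0.0030
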