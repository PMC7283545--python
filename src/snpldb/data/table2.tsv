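locus	allele	population	category	count	printed_pct	note
PC-1	PC-1-1	WA	brown	1	100.0
PC-1	PC-1-1	WA	gray	0
PC-1	PC-1-1	LR	brown	107	63.7
PC-1	PC-1-1	LR	gray	61	36.3
PC-1	PC-1-1	RC	brown	70	41.4
PC-1	PC-1-1	RC	gray	99	58.6
PC-1	PC-1-2	WA	brown	0
PC-1	PC-1-2	WA	gray	0
PC-1	PC-1-2	LR	brown	11	23.4
PC-1	PC-1-2	LR	gray	36	76.6
PC-1	PC-1-2	RC	brown	7	3.2
PC-1	PC-1-2	RC	gray	212	96.8
PC-1	PC-1-3	WA	brown	107	100.0
PC-1	PC-1-3	WA	gray	0
PC-1	PC-1-3	LR	brown	66	80.5
PC-1	PC-1-3	LR	gray	16	19.5
PC-1	PC-1-3	RC	brown	4	80.0
PC-1	PC-1-3	RC	gray	1	20.0
PC-1	PC-1-4	WA	brown	32	100.0
PC-1	PC-1-4	WA	gray	0
PC-1	PC-1-4	LR	brown	37	64.9
PC-1	PC-1-4	LR	gray	20	35.1
PC-1	PC-1-4	RC	brown	36	87.8
PC-1	PC-1-4	RC	gray	5	12.2
PC-1	PC-1-5	WA	brown	29	100.0
PC-1	PC-1-5	WA	gray	0
PC-1	PC-1-5	LR	brown	23	63.9
PC-1	PC-1-5	LR	gray	13	36.1
PC-1	PC-1-5	RC	brown	4	44.4
PC-1	PC-1-5	RC	gray	5	55.6
PC-1	PC-1-6	WA	brown	13	100.0
PC-1	PC-1-6	WA	gray	0
PC-1	PC-1-6	LR	brown	6	100.0
PC-1	PC-1-6	LR	gray	0
PC-1	PC-1-6	RC	brown	1	33.3
PC-1	PC-1-6	RC	gray	2	66.7
Glyma06g21551	a1.CTATA	WA	brown	145	100.0
Glyma06g21551	a1.CTATA	WA	gray	0
Glyma06g21551	a1.CTATA	LR	brown	204	66.2
Glyma06g21551	a1.CTATA	LR	gray	104	33.8
Glyma06g21551	a1.CTATA	RC	brown	112	50.7
Glyma06g21551	a1.CTATA	RC	gray	109	49.3
Glyma06g21551	a2.TCAAC	WA	brown	12	100.0
Glyma06g21551	a2.TCAAC	WA	gray	0
Glyma06g21551	a2.TCAAC	LR	brown	17	32.7
Glyma06g21551	a2.TCAAC	LR	gray	35	67.3
Glyma06g21551	a2.TCAAC	RC	brown	7	3.2
Glyma06g21551	a2.TCAAC	RC	gray	211	96.8
Glyma06g21551	a3.CTTTA	WA	brown	21	100.0
Glyma06g21551	a3.CTTTA	WA	gray	0
Glyma06g21551	a3.CTTTA	LR	brown	26	83.9
Glyma06g21551	a3.CTTTA	LR	gray	5	16.1
Glyma06g21551	a3.CTTTA	RC	brown	2	100.0
Glyma06g21551	a3.CTTTA	RC	gray	0
Glyma06g21551	a4.CCAAC	WA	brown	2	100.0
Glyma06g21551	a4.CCAAC	WA	gray	0
Glyma06g21551	a4.CCAAC	LR	brown	2	100.0
Glyma06g21551	a4.CCAAC	LR	gray	0
Glyma06g21551	a4.CCAAC	RC	brown	0
Glyma06g21551	a4.CCAAC	RC	gray	2	100.0
Glyma06g21551	a5.CCATA	WA	brown	1	100.0
Glyma06g21551	a5.CCATA	WA	gray	0
Glyma06g21551	a5.CCATA	LR	brown	0
Glyma06g21551	a5.CCATA	LR	gray	1	100.0
Glyma06g21551	a5.CCATA	RC	brown	0
Glyma06g21551	a5.CCATA	RC	gray	0
Glyma06g21551	a6.TCAAA	WA	brown	1	100.0
Glyma06g21551	a6.TCAAA	WA	gray	0
Glyma06g21551	a6.TCAAA	LR	brown	0
Glyma06g21551	a6.TCAAA	LR	gray	0
Glyma06g21551	a6.TCAAA	RC	brown	0
Glyma06g21551	a6.TCAAA	RC	gray	1	100.0
Glyma06g21551	a7.TCATA	WA	brown	0
Glyma06g21551	a7.TCATA	WA	gray	0
Glyma06g21551	a7.TCATA	LR	brown	0
Glyma06g21551	a7.TCATA	LR	gray	0
Glyma06g21551	a7.TCATA	RC	brown	1	50.0
Glyma06g21551	a7.TCATA	RC	gray	1	50.0
Glyma06g21551	a8.CTAAC	WA	brown	0
Glyma06g21551	a8.CTAAC	WA	gray	0
Glyma06g21551	a8.CTAAC	LR	brown	1	100.0
Glyma06g21551	a8.CTAAC	LR	gray	0
Glyma06g21551	a8.CTAAC	RC	brown	0
Glyma06g21551	a8.CTAAC	RC	gray	0
Glyma06g21551	a9.TTAAC	WA	brown	0
Glyma06g21551	a9.TTAAC	WA	gray	0
Glyma06g21551	a9.TTAAC	LR	brown	0
Glyma06g21551	a9.TTAAC	LR	gray	1	100.0
Glyma06g21551	a9.TTAAC	RC	brown	0
Glyma06g21551	a9.TTAAC	RC	gray	0
FC-1	FC-1-1	WA	purple	11	91.7
FC-1	FC-1-1	WA	white	1	8.3
FC-1	FC-1-1	LR	purple	228	92.3
FC-1	FC-1-1	LR	white	19	7.7
FC-1	FC-1-1	RC	purple	205	95.3
FC-1	FC-1-1	RC	white	10	4.4	printed_typo:10/215=4.7
FC-1	FC-1-2	WA	purple	0
FC-1	FC-1-2	WA	white	5	100.0
FC-1	FC-1-2	LR	purple	13	10.3
FC-1	FC-1-2	LR	white	113	89.7
FC-1	FC-1-2	RC	purple	27	11.7
FC-1	FC-1-2	RC	white	203	88.3
FC-1	FC-1-3	WA	purple	63	100.0
FC-1	FC-1-3	WA	white	0
FC-1	FC-1-3	LR	purple	6	85.7
FC-1	FC-1-3	LR	white	1	14.3
FC-1	FC-1-3	RC	purple	1	100.0
FC-1	FC-1-3	RC	white	0
FC-1	FC-1-4	WA	purple	44	91.7
FC-1	FC-1-4	WA	white	4	8.3
FC-1	FC-1-4	LR	purple	13	100.0
FC-1	FC-1-4	LR	white	0
FC-1	FC-1-4	RC	purple	0
FC-1	FC-1-4	RC	white	0
FC-1	FC-1-5	WA	purple	54	100.0
FC-1	FC-1-5	WA	white	0
FC-1	FC-1-5	LR	purple	3	100.0
FC-1	FC-1-5	LR	white	0
FC-1	FC-1-5	RC	purple	0
FC-1	FC-1-5	RC	white	0
Glyma13g04210	b1.GG	WA	purple	151	93.8
Glyma13g04210	b1.GG	WA	white	10	6.2
Glyma13g04210	b1.GG	LR	purple	116	47.7
Glyma13g04210	b1.GG	LR	white	127	52.3
Glyma13g04210	b1.GG	RC	purple	140	39.9
Glyma13g04210	b1.GG	RC	white	211	60.1
Glyma13g04210	b2.AG	WA	purple	10	100.0
Glyma13g04210	b2.AG	WA	white	0
Glyma13g04210	b2.AG	LR	purple	146	96.1
Glyma13g04210	b2.AG	LR	white	6	3.9
Glyma13g04210	b2.AG	RC	purple	93	97.9
Glyma13g04210	b2.AG	RC	white	2	2.1
Glyma13g04210	b3.GA	WA	purple	11	100.0
Glyma13g04210	b3.GA	WA	white	0
Glyma13g04210	b3.GA	LR	purple	1	100.0
Glyma13g04210	b3.GA	LR	white	0
Glyma13g04210	b3.GA	RC	purple	0
Glyma13g04210	b3.GA	RC	white	0
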