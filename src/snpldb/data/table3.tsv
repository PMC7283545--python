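locus	allele	WA	WA_I	WA_II	WA_III	WA_IV	LR	LR_I	LR_II	LR_III	LR_IV	RC	RC_I	RC_II	RC_III	RC_IV
PC-1	PC-1-1	0.6				4.2	42.4	31.1	43.6	59.0	36.8	37.9	4.5	42.1	61.3	69.6
PC-1	PC-1-2						11.9	31.1	10.0	9.0	9.2	49.1	89.4	38.8	27.4	18.8
PC-1	PC-1-3	58.8	41.8	57.6	79.5	62.5	20.7	11.1	9.1	12.8	35.0	1.1		1.1	1.6	2.9
PC-1	PC-1-4	17.6	32.7	16.9	9.1		14.4	22.2	34.5	7.7	1.8	9.2	2.3	16.4	8.1	4.3
PC-1	PC-1-5	15.9	23.6	13.6	2.3	29.2	9.1	4.4	2.7	11.5	13.5	2.0	2.3	1.1	1.6	4.3
PC-1	PC-1-6	7.1	1.8	11.9	9.1	4.2	1.5				3.7	0.7	1.5	0.5
FC-1	FC-1-1	6.6		5.1	13.6	12.5	62.4	62.2	42.7	78.2	68.1	48.2	38.6	55.7	41.9	52.2
FC-1	FC-1-2	2.7	3.6	1.7	4.5		31.8	33.3	46.4	19.2	27.6	51.6	60.6	44.3	58.1	47.8
FC-1	FC-1-3	34.6	18.2	20.3	52.3	75.0	1.8		0.9	1.3	3.1	0.2	0.8
FC-1	FC-1-4	26.4	25.5	47.5	11.4	4.2	3.3	4.4	10.0
FC-1	FC-1-5	29.7	52.7	25.4	18.2	8.3	0.8			1.3	1.2
Glyma06g21551	a1.CTATA	79.7	90.9	72.9	77.3	75.0	77.8	64.4	83.6	85.9	73.6	49.6	9.1	60.1	71.0	79.7
Glyma06g21551	a2.TCAAC	6.6	1.8	10.2	9.1	4.2	13.1	31.1	9.1	9.0	12.9	48.9	90.9	38.3	25.8	17.4
Glyma06g21551	a3.CTTTA	11.5	5.5	15.3	13.6	12.5	7.8	4.4	4.5	3.8	12.9	0.4			1.6	1.4
Glyma06g21551	a4.CCAAC	1.1				8.3	0.5			1.3	0.6	0.4		0.5		1.4
Glyma06g21551	a5.CCATA	0.5	1.8				0.3		0.9
Glyma06g21551	a6.TCAAA	0.5		1.7								0.2			1.6
Glyma06g21551	a7.TCATA											0.4		1.1
Glyma06g21551	a8.CTAAC						0.3		0.9
Glyma06g21551	a9.TTAAC						0.3		0.9
Glyma13g04210	b1.GG	88.5	100.0	94.9	70.5	79.2	61.4	57.8	70.9	55.1	58.9	78.7	94.7	71.6	74.2	71.0
Glyma13g04210	b2.AG	5.5		3.4	9.1	16.7	38.4	42.2	29.1	44.9	40.5	21.3	5.3	28.4	25.8	29.0
Glyma13g04210	b3.GA	6.0		1.7	20.5	4.2	0.3				0.6
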