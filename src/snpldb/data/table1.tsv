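group	n	pc_brown	pc_gray	fc_purple	fc_white
WA	182	100.0		94.5	5.5
WA_I	55	100.0		96.4	3.6
WA_II	59	100.0		93.2	6.8
WA_III	44	100.0		90.9	9.1
WA_IV	24	100.0		100.0
LR	396	63.1	36.9	66.4	33.6
LR_I	45	51.1	48.9	73.3	26.7
LR_II	110	51.8	48.2	50.9	49.1
LR_III	78	66.7	33.3	75.6	24.4
LR_IV	163	72.4	27.6	70.6	29.4
RC	446	27.4	72.6	52.2	47.8
RC_I	132	7.6	92.4	44.7	55.3
RC_II	183	34.4	65.6	58.5	41.5
RC_III	62	30.6	69.4	46.8	53.2
RC_IV	69	43.5	56.5	55.1	44.9
CSGP	1024	54.1	45.9	65.2	34.8
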