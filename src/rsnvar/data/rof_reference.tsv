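patient	network	in_t1	out_t1	rof_t1	in_t2	out_t2	rof_t2	delta_rof
EMCS	auditory				85	87	-0.01	0.01
EMCS	DMN	81	13	0.19	78	76	0.01	0.18
EMCS	ECNL	46	27	0.12	57	70	-0.08	0.20
EMCS	ECNR				11	0	0.08	-0.08
EMCS	salience				30	108	-0.67	0.67
EMCS	sensorimotor	39	213	-1.71	2	27	-0.25	-1.46
EMCS	VL				35	179
EMCS	VM	125	37	0.32	37	22	0.05	0.27
EMCS	VO
MCS	auditory	41	26	0.06	36	9	0.10	-0.04
MCS	DMN	82	8	0.21	107	44	0.18	0.03
MCS	ECNL	20	142	-0.80	48	88	-0.26	-0.54
MCS	ECNR	30	49	-0.15	46	125	-0.60	0.45
MCS	salience	58	303	-2.11	46	228	-1.57	-0.54
MCS	sensorimotor	42	30	0.12	41	13	0.27	-0.15
MCS	VL	4	79	-0.56	10	75	-0.49	-0.07
MCS	VM	93	21	0.26	48	53	-0.02	0.28
MCS	VO	41	54	-0.07	93	57	0.20	-0.27
UWS	auditory				108	162	-0.20	0.20
UWS	DMN	53	123	-0.20				-0.20
UWS	ECNL	29	158	-0.84				-0.84
UWS	ECNR
UWS	salience	16	52	-0.31	37	235	-1.71	1.40
UWS	sensorimotor	36	69	-0.32				-0.32
UWS	VL				42	108	-0.50	0.50
UWS	VM
UWS	VO				6	14	-0.04	0.04
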