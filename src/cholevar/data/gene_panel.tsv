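symbol	chromosome_band	product	omim_id	exons	length_kb	associated_disease
ABCB4	7q21.1		171060	27	81	PFIC-3
ABCB11	2q31.1	BSEP	603201	28	115	PFIC-2
ATP8B1	18q21.31	FIC1	602397	28	157	PFIC-1
TJP2	9q21.11		607709	25	153	PFIC-4
NR1H4	12q23.1	FXR	603826	11	90	PFIC-5
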