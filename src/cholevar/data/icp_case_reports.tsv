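volunteer_id	gene	variant	zygosity	type	highest_tsba
3	ABCB4	G1254S/G1261S	het	Non-synonymous	80.1
3	ABCB11	N591S	het	Non-synonymous	80.1
4	ABCB4	P1050S	het	Non-synonymous	53
5	TJP2	Q105K	hom	Non-synonymous	15
6	ABCB11	N591S	het	Non-synonymous	17
13	TJP2	Q105K	het	Non-synonymous	25
15	ATP8B1	R384H	het	Non-synonymous	31.6
15	TJP2	Q105K	hom	Non-synonymous	31.6
18	ABCB11	N591S	het	Non-synonymous	115
18	TJP2	R21H	het	Non-synonymous	115
20	ABCB11	N591S	het	Non-synonymous	18
20	NR1H4	M173T	het	Non-synonymous	18
21	ABCB11	M677V	het	Non-synonymous	14
21	NR1H4	N358H	het	Non-synonymous	14
22	ABCB11	N591S	het	Non-synonymous	14
25	ABCB4	S99x	het	Frameshift	55
26	ABCB11	V284A	het	Non-synonymous	35
26	ABCB4	N510S	het	Non-synonymous	35
31	ABCB4	T175A	het	Non-synonymous	32
32	ABCB11	D1284N	het	Non-synonymous	
32	ABCB11	N591S	het	Non-synonymous	
38	ABCB11	N591S	het	Non-synonymous	45.2
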