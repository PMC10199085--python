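gene	transcript	protein_change	cdna_change	dbsnp	consequence	af_gnomad	af_cohort	polyphen	sift	cadd	revel	metalr	metasvm	mcap	literature_known	clinvar	acmg_codes	phenotype_groups	zygosity	het_n	hom_n	verdict
ABCB4	ENSP00000496956.1:p.Gly1254Ser	G1254S		rs781315185		0.00003656	0.00028843								true		PM1,PM2,PP2,PP3	ICP	het			LP
ABCB4	ENSP00000497931.1:p.Asp1284Asn	P1050S					0.00019146								false		PM1,PM2,PP2,PP3	ICP	het			LP
ABCB4	ENSP00000496956.1:p.Ala833Thr	A833T					0.00009638								false		PM1,PM2,PP2,PP3	ICP	het			LP
ABCB4	ENSP00000496956.1:p.Asn510Ser	N510S		rs375315619		0.00019110	0.00057394								true	LP	PM1,PM2,PP2,PP3,PP5	ICP	het			LP
ABCB4	ENSP00000496956.1:p.Thr175Ala	T175A		rs58238559		0.01155000	0.01315030								true	Benign/likely benign	PM1,PP2,PP3,BS1,BS2,BP6	ICP	both	126	6	LB
ABCB4	ENSP00000496956.1:p.Arg1137Gln	R1137Q		rs780738927		0.00003250	0.00028846								false		PM1,PM2,PP2,PP3	gallstone	het			LP
ABCB4	ENSP00000496956.1:p.Gly826Arg	G826R					0.00028681								false		PM1,PM2,PP2,PP3	gallstone	het			LP
ABCB4	ENSP00000496956.1:p.Arg788Leu	R788L		rs8187801		0.00000813	0.00009579								true	Benign	PM1,PM2,PP2,PP3	gallstone	het			LP
ABCB4	ENSP00000496956.1:p.Asp686Asn	D686N		rs78653500			0.00009586								false		PM2,PP2,BP4	gallstone	het			VUS
ABCB4	ENSP00000496956.1:p.Met676Ile	M676I		rs376702091		0.00002033	0.00038278								false		PM2,PP2,BP4	gallstone	het			VUS
ABCB4	ENSP00000496956.1:p.Thr651Asn	T651N		rs45476795		0.0005776	0.0006719								true	conflicting	PM2,PP2,BP4,BP6	gallstone	het			LB
ABCB4	ENSP00000496956.1:p.Lys391Glu	K391E		rs781347049		0.00002440	0.00009582								false		PM2,PP2,BP4,BP6	gallstone	het			LB
ABCB4	ENSP00000496956.1:p.Gln668His	Q668H					0.00009586								false		PM2,PP2,BP4	cholangiocarcinoma	het			LB
ABCB11	ENSP00000497931.1:p.Asp1284Asn	D1284N		rs766784155		0.00001228	0.00028780								false		PM1,PM2,PP2,PP3	ICP	het			LP
ABCB11	ENSP00000497931.1:p.Arg1050His	R1050H		rs72549398		0.00000421	0.00019135								false		PM2,PP2,BP4	ICP	het			VUS
ABCB11	ENSP00000497931.1:p.Met677Val	M677V		rs11568364		0.02364000	0.01005750								true	Benign	PP2,BA1,BS3,BP6,BP4	ICP	both	99	3	Benign
ABCB11	ENSP00000497931.1:p.Asn591Ser	N591S		rs11568367		0.01436000	0.12647200								true	Benign	PM1,PP2,BA1,BP6	ICP	both	760	99	Benign
ABCB11	ENSP00000497931.1:p.Val284Ala	V284A		rs200739891		0.00026040	0.00009558								true	Conflicting	PM1,PM2,PM5,PP2,PP3,BP6	ICP	het			LP
ABCB11	ENSP00000497931.1:p.Ala1260Pro	A1260P		rs772097949		0.00001641	0.00028153								true	VUS	PM1,PM2,PP2,PP3	gallstone	het			LP
ABCB11	ENSP00000497931.1:p.Gln976Arg	Q976R		rs199940188		0.00054840	0.00066883								true	Conflicting	PM1,PM2,PP2,BP4	gallstone	het			VUS
ABCB11	ENSP00000497931.1:p.Ala926Ser	A926S					0.00040667								false		PM1,PM2,PM5,PP2,PP3	gallstone	het			LP
ABCB11	ENSP00000497931.1:p.Ala679Val	A679V		rs200912109		0.00045560	0.00143761								true	Conflicting	PM2,PP2,BP4	gallstone	het			VUS
ABCB11	ENSP00000497931.1:p.Asn539Asp	N539D					0.00022604								false		PM1,PM2,PP2,BP4	gallstone	het			VUS
ABCB11	ENSP00000497931.1:p.Arg487Cys	R487C		rs770693935		0.00002043	0.00009549								true		PM1,PM2,PP2,PP3	gallstone	het			LP
ABCB11	ENSP00000497931.1:p.Ala311Thr	A311T		rs200509511		0.00004073	0.00028969								false		PM1,PM2,PP2,PP3	gallstone	het			LP
ABCB11	ENSP00000497931.1:p.Val95Ile	V95I		rs201735739		0.00009766	0.00028708								false		PM1,PM2,PP2,BP4	gallstone	het			Benign
ABCB11	ENSP00000497931.1:p.Asp94Asn	D94N		rs760920706		0.00010170	0.00095621								true	Conflicting	PM1,PM2,PP2	gallstone	het			LP
ABCB11	ENSP00000497931.1:p.Lys12Arg	K12R					0.00010378								false		PM1,PM2,PP2,PP3	gallstone	het			LP
ATP8B1	ENSP00000497896.1:p.Arg384His	R384H		rs2271260		0.00026400	0.00048040								true		PM2,PP2,BP6	ICP;gallstone	het			VUS
ATP8B1	ENSP00000497896.1:p.Val1161Ala	V1161A		rs1255793857		0.00000406	0.00009549								false		PM2,PP2	gallstone	het			VUS
ATP8B1	ENSP00000497896.1:p.Thr1092Ile	T1092I		rs780425796		0.00001220	0.00030581								false		PM2,PP2,PP3	gallstone	het			VUS
ATP8B1	ENSP00000497896.1:p.Met674Thr	M674T		rs35470719		0.00456300	0.00632063								true	Benign/Likely benign	PP2,BA1,BP4,BP6	gallstone	both	67	2	Benign
ATP8B1	ENSP00000497896.1:p.Ile577Val	I577V		rs3745078		0.00467800	0.00628992								true	Benign	PP2,BA1,BP6	gallstone	both	61	2	Benign
ATP8B1	ENSP00000497896.1:p.His78Gln	H78Q		rs3745079		0.00421800	0.00495751								true	Benign	PP2,BP4,BP6,BS1,BS2	gallstone	both	47	1	Benign
ATP8B1	ENSP00000497896.1:p.Asp14Tyr	D14Y					0.00009560								false		PM1,PM2,PP2,BP4	gallstone	het			VUS
ATP8B1	ENSP00000497896.1:p.Ile513Thr	I513T		rs772028343		0.00008531	0.00066973								false		PM2,PP2	cirrhosis	het			VUS
ATP8B1	ENSP00000497896.1:p.Asp70Asn	D70N		rs34719006		0.00313900	0.00302678								true	Conflicting	PM2,PP2,PP3	cirrhosis;neoplasm	both	24	1	VUS
NR1H4	ENSP00000496908.1:p.Asn358His	N358H		rs149287629		0.00041020	0.00038307								true	VUS	PM2	ICP	het			VUS
NR1H4	ENSP00000496908.1:p.Met173Thr	M173T		rs61755050		0.00374800	0.00267482								true	likely benign	PM1,PP3,BS1,BS2,BP6	ICP	het			LB
TJP2	ENSP00000497787.1:p.Thr377Ala	T377A		rs766748789		0.00000406	0.00047765								false		PM2,BP4	ICP	het			VUS
TJP2	ENSP00000496791.1:p.Gln105Lys	Q105K		rs41305539		0.05150000	0.12031400								true	benign	BA1,BP4,BP6	ICP	both	711	76	Benign
TJP2	ENSP00000497861.1:p.Arg21His	R21H		rs4493966		0.07416000	0.04555170								true	benign	BA1,BP4,BP6	ICP	both	443	16	Benign
TJP2	ENSP00000496791.1:p.Gln8Arg	Q8R					0.00009553								false		PM2,PP3	gallstone	het			VUS
TJP2	ENSP00000496791.1:p.Thr68Asn	T68N					0.00019150								false		PM1,PM2	gallstone	het			VUS
TJP2	ENSP00000496791.1:p.Pro152Leu	P152L		rs754300892		0.00007876	0.00046685								false		BP4	gallstone	het			VUS
TJP2	ENSP00000497787.1:p.Arg178Cys	R178C		rs199761505		0.00043060	0.00223305								false		PP3	gallstone	het			VUS
TJP2	ENSP00000497787.1:p.Arg255His	R255H		rs532438219		0.00012990	0.00066947								false			gallstone	het			VUS
TJP2	ENSP00000497787.1:p.Arg461Pro	R461P		rs748523814		0.00009746	0.00078125								false		PP3	gallstone	het			VUS
TJP2	ENSP00000496791.1:p.Thr902Met	T902M		rs774198938		0.00010970	0.00010449								false		PP3	gallstone	het			VUS
TJP2	ENSP00000496791.1:p.Arg1070Lys	R1070K					0.00009564								true	VUS	PM2,BP4	gallstone	het			VUS
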