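gene	transcript	protein_change	cdna_change	dbsnp	consequence	af_gnomad	af_cohort	polyphen	sift	cadd	revel	metalr	metasvm	mcap	literature_known	clinvar	acmg_codes	phenotype_groups	zygosity	het_n	hom_n	verdict
ABCB4	ENSP00000395716.1:p.Ser99LeufsTer11	S99x			Frameshift	0.00039970	0.00336538								false		PVS1,PM2,PP3	ICP	het			P
ABCB4	ENSP00000392983.1:p.Leu759TyrfsTer38	F758x			Frameshift		0.00009610								false		PVS1,PM2		het			LP
ABCB4	ENSP00000392983.1:p.Lys30GlyfsTer7	Lys30Glyfster7			Frameshift	0.00000408	0.00020243								false		PVS1,PM2		het			LP
ABCB4	ENSP00000392983.1:p.Arg595Ter	R595*			Stop-gained	0.00001627	0.00009593								true	Pathogenic	PVS1,PM2,PP3,PP5		het			P
ABCB11	ENSP00000497931.1:p.Ala1044LeufsTer53	A1044x			Frameshift		0.00009562								false		PVS1,PM2,PP3		het			P
ABCB11	ENST00000263817.7:c.2611-2A > T		c.2611-2A>T		Splice-acceptor-variant	0.00000407	0.00057870								false		PVS1,PM2,PP3		het			P
ABCB11	ENSP00000497931.1:p.Trp239Ter	W239x			Stop-gained		0.00009566								false		PVS1,PM2,PP3		het			P
ATP8B1	ENSP00000283684.4:p.Gln1179GlufsTer56	Q1178-1179IX			Frameshift_variant & splice_region_variant		0.00193798								false				het			
ATP8B1	ENSP00000283684.4:p.Pro792HisfsTer8	F791X			frameshift_variant		0.00019069								false		PVS1,PM2,PP3		het			P
ATP8B1	ENST00000283684.9:c.182-4_183del	?-61	c.182-4_183del		Splice_acceptor_variant & coding_sequence_variant & intron_variant		0.00048956								false				het			
ATP8B1	ENSP00000283684.4:p.Glu20Ter	E20*			Stop_gained		0.00009566								false		PVS1,PM2,PP3	gallstone	het			P
NR1H4	ENSP00000446760.1:p.Lys4Ter	K4*			Stop_gained		0.00014188								false		PVS1,PM2,PP3		het			P
TJP2	ENSP00000438262.1:p.Glu44Ter	E44*			Stop_gained		0.00009604								false		PVS1,PM2		het			LP
TJP2	ENSP00000345893.4:p.Gly5ArgfsTer26	M1MPVX			Frameshift_variant & start_lost	0.00001343	0.00029768								false		PVS1,PM2,PP3		het			P
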