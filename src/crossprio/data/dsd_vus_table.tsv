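# Variants of unknown significance in candidate genes from a 32-patient 46,XY DSD exome cohort.
# One row per (patient, variant); MAF is the gnomAD minor allele frequency on a percent scale.
gene	patient_id	zygosity	hgvs_c	hgvs_p	maf_percent
TOX2	RDSD021	Het	c.319G>A	p.Gly107Ser	0
TOX2	CDSD036	Cmpd Het	c.448A>G	p.Met150Val	0
TOX2	CDSD036	Cmpd Het	c.1201C>G	p.Pro401Ala	0
TOX2	CDSD036	Cmpd Het	c.1122_1124dupGCC	p.Pro376dup	0
DUSP15	RDSD020	Het	c.563G>C	p.Arg188Pro	0.002
NKD2	RDSD003	Het	c.1151G>A	p.Arg384Gln	0.001
CNGA1	CDSD030	Het	c.1478G>A	p.Arg493Gln	0.09
CNGA1	RDSD022	Het	c.398G>T	p.Gly133Val	0.03
PTK2B	RDSD011	Het	c.1799G>A	p.Arg600Gln	0.0008
ESPN	RDSD044	Het	c.2230G>A	p.Asp744Asn	0.02
SMOC2	CDSD030	Het	c.1276G>A	p.Val426Met	0.3
ADAMTS16	RDSD013	Het	c.2200G>A	p.Val734Ile	0.8
ADAMTS16	RDSD002	Het	c.298C>T	p.Arg100Trp	0.1
ADAMTS16	RDSD022	Het	c.1405T>G	p.Phe469Val	0.02
FBLN2	CDSD030	Het	c.1486G>A	p.Ala496Thr	0.033
FBLN2	CDSD029	Het	c.3605C>G	p.Ala1202Gly	0.004
NIPAL1	RDSD003	Het	c.1207A>G	p.Thr403Ala	0.1
NIPAL1	CDSD031	Het	c.31G>A	p.Glu11Lys	0
CYP26B1	CDSD032	Het	c.805C>G	p.Leu269Val	0.008
SPRY4	CDSD039	Het	c.446C>G	p.Pro149Arg	0.0004
MYBL1	RDSD004	Het	c.754T>A	p.Phe252Ile	0.05
MYBL1	CDSD029	Het	c.1832G>C	p.Ser611Thr	0.0008
MYBL1	RDSD049	Het	c.936T>A	p.Asn312Lys	0.03
ETV4	RDSD006	Het	c.523C>A	p.His175Asn	0.1
LGR5	RDSD007	Het	c.1834G>A	p.Val612Met	0.004
LGR5	RDSD020	Het	c.2341C>G	p.Pro781Ala	0.8
LGR5	RDSD048	Het	c.2537C>A	p.Thr846Asn	0
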