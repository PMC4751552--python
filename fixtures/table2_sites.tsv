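tissue	chrom	pos	dna_allele	rna_allele	canonical	replicates	gene_names	localization
WAT	1	79605543	T	C	yes	3	PLA1A,POPDC2	Downstream gene
WAT	1	90873162	T	C	yes	3	MPZL1,BRP44	Downstream gene
WAT	1	103511385	T	C	yes	6	GRIK1	Intron
WAT	1	167109833	A	G	yes	3	COG3	Exon (missense)
WAT	1	169769193	A	G	yes	3	THSD1	Downstream gene
WAT	1	187056174	A	G	yes	3	NOX4	Downstream gene
WAT	1	187056183	A	G	yes	3	NOX4	Downstream gene
WAT	1	187057565	A	G	yes	3		Intergenic
WAT	2	86000926	T	C	yes	5	NDUFS6	Upstream
WAT	4	17996546	T	C	yes	4		Intergenic
WAT	5	22958596	T	C	yes	3	DGKZ	Intron
WAT	11	10634278	A	G	yes	5	CES1	Exon (missense)
WAT	11	19169664	A	C	no	3	DHODH,IST1	Upstream, Intron
WAT	12	8909946	A	G	yes	6	FLNB	Exon (missense)
WAT	12	8910897	A	G	yes	5	FLNB	Intron
WAT	17	4705	T	C	yes	3		Intron
WAT	17	94999	C	T	yes	6		Intergenic
WAT	18	28378	T	C	yes	6	ZNF302	Upstream
WAT	19	4812610	C	T	yes	4	CCLI8	Intron
Liver	1	79608260	T	C	yes	7	POPDC2,PLA1A	Downstream gene
Liver	1	90873162	T	C	yes	3	MPZL1,BRP44	Downstream gene
Liver	1	90873188	T	C	yes	4	MPZL1,BRP44	Downstream gene
Liver	1	167109833	A	G	yes	5	COG3	Exon (missense)
Liver	1	193343226	A	G	yes	6	MADPRT,ART7B	Upstream
Liver	2	86000926	T	C	yes	5	NDUFS6	Upstream
Liver	6	13236424	A	G	yes	3	KCNMA1	Exon (missense)
Liver	7	7564791	A	G	yes	5	MYO1B	Intron
Liver	8	25588113	T	C	yes	3		Exon (synonymous)
Liver	28	518606	A	C	no	3	HNRNPM	Missense
Liver	LGE64	615592	T	C	yes	4		Intron
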