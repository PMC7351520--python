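feature_id	gene_name	biotype	log2fc	fdr
AC004241.1	AC004241.1	lncRNA_novel	4.4723	0.05
AC004477.3	AC004477.3	lncRNA_novel	1.9133	0.05
AC006504.5	AC006504.5	lncRNA_novel	2.3449	0.05
AC008105.3	AC008105.3	lncRNA_novel	4.2391	0.05
AC009022.1	AC009022.1	lncRNA_novel	8.7676	0.05
AC010457.1	AC010457.1	lncRNA_novel	2.2489	0.05
AC016582.2	AC016582.2	lncRNA_novel	5.1047	0.05
AC021092.1	AC021092.1	lncRNA_novel	1.131	0.05
AC061992.1	AC061992.1	lncRNA_novel	-4.2812	0.05
AC068473.5	AC068473.5	lncRNA_novel	1.4616	0.05
AC068888.1	AC068888.1	lncRNA_novel	7.4252	0.05
AC092279.1	AC092279.1	lncRNA_novel	-5.9393	0.05
AC109460.3	AC109460.3	lncRNA_novel	6.9064	0.05
AC141930.1	AC141930.1	lncRNA_novel	3.2551	0.05
AL031429.1	AL031429.1	lncRNA_novel	3.3503	0.05
AL139260.1	AL139260.1	lncRNA_novel	7.4131	0.05
AL356056.1	AL356056.1	lncRNA_novel	5.4758	0.05
AL591848.3	AL591848.3	lncRNA_novel	1.5321	0.05
AP000317.2	AP000317.2	lncRNA_novel	-11.2572	0.05
APTR	APTR	lncRNA_known	3.3044	0.05
CFLAR-AS1	CFLAR-AS1	lncRNA_known	-6.3218	0.05
FAM198B-AS1	FAM198B-AS1	lncRNA_known	3.8088	0.05
FAM27E3	FAM27E3	lncRNA_known	3.9401	0.05
H19	H19	lncRNA_known	-22.6445	0.05
HIF1A-AS1	HIF1A-AS1	lncRNA_known	3.7185	0.05
LINC00926	LINC00926	lncRNA_known	4.5816	0.05
LINC00968	LINC00968	lncRNA_known	8.9218	0.05
LINC01106.t1	LINC01106	lncRNA_known	19.5614	0.05
LINC01106.t2	LINC01106	lncRNA_known	20.9418	0.05
LINC01140.t1	LINC01140	lncRNA_known	-3.7389	0.05
LINC01140.t2	LINC01140	lncRNA_known	-3.597	0.05
LINC01348	LINC01348	lncRNA_known	8.9118	0.05
MINCR	MINCR	lncRNA_known	3.7292	0.05
MIR100HG.t1	MIR100HG	lncRNA_known	-8.2382	0.05
MIR4435-2HG.t1	MIR4435-2HG	lncRNA_known	9.2841	0.05
MSC-AS1	MSC-AS1	lncRNA_known	-23.2039	0.05
NUTM2A-AS1.t1	NUTM2A-AS1	lncRNA_known	-6.5505	0.05
NUTM2A-AS1.t2	NUTM2A-AS1	lncRNA_known	9.2961	0.05
PGM5P3-AS1	PGM5P3-AS1	lncRNA_known	-7.6345	0.05
RASSF8-AS1.t1	RASSF8-AS1	lncRNA_known	19.9364	0.05
SCAT8	SCAT8	lncRNA_known	-3.9716	0.05
SLC14A2-AS1	SLC14A2-AS1	lncRNA_known	6.434	0.05
SNHG16	SNHG16	lncRNA_known	4.6908	0.05
STAG3L5P-PVRIG2P-PILRB	STAG3L5P-PVRIG2P-PILRB	lncRNA_known	20.8685	0.05
TPTEP1	TPTEP1	lncRNA_known	7.4005	0.05
TPT1-AS1	TPT1-AS1	lncRNA_known	-6.8438	0.05
USP9Y	USP9Y	lncRNA_known	8.9477	0.05
ZNF883	ZNF883	lncRNA_known	6.9421	0.05
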