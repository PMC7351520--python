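feature_id	gene_name	biotype	log2fc	fdr
AC007098.1	AC007098.1	lncRNA_novel	6.669	0.05
AC009022.1	AC009022.1	lncRNA_novel	8.7671	0.05
AC010457.1	AC010457.1	lncRNA_novel	2.8844	0.05
AC016582.2	AC016582.2	lncRNA_novel	5.2659	0.05
AC022007.1	AC022007.1	lncRNA_novel	9.3198	0.05
AC023421.1	AC023421.1	lncRNA_novel	5.48	0.05
AC068888.1	AC068888.1	lncRNA_novel	8.363	0.05
AC084757.3	AC084757.3	lncRNA_novel	-2.9022	0.05
AC099518.3	AC099518.3	lncRNA_novel	-7.8032	0.05
AC109460.3	AC109460.3	lncRNA_novel	6.2148	0.05
AC114956.3	AC114956.3	lncRNA_novel	2.6267	0.05
AC144548.1	AC144548.1	lncRNA_novel	-1.032	0.05
AL031429.1	AL031429.1	lncRNA_novel	4.1653	0.05
AL078612.1	AL078612.1	lncRNA_novel	2.7046	0.05
AL138828.1	AL138828.1	lncRNA_novel	2.3053	0.05
AL138963.4	AL138963.4	lncRNA_novel	2.2073	0.05
AL139260.1	AL139260.1	lncRNA_novel	7.3094	0.05
AC016582.1	AC016582.1	lncRNA_novel	5.2659	0.05
AL161772.1	AL161772.1	lncRNA_novel	1.9376	0.05
AL355607.2	AL355607.2	lncRNA_novel	1.9507	0.05
AL356056.1	AL356056.1	lncRNA_novel	6.9848	0.05
AP000317.2	AP000317.2	lncRNA_novel	-11.2572	0.05
AP000790.1	AP000790.1	lncRNA_novel	6.1063	0.05
FP236383.3	FP236383.3	lncRNA_novel	8.4412	0.05
AGAP11	AGAP11	lncRNA_known	1.8547	0.05
APTR	APTR	lncRNA_known	2.8546	0.05
ARHGEF7-AS2	ARHGEF7-AS2	lncRNA_known	4.6621	0.05
BCYRN1	BCYRN1	lncRNA_known	3.1417	0.05
FAM198B-AS1	FAM198B-AS1	lncRNA_known	4.6582	0.05
FAM27E3	FAM27E3	lncRNA_known	3.9401	0.05
FOXP4-AS1	FOXP4-AS1	lncRNA_known	6.368	0.05
LINC00486	LINC00486	lncRNA_known	6.96	0.05
LINC00968	LINC00968	lncRNA_known	8.4248	0.05
LINC01106.t1	LINC01106	lncRNA_known	22.0251	0.05
LINC01106.t2	LINC01106	lncRNA_known	19.8254	0.05
LINC01184	LINC01184	lncRNA_known	-8.4369	0.05
LINC01239	LINC01239	lncRNA_known	-2.1368	0.05
LINC01291	LINC01291	lncRNA_known	-21.0782	0.05
LINC01348	LINC01348	lncRNA_known	7.3795	0.05
LINC01619	LINC01619	lncRNA_known	-8.8258	0.05
MAP4K3-DT	MAP4K3-DT	lncRNA_known	5.1283	0.05
MINCR	MINCR	lncRNA_known	4.192	0.05
MIR100HG.t1	MIR100HG	lncRNA_known	-21.7228	0.05
MIR100HG.t2	MIR100HG	lncRNA_known	-9.8115	0.05
MIR4435-2HG.t1	MIR4435-2HG	lncRNA_known	9.1337	0.05
MIR4435-2HG.t2	MIR4435-2HG	lncRNA_known	-9.4517	0.05
MIR4435-2HG.t3	MIR4435-2HG	lncRNA_known	-8.6134	0.05
OLMALINC	OLMALINC	lncRNA_known	-2.9871	0.05
SLC14A2-AS1	SLC14A2-AS1	lncRNA_known	9.1498	0.05
SNHG16	SNHG16	lncRNA_known	5.3027	0.05
SNHG29	SNHG29	lncRNA_known	-7.6114	0.05
STAG3L5P-PVRIG2P-PILRB	STAG3L5P-PVRIG2P-PILRB	lncRNA_known	20.8685	0.05
TMEM161B-AS1	TMEM161B-AS1	lncRNA_known	4.6379	0.05
TPTEP1	TPTEP1	lncRNA_known	7.4005	0.05
UBA6-AS1	UBA6-AS1	lncRNA_known	-8.0421	0.05
XIST	XIST	lncRNA_known	-25.1297	0.05
ZNF295-AS1	ZNF295-AS1	lncRNA_known	1.8551	0.05
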