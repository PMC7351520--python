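feature_id	gene_name	biotype	log2fc	fdr
AC008105.3	AC008105.3	lncRNA_novel	4.4356	0.05
AC021092.1	AC021092.1	lncRNA_novel	1.0531	0.05
AC022007.1	AC022007.1	lncRNA_novel	9.0501	0.05
AC109460.3	AC109460.3	lncRNA_novel	6.8707	0.05
AC139256.1	AC139256.1	lncRNA_novel	2.828	0.05
AL031429.1	AL031429.1	lncRNA_novel	3.0813	0.05
AL139260.1	AL139260.1	lncRNA_novel	6.2839	0.05
APTR	APTR	lncRNA_known	4.0329	0.05
DLGAP1-AS1	DLGAP1-AS1	lncRNA_known	1.4003	0.05
FAM198B-AS1	FAM198B-AS1	lncRNA_known	4.4575	0.05
HIF1A-AS1	HIF1A-AS1	lncRNA_known	2.9894	0.05
HOXB-AS3	HOXB-AS3	lncRNA_known	-7.1867	0.05
LINC00926	LINC00926	lncRNA_known	4.6596	0.05
LINC00968	LINC00968	lncRNA_known	8.3768	0.05
LINC01106.t1	LINC01106	lncRNA_known	19.7102	0.05
LINC01106.t2	LINC01106	lncRNA_known	20.612	0.05
LINC01348	LINC01348	lncRNA_known	8.2512	0.05
LNCOG	LNCOG	lncRNA_known	1.8031	0.05
LUCAT1	LUCAT1	lncRNA_known	9.5244	0.05
MALINC1	MALINC1	lncRNA_known	2.0735	0.05
MIR3142HG	MIR3142HG	lncRNA_known	3.1109	0.05
MIR4435-2HG.t1	MIR4435-2HG	lncRNA_known	9.7786	0.05
RASSF8-AS1.t1	RASSF8-AS1	lncRNA_known	22.0934	0.05
RASSF8-AS1.t2	RASSF8-AS1	lncRNA_known	-9.9462	0.05
SNHG16	SNHG16	lncRNA_known	4.6101	0.05
SNORD3C	SNORD3C	lncRNA_known	6.8661	0.05
TPRG1-AS1	TPRG1-AS1	lncRNA_known	-1.6872	0.05
ZFAS1	ZFAS1	lncRNA_known	-5.2589	0.05
ZNF883	ZNF883	lncRNA_known	7.4847	0.05
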