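feature_id	gene_name	biotype	log2fc	fdr
let-7c-5p	let-7c-5p	miRNA	0.8158	0.06
let-7e-3p	let-7e-3p	miRNA	-0.5273	0.06
miR-1247-5p	miR-1247-5p	miRNA	-1.2365	0.06
miR-125a-5p	miR-125a-5p	miRNA	-0.6889	0.06
miR-1287-5p	miR-1287-5p	miRNA	1.1111	0.06
miR-1296-5p	miR-1296-5p	miRNA	-0.9913	0.06
miR-144-5p	miR-144-5p	miRNA	1.3677	0.06
miR-152-3p	miR-152-3p	miRNA	0.6263	0.06
miR-181c-3p	miR-181c-3p	miRNA	1.1703	0.06
miR-181c-5p	miR-181c-5p	miRNA	1.219	0.06
miR-181d-5p	miR-181d-5p	miRNA	1.2244	0.06
miR-185-5p	miR-185-5p	miRNA	0.784	0.06
miR-193b-3p	miR-193b-3p	miRNA	-0.741	0.06
miR-24-3p	miR-24-3p	miRNA	0.6745	0.06
miR-345-5p	miR-345-5p	miRNA	-0.8146	0.06
miR-34a-5p	miR-34a-5p	miRNA	0.9133	0.06
miR-361-3p	miR-361-3p	miRNA	-0.4835	0.06
miR-421	miR-421	miRNA	0.8311	0.06
miR-451a	miR-451a	miRNA	1.2621	0.06
miR-483-5p	miR-483-5p	miRNA	1.0648	0.06
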