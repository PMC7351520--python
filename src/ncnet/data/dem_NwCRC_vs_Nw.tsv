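feature_id	gene_name	biotype	log2fc	fdr
let-7f-5p	let-7f-5p	miRNA	0.6367	0.06
miR-1246	miR-1246	miRNA	1.4342	0.06
miR-1247-5p	miR-1247-5p	miRNA	-1.1469	0.06
miR-125a-5p	miR-125a-5p	miRNA	-0.6525	0.06
miR-125b-1-3p	miR-125b-1-3p	miRNA	-1.1204	0.06
miR-193b-3p	miR-193b-3p	miRNA	-0.7937	0.06
miR-22-5p	miR-22-5p	miRNA	0.6981	0.06
miR-29b-2-5p	miR-29b-2-5p	miRNA	0.6554	0.06
miR-29b-3p	miR-29b-3p	miRNA	0.9662	0.06
miR-3182	miR-3182	miRNA	1.2731	0.06
miR-328-3p	miR-328-3p	miRNA	-0.84	0.06
miR-33b-3p	miR-33b-3p	miRNA	-1.243	0.06
miR-345-5p	miR-345-5p	miRNA	-0.6699	0.06
miR-3622a-5p	miR-3622a-5p	miRNA	-1.249	0.06
miR-374a-3p	miR-374a-3p	miRNA	0.765	0.06
miR-374b-5p	miR-374b-5p	miRNA	0.9486	0.06
miR-4455	miR-4455	miRNA	-1.3104	0.06
miR-452-5p	miR-452-5p	miRNA	0.6354	0.06
miR-598-3p	miR-598-3p	miRNA	0.9845	0.06
miR-664a-3p	miR-664a-3p	miRNA	0.9304	0.06
miR-7706	miR-7706	miRNA	-0.8991	0.06
miR-98-5p	miR-98-5p	miRNA	0.7211	0.06
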