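feature_id	gene_name	biotype	log2fc	fdr
let-7e-3p	let-7e-3p	miRNA	-0.5072	0.06
let-7i-3p	let-7i-3p	miRNA	-0.7816	0.06
miR-100-5p	miR-100-5p	miRNA	-0.8363	0.06
miR-107	miR-107	miRNA	0.4816	0.06
miR-10b-3p	miR-10b-3p	miRNA	0.9854	0.06
miR-10b-5p	miR-10b-5p	miRNA	1.069	0.06
miR-1247-5p	miR-1247-5p	miRNA	-1.0182	0.06
miR-125a-5p	miR-125a-5p	miRNA	-0.727	0.06
miR-125b-1-3p	miR-125b-1-3p	miRNA	-1.1041	0.06
miR-1287-5p	miR-1287-5p	miRNA	1.2275	0.06
miR-1299	miR-1299	miRNA	1.2495	0.06
miR-1323	miR-1323	miRNA	-1.4956	0.06
miR-152-3p	miR-152-3p	miRNA	0.6534	0.06
miR-181c-5p	miR-181c-5p	miRNA	1.2047	0.06
miR-181d-5p	miR-181d-5p	miRNA	1.272	0.06
miR-185-5p	miR-185-5p	miRNA	0.8778	0.06
miR-193b-3p	miR-193b-3p	miRNA	-0.7744	0.06
miR-22-5p	miR-22-5p	miRNA	0.7611	0.06
miR-24-3p	miR-24-3p	miRNA	0.766	0.06
miR-28-5p	miR-28-5p	miRNA	0.4959	0.06
miR-29b-2-5p	miR-29b-2-5p	miRNA	0.733	0.06
miR-30c-5p	miR-30c-5p	miRNA	-0.674	0.06
miR-34a-5p	miR-34a-5p	miRNA	1.1756	0.06
miR-378f	miR-378f	miRNA	-1.0918	0.06
miR-421	miR-421	miRNA	0.8296	0.06
miR-4455	miR-4455	miRNA	-1.2491	0.06
miR-452-5p	miR-452-5p	miRNA	0.7434	0.06
miR-508-3p	miR-508-3p	miRNA	1.1567	0.06
miR-512-3p	miR-512-3p	miRNA	-1.3976	0.06
miR-515-5p	miR-515-5p	miRNA	-1.1957	0.06
miR-516a-5p	miR-516a-5p	miRNA	-1.4569	0.06
miR-516b-5p	miR-516b-5p	miRNA	-1.3241	0.06
miR-517a-3p	miR-517a-3p	miRNA	-1.5517	0.06
miR-517b-3p	miR-517b-3p	miRNA	-1.5517	0.06
miR-548az-5p	miR-548az-5p	miRNA	1.3631	0.06
miR-7706	miR-7706	miRNA	-0.6495	0.06
miR-92a-3p	miR-92a-3p	miRNA	-0.5834	0.06
miR-98-5p	miR-98-5p	miRNA	0.6373	0.06
miR-99a-3p	miR-99a-3p	miRNA	0.5715	0.06
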