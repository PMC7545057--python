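accession	gene_symbol	description	rpkm	stage
comp30822_c1_seq1	BMP-3B	bone morphogenetic protein 3/3B	0.415	NP
comp26554_c0_seq1	GPR64	G protein-coupled receptor 64	0.386	NP
comp1343_c1_seq1	MYSM1	protein MYSM1	0.958	D
comp14291_c0_seq1	MYB	myb proto-oncogene protein	1.720	D
comp15472_c0_seq1	GZMH	granzyme H (cathepsin G-like 2)	5.420	D
comp17324_c0_seq1	GJB2	gap junction protein, beta 2	2.511	D
comp25676_c0_seq1	ITGA11	integrin alpha 11	0.659	D
comp28858_c0_seq1	ZSCAN20	KRAB domain-containing zinc finger protein	0.821	D
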