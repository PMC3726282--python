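gene_id	description	qpcr_ratio	rnaseq_ratio
sll0221	Bacterioferritin comigratory protein	-1.18	-1.87
sll0248	Flavodoxin	1.31	3.67
sll0629	Photosystem I reaction center subunit PsaK 2	1.05	1.11
sll1327	ATP synthase gamma chain	1.29	1.10
sll1734	Hypothetical protein	1.52	1.29
sll1796	Cytochrome c6	1.74	2.38
slr0288	Glutamate--ammonia ligase	4.47	2.28
slr0952	Fructose-1,6-bisphosphatase class 1	-1.52	1.36
slr1828	Ferredoxin	1.96	3.33
slr1909	NarL subfamily response regulator	1.50	1.06
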