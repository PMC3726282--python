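gene_id	transcript_fc_24h	transcript_fc_48h	transcript_fc_72h	protein_fc_24h	protein_fc_48h	description
sll0135	1.64	1.61	2.51		2.42	5'-methylthioadenosine phosphorylase
slr1390	1.83	1.62	2.74		1.52	Cell division protein FtsH
sll1796	3.70	2.38	9.75	3.80	2.91	Cytochrome C553
slr0093	2.61	1.53	2.61		1.93	DnaJ protein
slr1330	3.18	2.11	5.69	1.86		F0F1 ATP synthase subunit epsilon
slr1828	3.38	3.33	11.00	2.09	1.66	Ferredoxin
sll0248	3.60	3.67	1.86	1.59	6.26	Flavodoxin FldA
sll0335	1.64	4.33	1.75		1.52	Hypothetical protein
sll0470	4.27	1.55	2.84		1.67	Hypothetical protein
sll1618	1.63	2.71	1.86	1.53	1.67	Hypothetical protein
sll1895	2.23	1.69	2.31		1.59	Hypothetical protein
slr0643	2.13	1.69	2.25	1.52	1.88	Hypothetical protein
slr1046	1.86	1.75	1.50	1.57		Hypothetical protein
ssl0242	2.63	2.53	2.47	1.79	1.66	Hypothetical protein
ssl0352	2.30	2.60	6.33	1.62	1.84	Hypothetical protein
sll0689	2.21	1.63	3.28	1.70	1.93	Na/H+ antiporter
slr1755	1.97	1.85	3.44	1.56		NAD(P)H-dependent glycerol-3-phosphate dehydrogenase
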