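gene_id	fc_24h	fc_48h	fc_72h	category	description
sll0034	2.52	1.54	1.86	Cell envelope	D,D-carboxypeptidase
sll0286	2.33	1.90	1.55	Cell envelope	Uncharacterized N-acetyltransferase
sll0886	1.88	1.78	2.79	Cell envelope	UDP-N-acetylglucosamine-peptide N-acetylglucosaminyltransferase
sll1053	3.52	4.00	12.12	Cell envelope	Membrane fusion protein mtrc precursor, putative
sll1395	1.91	2.61	1.54	Cell envelope	dTDP-6-6-deoxy-L-mannose-dehydrogenase
sll2010	1.60	1.78	2.89	Cell envelope	UDP-N-acetylmuramoylalanine--D-glutamate ligase
slr0528	2.52	1.91	2.45	Cell envelope	UDP-N-acetylmuramoylalanyl-D-glutamate--2,6-diaminopimelate ligase
slr0993	1.75	2.33	4.21	Cell envelope	Putative peptidase
slr1166	2.86	1.68	2.36	Cell envelope	UDP-glucose:tetrahydrobiopterin glucosyltransferase
slr1196	4.07	1.91	2.74	Cell envelope	Periplasmic protein, function unknown
slr1744	1.89	1.92	2.42	Cell envelope	N-acetylmuramoyl-L-alanine amidase, periplasmic protein
slr2015	3.56	4.15	2.39	Cell envelope	Type 4 pilin-like protein, essential for motility
slr2016	4.40	1.71	1.71	Cell envelope	Type 4 pilin-like protein, essential for motility
sll0646	4.03	1.87	1.96	Central intermediary metabolism	Guanylyl cyclase
slr0288	1.65	2.28	2.58	Central intermediary metabolism	Glutamate--ammonia ligase
slr0899	2.19	2.75	2.50	Central intermediary metabolism	Cyanate lyase
slr0940	3.33	1.96	4.21	Central intermediary metabolism	Zeta-carotene desaturase
slr1254	1.73	1.76	4.43	Central intermediary metabolism	Phytoene dehydrogenase (phytoene desaturase)
slr1877	6.00	3.15	3.75	Central intermediary metabolism	2-hydroxyhepta-2,4-diene-1,7-dioate isomerase
sll0248	3.60	3.67	1.86	Common stress response	Flavodoxin
sll1388	3.21	1.58	1.82	Common stress response	Universal stress protein
sll1988	1.90	1.53	1.81	Common stress response	33 kDa chaperonin
slr0093	2.61	1.53	2.61	Common stress response	DnaJ protein, molecular chaperone
slr1795	2.43	1.71	2.16	Common stress response	Peptide methionine sulfoxide reductase
slr1828	3.38	3.33	11.00	Common stress response	Ferredoxin, petF-like protein
slr1846	1.53	2.25	4.71	Common stress response	Uncharacterized monothiol glutaredoxin
slr1854	4.09	1.59	4.38	Common stress response	General stress protein 18 (gsp17)
slr2047	2.06	1.65	1.62	Common stress response	Phosphate starvation-inducible protein
ssl2250	6.00	2.00	5.00	Common stress response	Bacterioferritin-associated ferredoxin
sll0616	4.19	1.88	3.54	Protein fate	Preprotein translocase SecA subunit
sll0716	3.50	3.00	1.83	Protein fate	Probable signal peptidase I-1
slr0835	1.87	2.17	6.92	Protein fate	MoxR protein homolog
slr0994	2.22	1.62	2.30	Protein fate	Octanoyltransferase
slr1046	1.86	1.75	1.50	Protein fate	Putative TatA protein
slr1204	4.18	2.63	5.57	Protein fate	Putative serine protease HtrA
slr1331	2.94	2.26	3.98	Protein fate	Periplasmic processing protease
ssr3307	1.76	1.63	2.04	Protein fate	Preprotein translocase SecG subunit
sll0043	3.20	3.20	2.21	Regulatory functions	Positive phototaxis histidine kinase
sll0690	5.00	1.57	6.00	Regulatory functions	Probable transcription regulator
slr0640	2.28	1.86	2.20	Regulatory functions	Two-component sensor histidine kinase
slr0780	1.84	1.70	2.33	Regulatory functions	Transcriptional repressor NrdR
slr0947	3.18	2.38	5.44	Regulatory functions	Response regulator for energy transfer from phycobilisomes to photosystems
slr1037	3.63	2.00	3.33	Regulatory functions	Two-component response regulator CheY subfamily
slr1042	3.60	2.45	1.72	Regulatory functions	Two-component response regulator CheY subfamily
slr1414	1.54	1.67	1.66	Regulatory functions	Two-component sensor histidine kinase
slr1531	3.00	1.83	1.55	Regulatory functions	Signal recognition particle protein
slr1805	1.53	3.81	4.66	Regulatory functions	Two-component sensor histidine kinase
ssl0707	2.67	1.93	2.78	Regulatory functions	Nitrogen regulatory protein P-II
slr1993	8.75	1.76	4.79	Storage compound biosynthesis	PHA-specific beta-ketothiolase
slr1994	32.00	11.50	4.86	Storage compound biosynthesis	PHA-specific acetoacetyl-CoA reductase
slr2002	3.52	2.09	2.57	Storage compound biosynthesis	Cyanophycin synthetase
sll0374	1.65	1.90	2.83	Transport and binding proteins	Urea transport system ATP-binding protein
sll0689	2.21	1.63	3.28	Transport and binding proteins	Na+/H+ antiporter
sll0759	3.11	1.56	6.87	Transport and binding proteins	ABC transporter ATP-binding protein
sll1041	3.74	2.50	3.43	Transport and binding proteins	Similar to sulfate transport ATP-binding protein CysA
sll1154	1.76	2.80	3.98	Transport and binding proteins	NorA
sll1164	6.60	1.50	1.60	Transport and binding proteins	Uncharacterized transporter
sll1428	32.00	2.00	7.00	Transport and binding proteins	Probable sodium-dependent transporter
sll1450	2.89	3.98	5.27	Transport and binding proteins	Nitrate/nitrite transport system substrate-binding protein
sll1451	2.52	1.73	5.97	Transport and binding proteins	Nitrate/nitrite transport system permease protein
sll1452	1.98	1.66	3.12	Transport and binding proteins	Nitrate/nitrite transport system ATP-binding protein
sll1481	3.14	1.66	3.38	Transport and binding proteins	ABC-transporter membrane fusion protein
sll1482	3.30	1.51	2.57	Transport and binding proteins	ABC transporter permease protein
sll1623	2.15	1.56	1.91	Transport and binding proteins	ABC transporter ATP-binding protein
slr1248	2.57	2.63	3.00	Transport and binding proteins	Phosphate transport system permease protein PstC homolog
slr1295	2.33	1.79	5.92	Transport and binding proteins	Iron transport system substrate-binding protein
slr1318	1.50	2.50	1.77	Transport and binding proteins	Iron (III) dicitrate transport system ATP-binding protein
slr1515	2.56	1.61	3.47	Transport and binding proteins	Putative membrane protein required for bicarbonate uptake
slr1729	1.96	1.52	2.13	Transport and binding proteins	Potassium-transporting P-type ATPase B chain
slr2131	4.50	2.51	12.87	Transport and binding proteins	RND multidrug efflux transporter
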