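metabolite	s24	s48	s72	cluster
Aspartic acid	4	9	9	I
Glycerol 1-phosphate	7	9	6	I
3-phosphoglycerate	3	9	3	I
Citric acid	2	9	6	I
D-allose	9	3	9	I
Adenosine	5	9	8	I
Urea	1	7	3	I
Oxalic acid	0	9	6	II
Glycine	0	4	5	II
Succinic acid	0	6	6	II
L-glutamic acid (dehydrated)	0	9	6	II
Isocitric acid	0	6	6	II
Myristic acid	0	6	8	II
Sucrose	0	6	9	II
1,3 Propanediol	6	-6	-6	III
L-alanine	3	-3	-9	III
Itaconic acid	9	-4	-9	III
Spermidine	4	-9	-5	III
Methyl palmitate	9	-5	6	IV
Talose	9	-4	9	IV
Benzene-1,2,4-triol	2	-3	6	IV
Adrenaline	7	-6	9	IV
Lauric acid	9	-8	7	IV
L-threonine	7	9	0	V
D-malic acid	5	3	0	V
L-serine	6	5	0	V
L-pyroglutamic acid	-3	-9	-3	VI
Linoleic acid	7	0	9	VI
L-(+) lactic acid	2	-6	0	VI
Pyruvic acid	-6	0	9	VI
3-hydroxypyridine	0	-5	9	VI
4-hydroxypyridine	0	-3	8	VI
Malonic acid	-5	-3	8	VI
Caprylic acid	-6	0	9	VI
Octane	-2	-5	8	VI
Glycerol	6	-5	0	VI
Glyceric acid	8	-9	0	VI
Uracil	-8	6	4	VI
Putrescine	-8	0	2	VI
Tagatose	-5	0	9	VI
Palmitic acid	0	-6	5	VI
Methyl stearate	-9	9	9	VI
D-glucose-6-phosphate	-3	8	9	VI
Stearic acid	0	-8	5	VI
Arachidic acid	-3	-8	5	VI
D-(+) trehalose	-3	9	0	VI
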