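metabolite,gene_id,pathway
Aspartic acid,slr0550,aspartate pathway (dihydrodipicolinate synthase)
L-serine,sll0455,serine pathway (homoserine dehydrogenase)
L-glutamic acid (dehydrated),sll1883,glutamate family (ornithine acetyltransferase/N-acetylglutamate synthase)
L-glutamic acid (dehydrated),sll0461,glutamate family (gamma-glutamyl phosphate reductase)
L-glutamic acid (dehydrated),slr0288,glutamate family (glutamate--ammonia ligase)
L-glutamic acid (dehydrated),slr1898,glutamate family (acetylglutamate kinase)
D-glucose-6-phosphate,slr0752,glycolysis (phosphopyruvate hydratase)
D-glucose-6-phosphate,sll0745,glycolysis (6-phosphofructokinase)
3-phosphoglycerate,slr0752,glycolysis (phosphopyruvate hydratase)
3-phosphoglycerate,sll0745,glycolysis (6-phosphofructokinase)
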