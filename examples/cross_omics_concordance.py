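"""Transcript-protein concordance classes and metabolite-gene links.

Joins the induced-gene set (curated fold-change tables) with the external
proteomic fold changes and with the qualified metabolites via the curated
pathway link table.
"""

import pandas as pd

from butomics import (
    FoldChangeTable,
    build_concordance,
    filter_consistent_induction,
    link_metabolites_to_genes,
    load_fixture,
    qualify_from_scores,
)

t2 = load_fixture("table2_fc")
t4 = load_fixture("table4")
fc2 = t2[["fc_24h", "fc_48h", "fc_72h"]].set_axis([24, 48, 72], axis=1)
fc4 = t4[["transcript_fc_24h", "transcript_fc_48h", "transcript_fc_72h"]].set_axis(
    [24, 48, 72], axis=1
)
induced = filter_consistent_induction(
    FoldChangeTable(fc=pd.concat([fc2, fc4[~fc4.index.isin(fc2.index)]]))
)

prot = t4[["protein_fc_24h", "protein_fc_48h"]].set_axis([24, 48], axis=1)
conc = build_concordance(induced, prot, threshold=1.5)
print("concordance classes over", len(induced), "induced genes:", conc.counts)
# both_up = protein also >= 1.5-fold at 24 or 48 h; genes without a
# detected protein count as unchanged.

t5 = load_fixture("table5_scores")
scores = t5[["s24", "s48", "s72"]].set_axis([24, 48, 72], axis=1)
qualified = list(scores.index[qualify_from_scores(scores)])
links = link_metabolites_to_genes(qualified, induced, load_fixture("link_table"))
print("\nmetabolite-gene links where both sides responded:")
print(links.to_string(index=False))
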