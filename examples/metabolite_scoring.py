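"""Replicate-ratio ternary scoring and time-course clustering.

Recomputes the differential-metabolite surface from the packaged sign-sum
score matrix: qualification, per-time-point detection counts, and the
sign-pattern clusters.
"""

from butomics import assign_cluster, load_fixture, qualify_from_scores
from butomics.metabolomics import cluster_sizes

t5 = load_fixture("table5_scores")
scores = t5[["s24", "s48", "s72"]].set_axis([24, 48, 72], axis=1)

# Each score is the sum of nine ternary codes (+1/0/-1 from the +-1.5
# cutoff on the 3x3 treated-vs-control replicate ratios), so it ranges
# -9..+9; |score| >= 5 at some time point implies >= 5 changed ratios.
qualified = qualify_from_scores(scores)
print(f"{int(qualified.sum())} of {len(scores)} metabolites qualify as "
      "differentially regulated")

nonzero = (scores != 0).sum(axis=0)
print("metabolites with a nonzero score per time point:",
      {int(t): int(n) for t, n in nonzero.items()})

assignment = assign_cluster(scores)
print("cluster sizes:", cluster_sizes(assignment))
# Cluster I = up at all three time points; II = up only at 48 and 72 h;
# VI collects every pattern outside the five canonical ones.
print("\naspartic acid:", assignment.loc["Aspartic acid"].to_dict())
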