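"""Build a signed co-expression network and detect modules.

Pipeline: Pearson correlation -> signed soft-threshold adjacency
((1+cor)/2)^beta with beta picked by the scale-free criterion ->
topological overlap -> average-linkage clustering of 1-TOM -> hybrid
dynamic tree cut -> module colors and eigengenes.
"""

from sklearn.metrics import adjusted_rand_score

from coexdiff import (
    average_linkage,
    build_network,
    default_paper_like_scenario,
    hybrid_dynamic_cut,
    module_eigengenes,
    simulate_two_condition,
    tom_dissimilarity,
)
from coexdiff.modules import ModulePartition, assign_colors

cfg = default_paper_like_scenario(seed=1)
expr_ref, _, _, truth = simulate_two_condition(cfg)

net, scan = build_network(expr_ref)
print(f"soft threshold: beta={net.beta} "
      f"(scale-free criterion met: {scan.criterion_met})")
print(scan.to_frame().round(3).to_string(index=False))

diss = tom_dissimilarity(net.tom)
dend = average_linkage(diss, gene_ids=net.gene_ids)
labels = hybrid_dynamic_cut(dend, diss, deep_split=1, cut_height=0.99, min_size=27)
part = assign_colors(ModulePartition(net.gene_ids, labels))

print(f"\ndetected {len(part.module_ids)} modules "
      f"({(labels == 0).sum()} genes unassigned/grey):")
eig = module_eigengenes(expr_ref, part)
for m in part.module_ids:
    print(f"  {part.color_of(m):10s} size {part.module_sizes()[m]:3d}  "
          f"eigengene variance explained {eig.var_explained[m]:.2f}")

mask = labels != 0
ari = adjusted_rand_score(truth.module_of.to_numpy()[mask], labels[mask])
print(f"\nadjusted Rand index vs planted modules (assigned genes): {ari:.3f}")
# ARI near 1 means the detected partition reproduces the planted module
# memberships almost exactly; weakly loaded modules may stay grey when the
# chosen beta crushes their topological-overlap contrast.
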