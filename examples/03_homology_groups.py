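"""Infer cross-species homology groups from hairpin sequences.

All-against-all seeded local alignment (word size 10) with search-space
E-values; hits at E <= 0.1 become edges whose connected components are the
candidate homology groups.  Multi-member groups get a neighbor-joining tree
on uncorrected distances for inspection.
"""

from mirsexbias.homology import (
    build_groups, distance_matrix, find_hits, neighbor_joining,
)
from mirsexbias.io_tables import write_newick
from mirsexbias.simulate import (
    SimulationConfig, simulate_annotation, simulate_sequences,
)

config = SimulationConfig(seed=1)
ann1, ann2, truth = simulate_annotation(config)
seqs1, seqs2 = simulate_sequences(ann1, ann2, truth, config)

hits = find_hits(seqs1, seqs2, word_size=10, evalue_max=0.1)
groups = build_groups(hits, [l.id for l in ann1], [l.id for l in ann2])

by_class = {}
for g in groups:
    by_class[g.cls] = by_class.get(g.cls, 0) + 1
print(f"{len(hits)} similarity hits -> {len(groups)} groups: {by_class}")

family = next(g for g in groups if len(g.members1 + g.members2) >= 3)
members = family.members1 + family.members2
seqs = {m: {**seqs1, **seqs2}[m] for m in members}
tree = neighbor_joining(distance_matrix(seqs))
print(f"example {family.cls} group tree: {write_newick(tree)}")
# Unpaired groups are the novel (lineage-specific) loci: they have no
# cross-species counterpart, so they stay as singletons in the graph.
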