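"""Simulate a two-species microRNA study with planted structure.

Builds annotations, hairpin sequences and count matrices for a
melanogaster-like reference species and a pseudoobscura-like focal species
(whose X carries the neo-X arm, Muller element D), and prints what was
planted so downstream stages can be judged against it.
"""

from mirsexbias.simulate import (
    SimulationConfig, simulate_annotation, simulate_counts, simulate_sequences,
)

config = SimulationConfig(seed=1, translocation_count=2)
ann1, ann2, truth = simulate_annotation(config)
seqs1, seqs2 = simulate_sequences(ann1, ann2, truth, config)
counts = simulate_counts(ann2, truth, config, design="paired")

print(f"species 1 ({config.species_names[0]}): {len(ann1)} loci")
print(f"species 2 ({config.species_names[1]}): {len(ann2)} loci, "
      f"{(truth.loci['age_class'] == 'novel').sum()} novel")
print(f"planted ortholog pairs: {len(truth.orthologs)}")
print(f"planted translocations: {len(truth.translocations)}")
print(truth.translocations.to_string(index=False))
print(f"count matrix: {counts.counts.shape[0]} loci x "
      f"{counts.counts.shape[1]} samples "
      f"({dict(counts.samples['sex'].value_counts())})")
# The translocated pairs listed above are the only ortholog pairs whose
# Muller elements differ; everything else is syntenic by construction.
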