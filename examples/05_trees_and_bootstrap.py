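"""Neighbor-joining trees with bootstrap supports and a consensus.

Builds the NJ tree from JC-corrected distances on simulated CDS data,
attaches bootstrap supports (fraction of column-resampled replicates
containing each bipartition), computes the majority-rule consensus of the
replicates, and scores the tree by Fitch parsimony.
"""

from domaindrift import synthetic_data as sd
from domaindrift.phylo import bootstrap_support, fitch_score, majority_rule_consensus

result = sd.simulate_cds(sd.mammal_config(seed=1))

boot = bootstrap_support(result.nucleotide, n_reps=200, seed=1, model="JC")
print("NJ tree with bootstrap supports (internal node labels):")
print(" ", boot.tree.to_newick())

consensus = majority_rule_consensus(boot.trees, cutoff=0.5)
print("\n50% majority-rule consensus of the replicates:")
print(" ", consensus.to_newick())

score = fitch_score(boot.tree, result.nucleotide)
print(f"\nFitch parsimony score of the NJ topology: {score} changes")
print(f"replicates skipped for saturation: {boot.n_skipped}")
# Supports near 1.0 mean the split is recovered in almost every resampled
# alignment; the generating topology groups primates, domesticated animals
# and rodents, and should be recovered here with strong support.
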