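"""Compress a gene-tree sample into conditional clade probabilities.

Builds a toy posterior sample for one gene family, compresses it into a
CCP table, and enumerates every rooted gene tree that can be amalgamated
from the observed clades together with its probability.
"""

from dtlrec import GeneSpeciesMap, TreeSample, build_ccp, enumerate_amalgamatable
from dtlrec.trees import nested_to_newick

# 100 sampled trees: the sample is 60% confident in ((a,b),c)
trees = [(("a", "b"), "c")] * 60 + [(("a", "c"), "b")] * 30 + [(("b", "c"), "a")] * 10
sample = TreeSample("toy", trees, rooted=True)
mapping = GeneSpeciesMap({"a": "SpeciesA", "b": "SpeciesB", "c": "SpeciesC"})

ccp = build_ccp(sample, mapping)
print(f"{len(ccp.clade_counts)} clades observed in {ccp.sample_size} trees\n")

print("amalgamatable rooted gene trees and their probabilities:")
for topo, prob in sorted(enumerate_amalgamatable(ccp), key=lambda x: -x[1]):
    print(f"  {nested_to_newick(topo):<15} {prob:.3f}")

# The probabilities are the sample frequencies here because three leaves
# admit no clade recombination; with more leaves, amalgamation assigns
# positive probability to topologies never seen whole in the sample.
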