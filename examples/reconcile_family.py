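"""Reconcile one gene family against a fixed species tree.

Computes the amalgamated likelihood of a family under the undated DTL
model, samples reconciled gene trees by stochastic backtracking, and
prints the per-species event summary and the consensus gene tree.
"""

from dtlrec import (
    GeneSpeciesMap,
    SpeciesTree,
    TreeSample,
    build_ccp,
    compute_family,
    majority_consensus,
    sample_reconciliations,
    summarize_events,
)

species_tree = SpeciesTree.from_newick("((A,B),C);")
# two gene copies in A — this family must contain a duplication or a transfer
trees = [(("a1", "a2"), ("b", "c"))] * 8 + [((("a1", "b"), "a2"), "c")] * 2
sample = TreeSample("fam1", trees, rooted=True)
mapping = GeneSpeciesMap({"a1": "A", "a2": "A", "b": "B", "c": "C"})
ccp = build_ccp(sample, mapping)

# duplication, transfer and loss probabilities δ, τ, λ
fl, matrix = compute_family(ccp, species_tree, 0.2, 0.05, 0.1)
print(f"log-likelihood of the family: {fl.log_likelihood:.4f}")
print(f"(survival conditioning constant: {fl.conditioning_constant:.4f})\n")

recs = sample_reconciliations(matrix, r=200, seed=1)
print("mean events per species branch over 200 sampled reconciliations:")
print(summarize_events(recs).round(3))
# S/D/T/TL/L are speciation, duplication, transfer, transfer-loss and loss
# counts; 'copies' is the mean number of ancestral gene copies per branch.

print("\nrooted majority-rule consensus gene tree (supports = sample fractions):")
print(majority_consensus(recs).to_newick())
# Note that the consensus can disagree with the raw sample frequencies:
# reconciled trees are drawn from the *joint* posterior, so a topology that
# is rarer in the input sample but far cheaper to reconcile (fewer implied
# duplications and losses) gains weight.

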