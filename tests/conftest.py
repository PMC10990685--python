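import numpy as np
import pytest

from dtlrec.ccp import CCPTable, GeneSpeciesMap, TreeSample, build_ccp
from dtlrec.trees import SpeciesTree, canonical_nested


@pytest.fixture
def three_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("((A,B),C);")


@pytest.fixture
def mapping_abc() -> GeneSpeciesMap:
    return GeneSpeciesMap({"a": "A", "b": "B", "c": "C"})


@pytest.fixture
def congruent_ccp(mapping_abc) -> CCPTable:
    """100 identical rooted trees congruent with ((A,B),C)."""
    sample = TreeSample("fam1", [(("a", "b"), "c")] * 100, rooted=True)
    return build_ccp(sample, mapping_abc)


@pytest.fixture
def mixed_ccp(mapping_abc) -> CCPTable:
    """60/30/10 mixture of the three rooted 3-leaf topologies."""
    trees = (
        [(("a", "b"), "c")] * 60 + [(("a", "c"), "b")] * 30 + [(("b", "c"), "a")] * 10
    )
    return build_ccp(TreeSample("fam1", trees, rooted=True), mapping_abc)


def caterpillar(labels):
    t = labels[0]
    for lab in labels[1:]:
        t = (t, lab)
    return canonical_nested(t)


def deep_multicopy_family(n_species: int, copies: int = 4, m: int = 5):
    """Congruent family with `copies` genes per species on a caterpillar tree.

    Each species leaf carries a balanced within-species subtree of gene
    copies, so the family requires one duplication per extra copy — the
    classic deep multi-copy instance whose likelihood underflows doubles.
    """
    labels = [f"S{i:02d}" for i in range(1, n_species + 1)]
    nested = caterpillar(labels)
    S = SpeciesTree.from_nested(nested)
    mapping: dict[str, str] = {}

    def expand(t):
        if isinstance(t, str):
            gs = [f"{t.lower()}_g{j}" for j in range(1, copies + 1)]
            for g in gs:
                mapping[g] = t
            if copies == 1:
                return gs[0]
            if copies == 2:
                return (gs[0], gs[1])
            if copies == 4:
                return ((gs[0], gs[1]), (gs[2], gs[3]))
            raise ValueError("copies must be 1, 2 or 4")
        return (expand(t[0]), expand(t[1]))

    gene_tree = expand(nested)
    ccp = build_ccp(
        TreeSample(f"deep{n_species}", [gene_tree] * m, rooted=True),
        GeneSpeciesMap(mapping),
    )
    return S, ccp


def random_rooted_sample(rng: np.random.Generator, n_leaves: int, m: int, family_id="fam"):
    """A sample of m random rooted topologies over n_leaves labelled leaves."""
    from dtlrec.trees import random_rooted_topology

    labels = [f"g{i}" for i in range(n_leaves)]
    trees = [random_rooted_topology(labels, rng) for _ in range(m)]
    return TreeSample(family_id, trees, rooted=True)
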