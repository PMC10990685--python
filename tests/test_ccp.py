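"""Conditional clade probability construction and amalgamation queries."""

import math

import numpy as np
import pytest

from dtlrec.ccp import (
    CCPError,
    GeneSpeciesMap,
    TreeSample,
    build_ccp,
    count_amalgamatable,
    enumerate_amalgamatable,
    parse_tree_sample,
    tree_probability,
)
from dtlrec.trees import (
    TreeFormatError,
    canonical_nested,
    parse_newick,
    random_rooted_topology,
    rootings_of_unrooted,
    unroot_nested,
)

from conftest import random_rooted_sample


class TestParseTreeSample:
    def test_parses_all_lines_without_burnin(self):
        text = "((A,B),C);\n" * 10
        sample = parse_tree_sample(text, burnin_fraction=0.0)
        assert len(sample.trees) == 10
        assert sample.rooted
        assert sample.burnin_discarded == 0

    def test_burnin_floor(self):
        text = "((A,B),C);\n" * 10
        sample = parse_tree_sample(text, burnin_fraction=0.5)
        assert len(sample.trees) == 5
        assert sample.burnin_discarded == 5

    def test_inconsistent_leaf_sets_rejected(self):
        text = "((A,B),C);\n((A,B),D);\n"
        with pytest.raises(CCPError, match="inconsistent leaf sets"):
            parse_tree_sample(text)

    def test_unparsable_line_reports_line_number(self):
        text = "((A,B),C);\n((A,B,C;\n"
        with pytest.raises(TreeFormatError, match="line 2"):
            parse_tree_sample(text)

    def test_multifurcation_rejected(self):
        with pytest.raises(TreeFormatError, match="multifurcation"):
            parse_tree_sample("((A,B,C,D),E);\n")

    def test_branch_lengths_and_comments_ignored(self):
        sample = parse_tree_sample("((A:0.1,B:0.2)0.9:0.05,C:0.3);\n")
        assert sample.trees[0] == (("A", "B"), "C")

    def test_unrooted_autodetect(self):
        sample = parse_tree_sample("(A,B,C);\n(A,B,C);\n")
        assert not sample.rooted

    def test_mixed_rooted_unrooted_rejected(self):
        with pytest.raises(CCPError, match="mixes rooted and unrooted"):
            parse_tree_sample("((A,B),C);\n(A,B,C);\n")


class TestBuildCCP:
    def test_single_topology_has_unit_split_frequencies(self, congruent_ccp):
        full = congruent_ccp.root_clade
        ab = congruent_ccp.mask_of(["a", "b"])
        assert congruent_ccp.splits[full] == [
            (congruent_ccp.mask_of(["c"]), ab, 1.0)
        ] or congruent_ccp.splits[full] == [(ab, congruent_ccp.mask_of(["c"]), 1.0)]
        (m1, m2, q) = congruent_ccp.splits[ab][0]
        assert q == 1.0

    def test_even_mixture_splits_half(self, mapping_abc):
        trees = [(("a", "b"), "c")] * 50 + [(("a", "c"), "b")] * 50
        ccp = build_ccp(TreeSample("f", trees, rooted=True), mapping_abc)
        qs = {tuple(sorted((m1, m2))): q for m1, m2, q in ccp.splits[ccp.root_clade]}
        assert all(abs(q - 0.5) < 1e-15 for q in qs.values())

    def test_missing_mapping_entry_rejected(self):
        sample = TreeSample("f", [("a", "b")], rooted=True)
        with pytest.raises(CCPError, match="missing from gene-species mapping"):
            build_ccp(sample, GeneSpeciesMap({"a": "A"}))

    def test_split_frequencies_normalize(self, mixed_ccp):
        for mask, splits in mixed_ccp.splits.items():
            assert abs(sum(q for _, _, q in splits) - 1.0) < 1e-12

    def test_duplicate_trees_count_with_full_weight(self, mapping_abc):
        ccp1 = build_ccp(
            TreeSample("f", [(("a", "b"), "c")] * 3 + [(("a", "c"), "b")], rooted=True),
            mapping_abc,
        )
        qs = {frozenset((m1, m2)): q for m1, m2, q in ccp1.splits[ccp1.root_clade]}
        ab = ccp1.mask_of(["a", "b"])
        c = ccp1.mask_of(["c"])
        assert qs[frozenset((ab, c))] == pytest.approx(0.75)


class TestTreeProbability:
    def test_certain_topology(self, congruent_ccp):
        assert tree_probability(congruent_ccp, (("a", "b"), "c")) == 1.0

    def test_unobserved_clade_gives_zero(self, congruent_ccp):
        assert tree_probability(congruent_ccp, (("a", "c"), "b")) == 0.0

    def test_mixture_probability_is_split_product(self, mapping_abc):
        trees = [(("a", "b"), "c")] * 50 + [(("a", "c"), "b")] * 50
        ccp = build_ccp(TreeSample("f", trees, rooted=True), mapping_abc)
        assert tree_probability(ccp, (("a", "b"), "c")) == pytest.approx(0.5)

    def test_leaf_set_mismatch_rejected(self, congruent_ccp):
        with pytest.raises(CCPError, match="leaf set"):
            tree_probability(congruent_ccp, (("a", "b"), "d"))


class TestEnumerateAmalgamatable:
    def test_single_topology(self, congruent_ccp):
        out = enumerate_amalgamatable(congruent_ccp)
        assert len(out) == 1
        topo, p = out[0]
        assert canonical_nested(topo) == canonical_nested((("a", "b"), "c"))
        assert p == 1.0

    def test_even_mixture_two_topologies(self, mapping_abc):
        trees = [(("a", "b"), "c")] * 50 + [(("a", "c"), "b")] * 50
        ccp = build_ccp(TreeSample("f", trees, rooted=True), mapping_abc)
        out = enumerate_amalgamatable(ccp)
        assert len(out) == 2
        assert all(p == pytest.approx(0.5) for _, p in out)

    def test_explosion_guard(self, mixed_ccp):
        with pytest.raises(CCPError, match="max_trees"):
            enumerate_amalgamatable(mixed_ccp, max_trees=1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_probabilities_sum_to_one(self, seed):
        """Telescoping of conditional split frequencies over the expansion."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        sample = random_rooted_sample(rng, n, m=30)
        mapping = GeneSpeciesMap({f"g{i}": f"S{i}" for i in range(n)})
        ccp = build_ccp(sample, mapping)
        out = enumerate_amalgamatable(ccp, max_trees=100_000)
        assert len(out) == count_amalgamatable(ccp)
        assert math.fsum(p for _, p in out) == pytest.approx(1.0, abs=1e-9)
        for topo, p in out:
            assert tree_probability(ccp, topo) == pytest.approx(p)


class TestUnrootedConstruction:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_all_rootings_construction(self, seed):
        """Unrooted CCPs must match rooting each tree on each of its edges."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        labels = [f"g{i}" for i in range(n)]
        mapping = GeneSpeciesMap({f"g{i}": f"S{i}" for i in range(n)})
        trees = [random_rooted_topology(labels, rng) for _ in range(10)]
        unrooted = [unroot_nested(t) for t in trees]

        ccp_u = build_ccp(TreeSample("f", unrooted, rooted=False), mapping)
        rooted_all = [r for t in unrooted for r in rootings_of_unrooted(t)]
        ccp_r = build_ccp(TreeSample("f", rooted_all, rooted=True), mapping)

        assert set(ccp_u.splits) == set(ccp_r.splits)
        for mask in ccp_u.splits:
            qu = {(a, b): q for a, b, q in ccp_u.splits[mask]}
            qr = {(a, b): q for a, b, q in ccp_r.splits[mask]}
            assert set(qu) == set(qr)
            for key in qu:
                assert qu[key] == pytest.approx(qr[key], abs=1e-12)

    def test_unrooted_sum_of_tree_probabilities_is_one(self):
        rng = np.random.default_rng(11)
        labels = [f"g{i}" for i in range(5)]
        mapping = GeneSpeciesMap({lab: lab.upper() for lab in labels})
        trees = [unroot_nested(random_rooted_topology(labels, rng)) for _ in range(20)]
        ccp = build_ccp(TreeSample("f", trees, rooted=False), mapping)
        out = enumerate_amalgamatable(ccp, max_trees=1_000_000)
        assert math.fsum(p for _, p in out) == pytest.approx(1.0, abs=1e-9)


class TestMappingFiles:
    def test_two_column_and_grouped_formats(self, tmp_path):
        p1 = tmp_path / "m1.tsv"
        p1.write_text("a\tA\nb\tB\n")
        m1 = GeneSpeciesMap.from_file(p1)
        assert m1.pairs == {"a": "A", "b": "B"}
        p2 = tmp_path / "m2.txt"
        p2.write_text("A:a1;a2\nB:b1\n")
        m2 = GeneSpeciesMap.from_file(p2)
        assert m2.pairs == {"a1": "A", "a2": "A", "b1": "B"}
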