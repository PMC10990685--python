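"""Conditional clade probabilities (CCPs) from gene-tree samples.

A per-family sample of gene trees (typically the posterior sample of a
Bayesian phylogenetic run) is compressed into a :class:`CCPTable`: the set
of clades observed in the sample, and for every observed clade the
frequency with which it splits into each observed pair of child clades,
conditioned on the clade occurring.  The table assigns a nonzero
probability to every rooted gene tree that can be *amalgamated* from
observed clades — the maximum-entropy distribution consistent with the
sample's marginal split frequencies — and is the object the
reconciliation likelihood sums over.

Clades are identified by leaf-membership bitmasks under a canonical
(lexicographic) ordering of the family's gene labels; the smaller mask of
a split pair is stored first.
"""

from __future__ import annotations

import io as _io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, TextIO, Union

from .trees import (
    Nested,
    TreeFormatError,
    dendropy_to_nested,
    is_rooted_nested,
    nested_leaves,
    parse_newick,
    unroot_nested,
)


class CCPError(ValueError):
    pass


@dataclass
class TreeSample:
    """An ordered sample of same-leaf-set gene-tree topologies for one family."""

    family_id: str
    trees: list[Nested]
    rooted: bool
    weight_per_tree: float = 1.0
    burnin_discarded: int = 0

    def __post_init__(self) -> None:
        if not self.trees:
            raise CCPError(f"family {self.family_id}: empty tree sample")
        first = nested_leaves(self.trees[0])
        ref = frozenset(first)
        if len(ref) != len(first):
            raise CCPError(f"family {self.family_id}: duplicate gene leaf labels")
        for i, t in enumerate(self.trees):
            leaves = nested_leaves(t)
            if frozenset(leaves) != ref or len(leaves) != len(first):
                raise CCPError(
                    f"family {self.family_id}: inconsistent leaf sets "
                    f"(tree {i + 1} differs from tree 1)"
                )

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(nested_leaves(self.trees[0]))


@dataclass
class GeneSpeciesMap:
    """Total mapping from gene leaf labels to species labels."""

    pairs: dict[str, str]

    def species_of(self, gene: str) -> str:
        try:
            return self.pairs[gene]
        except KeyError:
            raise CCPError(f"gene leaf {gene!r} missing from gene-species mapping") from None

    @classmethod
    def from_file(cls, path: Union[str, os.PathLike]) -> "GeneSpeciesMap":
        """Read a mapping file.

        Two formats are accepted, decided per line:
        tab-separated ``gene<TAB>species``, or ``species:gene1;gene2;...``.
        """
        pairs: dict[str, str] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "\t" in line:
                    parts = line.split("\t")
                    if len(parts) != 2:
                        raise CCPError(f"{path}:{lineno}: expected 2 tab-separated columns")
                    gene, species = parts
                    pairs[gene.strip()] = species.strip()
                elif ":" in line:
                    species, genes = line.split(":", 1)
                    for gene in genes.strip().split(";"):
                        gene = gene.strip()
                        if gene:
                            pairs[gene] = species.strip()
                else:
                    raise CCPError(f"{path}:{lineno}: unrecognized mapping line {line!r}")
        return cls(pairs)


@dataclass
class CCPTable:
    """Conditional clade probabilities of one family's gene-tree sample.

    ``splits[c]`` lists ``(c1, c2, q)`` with ``c1 | c2 == c``,
    ``c1 & c2 == 0``, ``c1 <= c2``, and ``q`` the probability that clade
    ``c`` splits as ``c1|c2`` given that ``c`` occurs.  The full leaf set is
    always registered as the root clade; its splits are the observed root
    splits.  For every registered non-leaf clade the ``q`` sum to one.
    """

    family_id: str
    leaf_order: list[str]
    leaf_species: dict[str, str]
    clade_counts: dict[int, float]
    splits: dict[int, list[tuple[int, int, float]]]
    sample_size: int
    rooted: bool

    @property
    def root_clade(self) -> int:
        return (1 << len(self.leaf_order)) - 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def leaf_mask(self, label: str) -> int:
        return 1 << self.leaf_order.index(label)

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= self.leaf_mask(lab)
        return m

    def clades_by_size(self) -> list[int]:
        return sorted(self.clade_counts, key=lambda m: (m.bit_count(), m))

    def species_of_leaf_mask(self, mask: int) -> str:
        label = self.leaf_order[mask.bit_length() - 1]
        return self.leaf_species[label]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

Source = Union[str, os.PathLike, TextIO, Iterable[str]]


def _iter_lines(source: Source) -> Iterable[str]:
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and not source.rstrip().endswith(";")
    ):
        with open(source) as fh:
            yield from fh
        return
    if isinstance(source, str):
        yield from _io.StringIO(source)
        return
    yield from source


def parse_tree_sample(
    source: Source,
    burnin_fraction: float = 0.0,
    family_id: str = "family",
    rooted: bool | None = None,
    weight_per_tree: float = 1.0,
) -> TreeSample:
    """Parse a one-tree-per-line Newick stream into a :class:`TreeSample`.

    ``burnin_fraction`` discards the first ``floor(f·m)`` tree lines.
    ``rooted=None`` autodetects: trees written with a bifurcating root are
    taken as rooted, a basal trifurcation marks the sample as unrooted
    (mixing the two in one sample is an error).  ``rooted=False`` forces
    unrooted interpretation, collapsing bifurcating roots.
    Branch lengths and comments are discarded; only topology is kept.
    """
    if not (0.0 <= burnin_fraction < 1.0):
        raise CCPError("burnin_fraction must be in [0, 1)")
    trees: list[Nested] = []
    for lineno, raw in enumerate(_iter_lines(source), 1):
        line = raw.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line))
        except (TreeFormatError, Exception) as exc:  # dendropy raises various types
            if isinstance(exc, TreeFormatError):
                raise TreeFormatError(f"family {family_id}, line {lineno}: {exc}") from None
            raise TreeFormatError(
                f"family {family_id}, line {lineno}: unparsable Newick ({exc})"
            ) from None
    m = len(trees)
    discard = math.floor(burnin_fraction * m)
    trees = trees[discard:]
    if not trees:
        raise CCPError(f"family {family_id}: no trees left after burn-in")

    arities = {2 if is_rooted_nested(t) else 3 for t in trees}
    if rooted is None:
        if arities == {2}:
            rooted_flag = True
        elif arities == {3}:
            rooted_flag = False
        else:
            raise CCPError(
                f"family {family_id}: sample mixes rooted and unrooted trees"
            )
    else:
        rooted_flag = rooted
        if rooted and 3 in arities:
            raise CCPError(
                f"family {family_id}: rooted sample requested but trees have "
                "a basal trifurcation"
            )
    if not rooted_flag:
        trees = [unroot_nested(t) for t in trees]
    return TreeSample(
        family_id=family_id,
        trees=trees,
        rooted=rooted_flag,
        weight_per_tree=weight_per_tree,
        burnin_discarded=discard,
    )


def parse_tree_sample_dendropy(trees, family_id: str = "family", **kw) -> TreeSample:
    """Build a sample from already-parsed dendropy trees."""
    return TreeSample(
        family_id=family_id, trees=[dendropy_to_nested(t) for t in trees], **kw
    )


# ---------------------------------------------------------------------------
# CCP construction
# ---------------------------------------------------------------------------

def build_ccp(sample: TreeSample, mapping: GeneSpeciesMap) -> CCPTable:
    """Compress a tree sample into conditional clade probabilities.

    Rooted samples: every tree contributes one observation to each clade it
    contains and to the split at each internal node (the root split
    included).  Unrooted samples: every tree contributes one observation per
    *directed* clade of each edge, and one root split per edge — equivalent
    to rooting each tree uniformly on each of its 2n−3 edges (conditional
    frequencies coincide because the direction multiplicity of a clade
    depends only on its size).
    """
    leaf_order = sample.leaf_labels
    leaf_species = {g: mapping.species_of(g) for g in leaf_order}
    index = {lab: i for i, lab in enumerate(leaf_order)}
    w = sample.weight_per_tree

    counts: dict[int, float] = {}
    split_counts: dict[int, dict[tuple[int, int], float]] = {}

    def add_clade(mask: int) -> None:
        counts[mask] = counts.get(mask, 0.0) + w

    def add_split(mask: int, m1: int, m2: int) -> None:
        if m2 < m1:
            m1, m2 = m2, m1
        d = split_counts.setdefault(mask, {})
        d[(m1, m2)] = d.get((m1, m2), 0.0) + w

    if sample.rooted:
        def walk(t: Nested) -> int:
            if isinstance(t, str):
                m = 1 << index[t]
                add_clade(m)
                return m
            a = walk(t[0])
            b = walk(t[1])
            m = a | b
            add_clade(m)
            add_split(m, a, b)
            return m

        for t in sample.trees:
            walk(t)
    else:
        full = (1 << len(leaf_order)) - 1
        for t in sample.trees:
            if isinstance(t, str):
                add_clade(1 << index[t])
                continue
            if len(t) == 2:  # 2-leaf family: a single edge
                a, b = 1 << index[t[0]], 1 << index[t[1]]
                add_clade(a)
                add_clade(b)
                add_clade(full)
                add_split(full, a, b)
                continue
            adj, labels = _adjacency(t, index)
            masks: dict[tuple[int, int], int] = {}

            def mask_of(frm: int, to: int) -> int:
                key = (frm, to)
                if key in masks:
                    return masks[key]
                if to in labels:
                    m = 1 << labels[to]
                else:
                    kids = [x for x in adj[to] if x != frm]
                    m = mask_of(to, kids[0]) | mask_of(to, kids[1])
                masks[key] = m
                return m

            seen_edges = set()
            for u in adj:
                for v in adj[u]:
                    if (v, u) in seen_edges:
                        continue
                    seen_edges.add((u, v))
                    for frm, to in ((u, v), (v, u)):
                        m = mask_of(frm, to)
                        add_clade(m)
                        if to not in labels:
                            kids = [x for x in adj[to] if x != frm]
                            add_split(m, mask_of(to, kids[0]), mask_of(to, kids[1]))
                    # root split on this edge
                    add_clade(full)
                    add_split(full, mask_of(u, v), mask_of(v, u))

    splits: dict[int, list[tuple[int, int, float]]] = {}
    for mask, d in split_counts.items():
        total = counts[mask]
        splits[mask] = sorted(
            ((m1, m2, c / total) for (m1, m2), c in d.items()),
            key=lambda x: (x[0], x[1]),
        )
    return CCPTable(
        family_id=sample.family_id,
        leaf_order=leaf_order,
        leaf_species=leaf_species,
        clade_counts=counts,
        splits=splits,
        sample_size=len(sample.trees),
        rooted=sample.rooted,
    )


def _adjacency(t: Nested, index: dict[str, int]):
    """Adjacency map of an unrooted (basal-trifurcation) topology."""
    adj: dict[int, list[int]] = {}
    labels: dict[int, int] = {}
    counter = [0]

    def new() -> int:
        i = counter[0]
        counter[0] += 1
        adj[i] = []
        return i

    def build(sub: Nested) -> int:
        i = new()
        if isinstance(sub, str):
            labels[i] = index[sub]
            return i
        for c in sub:
            j = build(c)
            adj[i].append(j)
            adj[j].append(i)
        return i

    build(t)
    return adj, labels


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def tree_probability(ccp: CCPTable, topology: Nested) -> float:
    """Amalgamation probability of one rooted topology under the CCP table.

    Product of the conditional split frequencies over every internal node
    (the root-split term included); zero as soon as a clade or split is
    unregistered.
    """
    leaves = nested_leaves(topology)
    if sorted(leaves) != ccp.leaf_order:
        raise CCPError(
            f"family {ccp.family_id}: query leaf set does not match the CCP table"
        )
    if not is_rooted_nested(topology):
        raise CCPError("tree_probability expects a rooted topology")
    index = {lab: i for i, lab in enumerate(ccp.leaf_order)}
    prob = [1.0]

    def walk(t: Nested) -> int:
        if isinstance(t, str):
            return 1 << index[t]
        a = walk(t[0])
        b = walk(t[1])
        if prob[0] == 0.0:
            return a | b
        m = a | b
        lo, hi = (a, b) if a <= b else (b, a)
        for (m1, m2, q) in ccp.splits.get(m, ()):
            if m1 == lo and m2 == hi:
                prob[0] *= q
                break
        else:
            prob[0] = 0.0
        return m

    walk(topology)
    return prob[0]


def restrict_to_topology(ccp: CCPTable, topology: Nested) -> CCPTable:
    """A CCP table whose only registered splits are those of one topology,
    keeping the original conditional frequencies.

    Running the likelihood recursion on the restricted table isolates that
    topology's (amalgamation probability × reconciliation likelihood)
    contribution; contributions over all amalgamatable topologies sum to
    the full table's likelihood by linearity.
    """
    if tree_probability(ccp, topology) <= 0.0:
        raise CCPError("topology is not amalgamatable from this table")
    index = {lab: i for i, lab in enumerate(ccp.leaf_order)}
    counts: dict[int, float] = {}
    splits: dict[int, list[tuple[int, int, float]]] = {}

    def walk(t: Nested) -> int:
        if isinstance(t, str):
            m = 1 << index[t]
            counts[m] = 1.0
            return m
        a = walk(t[0])
        b = walk(t[1])
        m = a | b
        counts[m] = 1.0
        lo, hi = (a, b) if a <= b else (b, a)
        q = next(
            q for (m1, m2, q) in ccp.splits[m] if (m1, m2) == (lo, hi)
        )
        splits[m] = [(lo, hi, q)]
        return m

    walk(topology)
    return CCPTable(
        family_id=ccp.family_id,
        leaf_order=ccp.leaf_order,
        leaf_species=ccp.leaf_species,
        clade_counts=counts,
        splits=splits,
        sample_size=ccp.sample_size,
        rooted=ccp.rooted,
    )


def count_amalgamatable(ccp: CCPTable) -> int:
    """Number of distinct rooted topologies with nonzero amalgamation probability."""
    memo: dict[int, int] = {}

    def count(mask: int) -> int:
        if mask.bit_count() == 1:
            return 1
        if mask in memo:
            return memo[mask]
        total = sum(count(m1) * count(m2) for (m1, m2, _q) in ccp.splits.get(mask, ()))
        memo[mask] = total
        return total

    return count(ccp.root_clade)


def enumerate_amalgamatable(
    ccp: CCPTable, max_trees: int = 10_000
) -> list[tuple[Nested, float]]:
    """Exhaustively expand every amalgamatable rooted topology with its probability.

    Intended for small families; refuses when more than ``max_trees``
    topologies are registered.
    """
    n = count_amalgamatable(ccp)
    if n > max_trees:
        raise CCPError(
            f"family {ccp.family_id}: {n} amalgamatable topologies exceed "
            f"max_trees={max_trees}"
        )

    memo: dict[int, list[tuple[Nested, float]]] = {}

    def expand(mask: int) -> list[tuple[Nested, float]]:
        if mask.bit_count() == 1:
            return [(ccp.leaf_order[mask.bit_length() - 1], 1.0)]
        if mask in memo:
            return memo[mask]
        out: list[tuple[Nested, float]] = []
        for (m1, m2, q) in ccp.splits.get(mask, ()):
            for t1, p1 in expand(m1):
                for t2, p2 in expand(m2):
                    out.append(((t1, t2), q * p1 * p2))
        memo[mask] = out
        return out

    return expand(ccp.root_clade)
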