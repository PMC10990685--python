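"""Rooted tree containers shared across the package.

Two representations are used throughout:

* *nested tuples* for gene-tree topologies: a leaf is its label (``str``),
  an internal node is a 2-tuple ``(left, right)``.  An unrooted topology is
  carried as a 3-tuple at the outermost level (the usual basal trifurcation
  of unrooted Newick).  Topologies carry no branch lengths.
* :class:`SpeciesTree` for the species tree: an indexed, rooted, strictly
  binary tree with one *branch* per node (the root included), postorder
  bookkeeping and stable internal labels, which is what the dynamic
  programming recursions index into.

Newick parsing and writing delegate to :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

import dendropy
import numpy as np

Nested = Union[str, tuple]


class TreeFormatError(ValueError):
    """Malformed or unsupported tree input."""


# ---------------------------------------------------------------------------
# nested-tuple helpers
# ---------------------------------------------------------------------------

def dendropy_to_nested(tree: dendropy.Tree) -> Nested:
    """Convert a dendropy tree to a nested-tuple topology.

    Bifurcating nodes become 2-tuples; a trifurcating seed node becomes a
    3-tuple (unrooted convention).  Any other multifurcation raises
    :class:`TreeFormatError` — conditional clade splits are only defined on
    binary nodes, and silently resolving polytomies would bias the split
    frequencies.
    """

    def conv(node: dendropy.Node) -> Nested:
        children = node.child_nodes()
        if not children:
            if node.taxon is not None and node.taxon.label is not None:
                return node.taxon.label.replace(" ", "_")
            if node.label:
                return node.label
            raise TreeFormatError("unlabeled leaf node")
        if len(children) != 2:
            raise TreeFormatError(
                f"multifurcation of degree {len(children)} is not supported"
            )
        return (conv(children[0]), conv(children[1]))

    top = tree.seed_node.child_nodes()
    if not top:
        # single-leaf tree
        return conv(tree.seed_node)
    if len(top) == 2:
        return (conv(top[0]), conv(top[1]))
    if len(top) == 3:
        return (conv(top[0]), conv(top[1]), conv(top[2]))
    raise TreeFormatError(
        f"root of degree {len(top)} is not supported (expected 2 or 3)"
    )


def parse_newick(text: str) -> Nested:
    """Parse one Newick string into a nested-tuple topology."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except TreeFormatError:
        raise
    except Exception as exc:
        raise TreeFormatError(f"unparsable Newick ({exc})") from None
    return dendropy_to_nested(tree)


def nested_leaves(t: Nested) -> list[str]:
    """Leaf labels of a nested topology, left-to-right."""
    if isinstance(t, str):
        return [t]
    out: list[str] = []
    for child in t:
        out.extend(nested_leaves(child))
    return out


def nested_to_newick(t: Nested) -> str:
    def fmt(n: Nested) -> str:
        if isinstance(n, str):
            return n
        return "(" + ",".join(fmt(c) for c in n) + ")"

    return fmt(t) + ";"


def unrooted_splits(t: Nested) -> frozenset:
    """Canonical identity of the unrooted topology: its set of bipartitions.

    Each split is the frozenset of its two leaf-label sides, so the result
    does not depend on where the basal trifurcation (or root) sits.
    """
    t = unroot_nested(t)
    all_leaves = frozenset(nested_leaves(t))
    splits: set[frozenset] = set()

    def walk(sub: Nested) -> frozenset:
        if isinstance(sub, str):
            side = frozenset([sub])
        else:
            side = frozenset().union(*(walk(c) for c in sub))
        if side != all_leaves:
            splits.add(frozenset((side, all_leaves - side)))
        return side

    walk(t)
    return frozenset(splits)


def is_rooted_nested(t: Nested) -> bool:
    return isinstance(t, str) or len(t) == 2


def canonical_nested(t: Nested) -> Nested:
    """Order children recursively by smallest leaf label (deterministic form)."""
    if isinstance(t, str):
        return t
    kids = sorted(
        (canonical_nested(c) for c in t), key=lambda c: min(nested_leaves(c))
    )
    return tuple(kids)


def unroot_nested(t: Nested) -> Nested:
    """Collapse the root of a rooted binary topology into a basal trifurcation."""
    if isinstance(t, str) or len(t) == 3:
        return t
    a, b = t
    if isinstance(a, tuple):
        return (a[0], a[1], b)
    if isinstance(b, tuple):
        return (a, b[0], b[1])
    return t  # two-leaf tree: nothing to collapse


def rootings_of_unrooted(t: Nested) -> list[Nested]:
    """All rooted binary topologies obtained by rooting ``t`` on each edge.

    ``t`` is a basal-trifurcation (or already rooted, in which case it is
    first unrooted).  For n leaves there are 2n-3 rootings.
    """
    t = unroot_nested(t)
    if isinstance(t, str):
        return [t]
    if len(t) == 2:  # 2-leaf tree has a single (trivial) rooting
        return [t]

    # Work on an explicit adjacency structure.
    edges: list[tuple[int, int]] = []
    labels: dict[int, str] = {}
    adj: dict[int, list[int]] = {}
    counter = [0]

    def add_node() -> int:
        i = counter[0]
        counter[0] += 1
        adj[i] = []
        return i

    def build(sub: Nested) -> int:
        i = add_node()
        if isinstance(sub, str):
            labels[i] = sub
            return i
        for c in sub:
            j = build(c)
            adj[i].append(j)
            adj[j].append(i)
            edges.append((i, j))
        return i

    build(t)

    def subtree(frm: int, to: int) -> Nested:
        """Nested topology of the component containing ``to`` seen from edge frm->to."""
        kids = [n for n in adj[to] if n != frm]
        if not kids:
            return labels[to]
        assert len(kids) == 2
        return (subtree(to, kids[0]), subtree(to, kids[1]))

    out = []
    for (u, v) in edges:
        out.append((subtree(v, u), subtree(u, v)))
    return out


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """Rooted strictly-binary species tree with array indexing.

    One *branch* per node (the root branch included), ``n_branches == 2·n_leaves − 1``.
    Node order is postorder (children before parents, root last), so the
    arrays can be swept bottom-up without extra bookkeeping.  Leaf labels
    are the species names; internal nodes get stable generated labels
    ``anc<postorder index>`` (deterministic for a given topology).
    """

    labels: list[str]
    parent: np.ndarray          # int, -1 at root
    left: np.ndarray            # int, -1 at leaves
    right: np.ndarray           # int, -1 at leaves
    nested: Nested = field(repr=False)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_nested(cls, t: Nested) -> "SpeciesTree":
        if not is_rooted_nested(t):
            raise TreeFormatError(
                "species tree must be rooted (bifurcating root); the given tree "
                "has a basal trifurcation — root it first"
            )
        t = canonical_nested(t)
        leaves = nested_leaves(t)
        if len(set(leaves)) != len(leaves):
            raise TreeFormatError("duplicate species labels in species tree")
        n = 2 * len(leaves) - 1
        labels: list[str] = [""] * n
        parent = np.full(n, -1, dtype=np.int64)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        counter = [0]

        def build(sub: Nested) -> int:
            if isinstance(sub, str):
                i = counter[0]
                counter[0] += 1
                labels[i] = sub
                return i
            a = build(sub[0])
            b = build(sub[1])
            i = counter[0]
            counter[0] += 1
            labels[i] = f"anc{i}"
            left[i], right[i] = a, b
            parent[a] = parent[b] = i
            return i

        build(t)
        return cls(labels=labels, parent=parent, left=left, right=right, nested=t)

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls.from_nested(parse_newick(text))

    # -- basic queries -------------------------------------------------------

    @property
    def n_branches(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_branches - 1

    def is_leaf(self, e: int) -> bool:
        return self.left[e] < 0

    @property
    def leaf_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.left < 0)

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.left >= 0)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[int(i)] for i in self.leaf_nodes]

    def node_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown species-tree label: {label!r}") from None

    def postorder(self) -> Iterator[int]:
        return iter(range(self.n_branches))  # construction order is postorder

    def clade_labels(self, e: int) -> frozenset[str]:
        if self.is_leaf(e):
            return frozenset([self.labels[e]])
        return self.clade_labels(int(self.left[e])) | self.clade_labels(int(self.right[e]))

    def clade_set(self) -> frozenset[frozenset[str]]:
        """Set of leaf-label clades, a canonical rooted-topology identifier."""
        return frozenset(self.clade_labels(e) for e in range(self.n_branches))

    def to_newick(self) -> str:
        return nested_to_newick(self.nested)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesTree):
            return NotImplemented
        return self.nested == other.nested

    def __hash__(self) -> int:
        return hash(self.nested)


def random_rooted_topology(labels: Sequence[str], rng: np.random.Generator) -> Nested:
    """Uniformly random rooted binary topology over ``labels``.

    Leaves are inserted in fixed (sorted) order; each insertion picks
    uniformly among the current tree's 2k−1 branches (root branch included),
    which yields the uniform distribution over rooted binary topologies.
    """
    labels = sorted(labels)
    if not labels:
        raise ValueError("need at least one label")
    tree: Nested = labels[0]
    for lab in labels[1:]:
        edges = _count_nodes(tree)
        k = int(rng.integers(edges))
        tree = _insert_at(tree, lab, [k])
    return canonical_nested(tree)


def _count_nodes(t: Nested) -> int:
    if isinstance(t, str):
        return 1
    return 1 + _count_nodes(t[0]) + _count_nodes(t[1])


def _insert_at(t: Nested, lab: str, k: list[int]) -> Nested:
    """Insert ``lab`` above the k-th node in preorder (mutating counter)."""
    if k[0] == 0:
        k[0] -= 1
        return (t, lab)
    k[0] -= 1
    if isinstance(t, str):
        return t
    a = _insert_at(t[0], lab, k)
    b = _insert_at(t[1], lab, k)
    return (a, b)
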