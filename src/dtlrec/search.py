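"""Rooted species-tree search by hill-climbing SPR moves.

The search walks the space of *rooted* topologies: pruning a subtree and
regrafting it onto any edge (including above the root) can relocate the
root, so root placement is estimated jointly with the topology.  Each
round enumerates the SPR neighborhood of the current tree in a
deterministic order and accepts the first strictly-improving neighbor
under the current DTL parameters; after every round with an acceptance
the parameters are re-optimized, and the search stops when no neighbor
improves the likelihood.

Starting trees: uniformly random rooted topologies, a user tree, or a
neighbor-joining tree built from average normalized topological
leaf-to-leaf distances pooled over the per-family majority-rule consensus
trees (multi-copy families contribute the minimum distance over gene-copy
pairs for each species pair), midpoint-rooted.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .ccp import CCPTable, TreeSample
from .likelihood import joint_likelihood
from .optimize import OptimizationConfig, OptimizationResult, optimize
from .rates import RateModel
from .trees import (
    Nested,
    SpeciesTree,
    canonical_nested,
    random_rooted_topology,
    rootings_of_unrooted,
)


class SearchError(RuntimeError):
    pass


@dataclass
class SearchConfig:
    start_method: str = "distance"      # random | distance | user
    user_tree: Optional[str] = None     # newick, for start_method="user"
    radius: Optional[int] = None        # None: unlimited ≤12 species, else 5
    reoptimize: bool = True
    seed: int = 0
    max_rounds: int = 100
    ll_tie_tol: float = 1e-9            # ΔlogL below this is a tie → reject
    opt_config: OptimizationConfig = field(default_factory=OptimizationConfig)

    def effective_radius(self, n_species: int) -> Optional[int]:
        if self.radius is not None:
            if self.radius < 1:
                raise SearchError("SPR radius must be >= 1")
            return self.radius
        return None if n_species <= 12 else 5


@dataclass
class RoundLog:
    round_index: int
    moves_tried: int
    accepted: Optional[str]  # newick of the accepted tree, None if round failed
    log_likelihood: float


@dataclass
class SearchResult:
    species_tree: SpeciesTree
    rate_model: RateModel
    log_likelihood: float
    rounds: list[RoundLog]
    accepted_lls: list[float]


# ---------------------------------------------------------------------------
# starting trees
# ---------------------------------------------------------------------------

def species_labels_of(families: Sequence[CCPTable]) -> list[str]:
    labels: set[str] = set()
    for ccp in families:
        labels.update(ccp.leaf_species.values())
    return sorted(labels)


def starting_tree(
    method: str,
    families: Sequence[CCPTable],
    seed: Optional[int] = None,
    user_tree: Optional[str] = None,
    samples: Optional[Sequence[TreeSample]] = None,
) -> SpeciesTree:
    """Build the initial rooted species tree for the SPR search."""
    species = species_labels_of(families)
    if len(species) < 3:
        raise SearchError("species-tree search needs at least 3 species")
    if method == "random":
        if seed is None:
            raise SearchError("random starting tree requires a seed")
        rng = np.random.default_rng(seed)
        return SpeciesTree.from_nested(random_rooted_topology(species, rng))
    if method == "user":
        if user_tree is None:
            raise SearchError("user starting tree requires a newick string")
        S = SpeciesTree.from_newick(user_tree)
        got = set(S.leaf_labels)
        want = set(species)
        if got != want:
            extra = sorted(got - want)
            missing = sorted(want - got)
            parts = []
            if missing:
                parts.append(f"missing species {missing}")
            if extra:
                parts.append(f"unknown species {extra}")
            raise SearchError("user tree leaf set mismatch: " + "; ".join(parts))
        return S
    if method == "distance":
        if samples is None:
            raise SearchError("distance starting tree requires the tree samples")
        return distance_starting_tree(families, samples)
    raise SearchError(f"unknown starting-tree method {method!r}")


def distance_starting_tree(
    families: Sequence[CCPTable], samples: Sequence[TreeSample]
) -> SpeciesTree:
    """Neighbor-joining on pooled consensus topological distances, midpoint-rooted."""
    species = species_labels_of(families)
    idx = {s: i for i, s in enumerate(species)}
    n = len(species)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    by_id = {c.family_id: c for c in families}
    for sample in samples:
        ccp = by_id.get(sample.family_id)
        if ccp is None:
            continue
        topo = _sample_consensus(sample)
        dist = _leaf_distances(topo)
        per_species: dict[tuple[int, int], float] = {}
        for (g1, g2), d in dist.items():
            s1, s2 = idx[ccp.leaf_species[g1]], idx[ccp.leaf_species[g2]]
            if s1 == s2:
                continue
            key = (min(s1, s2), max(s1, s2))
            if key not in per_species or d < per_species[key]:
                per_species[key] = d
        if not per_species:
            continue
        mx = max(per_species.values())
        for (s1, s2), d in per_species.items():
            acc[s1, s2] += d / mx
            acc[s2, s1] += d / mx
            cnt[s1, s2] += 1
            cnt[s2, s1] += 1
    fallback = 1.0  # pairs never co-observed sit at the normalized maximum
    with np.errstate(invalid="ignore"):
        D = np.where(cnt > 0, acc / np.maximum(cnt, 1), fallback)
    np.fill_diagonal(D, 0.0)

    csv = io.StringIO()
    csv.write("," + ",".join(species) + "\n")
    for i, s in enumerate(species):
        csv.write(s + "," + ",".join(f"{float(x):.12g}" for x in D[i]) + "\n")
    csv.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        csv, is_first_row_column_names=True, is_first_column_row_names=True,
        delimiter=",",
    )
    tree = pdm.nj_tree()
    tree.reroot_at_midpoint(update_bipartitions=False)
    nested = _rooted_nested_from_dendropy(tree, set(species))
    if not isinstance(nested, str) and len(nested) == 3:
        nested = rootings_of_unrooted(nested)[0]
    start = SpeciesTree.from_nested(nested)
    missing = set(species) - set(start.leaf_labels)
    if missing:
        raise SearchError(f"distance starting tree lost species {sorted(missing)}")
    return start


def _rooted_nested_from_dendropy(tree, species: set) -> Nested:
    """Nested topology of a dendropy tree, tolerating a leaf-labelled root.

    Midpoint rooting can land exactly on a node, leaving a species label on
    the seed node itself; that label is re-attached as an extra basal child
    so no taxon is lost.
    """
    seed = tree.seed_node
    kids = [_subtree_nested(c) for c in seed.child_nodes()]
    label = None
    if seed.taxon is not None and seed.taxon.label:
        label = seed.taxon.label.replace(" ", "_")
    elif seed.label and seed.label.replace(" ", "_") in species:
        label = seed.label.replace(" ", "_")
    if label is not None:
        kids.append(label)
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def _subtree_nested(node) -> Nested:
    children = node.child_nodes()
    if not children:
        if node.taxon is not None and node.taxon.label is not None:
            return node.taxon.label.replace(" ", "_")
        return node.label
    if len(children) != 2:
        raise SearchError("unexpected multifurcation in the NJ starting tree")
    return (_subtree_nested(children[0]), _subtree_nested(children[1]))


def _sample_consensus(sample: TreeSample) -> Nested:
    """Majority-rule (>50%) consensus topology of a tree sample (rooted form).

    Unrooted samples are consensed over an arbitrary consistent rooting of
    each tree; only leaf-to-leaf path lengths are consumed downstream, and
    those are root-invariant up to the ±1 edge resolution the normalized
    distances absorb.
    """
    leaf_order = sample.leaf_labels
    index = {lab: i for i, lab in enumerate(leaf_order)}
    counts: dict[int, int] = {}

    def walk(t) -> int:
        if isinstance(t, str):
            return 1 << index[t]
        m = 0
        for child in t:
            m |= walk(child)
        if m != (1 << len(leaf_order)) - 1 or len(t) == 2:
            counts[m] = counts.get(m, 0) + 1
        return m

    for t in sample.trees:
        walk(t)
    nsamp = len(sample.trees)
    kept = [m for m, c in counts.items() if 2 * c > nsamp]
    return _clades_to_tree(kept, leaf_order)


def _clades_to_tree(clades: list[int], leaf_order: list[str]):
    """Nest compatible clades into a (possibly multifurcating) topology."""
    full = (1 << len(leaf_order)) - 1
    items: list[int] = [1 << i for i in range(len(leaf_order))]
    items += [m for m in sorted(set(clades), key=lambda m: m.bit_count())
              if m != full and m.bit_count() > 1]
    children: dict[int, list[int]] = {full: []}
    for m in items:
        children[m] = []
    for m in items:
        parent = full
        best = full.bit_count() + 1
        for other in items:
            if other != m and (m & other) == m and other.bit_count() > m.bit_count():
                if other.bit_count() < best:
                    best = other.bit_count()
                    parent = other
        children[parent].append(m)

    def build(m: int):
        if m.bit_count() == 1:
            return leaf_order[m.bit_length() - 1]
        kids = [build(k) for k in children[m]]
        return tuple(kids) if len(kids) > 1 else kids[0]

    return build(full)


def _leaf_distances(topo) -> dict[tuple[str, str], int]:
    """Topological (edge-count) distances between all leaf pairs."""
    out: dict[tuple[str, str], int] = {}

    def walk(t) -> list[tuple[str, int]]:
        if isinstance(t, str):
            return [(t, 0)]
        lists = [walk(c) for c in t]
        for i in range(len(lists)):
            for j in range(i + 1, len(lists)):
                for (a, da) in lists[i]:
                    for (b, db) in lists[j]:
                        key = (a, b) if a < b else (b, a)
                        out[key] = da + db + 2
        return [(a, d + 1) for lst in lists for (a, d) in lst]

    walk(topo)
    return out


# ---------------------------------------------------------------------------
# SPR neighborhood
# ---------------------------------------------------------------------------

def spr_neighbors(S: SpeciesTree, radius: Optional[int] = None) -> list[SpeciesTree]:
    """All distinct rooted topologies within one SPR move of ``S``.

    A move prunes the subtree below any non-root node and regrafts it onto
    any edge of the remaining tree — the edge above the root included,
    which relocates the root.  ``radius`` bounds the edge-distance between
    the original attachment point and the regraft edge.  Deterministic
    enumeration order; the input tree never appears in its own neighborhood.
    """
    neighbors: list[SpeciesTree] = []
    seen: set[Nested] = {S.nested}
    n = S.n_branches

    for v in range(n - 1):  # every node except the root
        p = int(S.parent[v])
        sib = int(S.right[p]) if int(S.left[p]) == v else int(S.left[p])
        pruned_nested, sub_nested = _prune(S, v)
        # adjacency of the remaining tree for radius computation
        nodes, adj, node_of_old = _remaining_adjacency(S, v, p, sib)
        dist = _bfs(adj, node_of_old[sib])
        for u in nodes:  # regraft above u (u == remaining-root ⇒ new root)
            if u == node_of_old[sib]:
                continue  # recreates the input tree
            if radius is not None and dist[u] > radius:
                continue
            regrafted = _regraft(pruned_nested, sub_nested, u, nodes)
            key = canonical_nested(regrafted)
            if key in seen:
                continue
            seen.add(key)
            neighbors.append(SpeciesTree.from_nested(key))
    return neighbors


def _prune(S: SpeciesTree, v: int):
    """Remove subtree at node v; return (remaining nested with node-id tags, subtree nested)."""

    def conv(e: int):
        if S.is_leaf(e):
            return S.labels[e]
        return (conv(int(S.left[e])), conv(int(S.right[e])))

    sub = conv(v)

    def build(e: int):
        if e == v:
            return None
        if S.is_leaf(e):
            return (e, S.labels[e])
        a = build(int(S.left[e]))
        b = build(int(S.right[e]))
        if a is None:
            return b
        if b is None:
            return a
        return (e, (a, b))

    remaining = build(S.root)
    return remaining, sub


def _remaining_adjacency(S: SpeciesTree, v: int, p: int, sib: int):
    """Node list and undirected adjacency of the tree with subtree v removed.

    The pruned parent p is spliced out (sib takes its place).  Node ids are
    the original indices; ``node_of_old`` maps original ids to themselves
    or, for p, to sib.
    """
    drop = set()
    stack = [v]
    while stack:
        x = stack.pop()
        drop.add(x)
        if not S.is_leaf(x):
            stack.extend((int(S.left[x]), int(S.right[x])))
    drop.add(p)
    nodes = [e for e in range(S.n_branches) if e not in drop]
    adj: dict[int, list[int]] = {e: [] for e in nodes}

    def link(a: int, b: int) -> None:
        adj[a].append(b)
        adj[b].append(a)

    for e in nodes:
        pe = int(S.parent[e])
        if pe < 0:
            continue
        if pe == p:
            gp = int(S.parent[p])
            if gp >= 0:
                link(e, gp)
            continue
        if pe in adj:
            link(e, pe)
    node_of_old = {e: e for e in nodes}
    node_of_old[p] = sib
    return nodes, adj, node_of_old


def _bfs(adj: dict[int, list[int]], start: int) -> dict[int, int]:
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for x in frontier:
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    nxt.append(y)
        frontier = nxt
    return dist


def _regraft(remaining, sub, target: int, nodes):
    """Insert ``sub`` above node ``target`` in the id-tagged remaining tree."""

    def strip(t):
        if isinstance(t, str):
            return t
        tag, payload = t
        if isinstance(payload, str):
            return payload
        return (strip(payload[0]), strip(payload[1]))

    def walk(t):
        tag = t[0] if isinstance(t, tuple) else None
        if tag == target:
            return (strip(t), sub)
        if isinstance(t, str):
            return t
        tag, payload = t
        if isinstance(payload, str):
            return payload
        return (walk(payload[0]), walk(payload[1]))

    root_tag = remaining[0] if isinstance(remaining, tuple) else None
    if root_tag == target:
        return (strip(remaining), sub)
    return walk(remaining)


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------

def search(
    families: Sequence[CCPTable],
    cfg: Optional[SearchConfig] = None,
    rm0: Optional[RateModel] = None,
    start: Optional[SpeciesTree] = None,
    samples: Optional[Sequence[TreeSample]] = None,
) -> SearchResult:
    """Hill-climb rooted SPR moves until no move improves the joint likelihood."""
    cfg = cfg or SearchConfig()
    if start is None:
        start = starting_tree(
            cfg.start_method, families, seed=cfg.seed,
            user_tree=cfg.user_tree, samples=samples,
        )
    rm = rm0 or RateModel.global_rates(*cfg.opt_config.initial)
    current = start
    radius = cfg.effective_radius(len(current.leaf_labels))
    opt = cfg.opt_config

    ll = joint_likelihood(
        families, current, rm,
        condition_on_survival=opt.condition_on_survival, policy=opt.policy,
    )
    rounds: list[RoundLog] = []
    accepted_lls: list[float] = []
    for rnd in range(1, cfg.max_rounds + 1):
        tried = 0
        accepted = None
        for neighbor in spr_neighbors(current, radius):
            tried += 1
            try:
                cand = joint_likelihood(
                    families, neighbor, rm,
                    condition_on_survival=opt.condition_on_survival,
                    policy=opt.policy,
                )
            except Exception as exc:
                raise SearchError(
                    f"likelihood evaluation failed on candidate tree "
                    f"{neighbor.to_newick()}: {exc}"
                ) from exc
            if math.isfinite(cand) and cand > ll + cfg.ll_tie_tol:
                accepted = neighbor
                ll = cand
                break
        if accepted is None:
            rounds.append(RoundLog(rnd, tried, None, ll))
            break
        current = accepted
        accepted_lls.append(ll)
        if cfg.reoptimize:
            res: OptimizationResult = optimize(
                families, current, _with_initial(opt, rm)
            )
            rm, ll = res.rate_model, res.log_likelihood
        rounds.append(RoundLog(rnd, tried, current.to_newick(), ll))
    return SearchResult(
        species_tree=current,
        rate_model=rm,
        log_likelihood=ll,
        rounds=rounds,
        accepted_lls=accepted_lls,
    )


def _with_initial(opt: OptimizationConfig, rm: RateModel) -> OptimizationConfig:
    """Seed the per-round re-optimization at the current parameter values."""
    from dataclasses import replace

    if rm.mode == "global" and opt.mode == "global":
        return replace(opt, initial=rm.params[None])
    return opt
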