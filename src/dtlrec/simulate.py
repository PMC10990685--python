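"""Forward simulation of gene families under the undated DTL model.

These generators stand in for real data end to end: a family's history is
simulated forward along the species tree under the same per-branch event
distribution the likelihood uses, and the resulting (true) gene tree is
expanded into a pseudo-posterior sample by random NNI perturbation — a
desk-scale surrogate for the MCMC tree samples the method normally
consumes, with a single knob ``p`` controlling gene-tree uncertainty.

Simulation of one family: a single lineage originates on a uniformly
drawn branch; a lineage on branch *e* draws an event from
``(p_S, p_D, p_T, p_L)``.  Speciation descends into both children (at a
leaf branch, speciation means the gene is sampled); duplication forks on
the same branch; transfer keeps one copy and sends the other to a
uniformly drawn recipient branch; loss terminates the lineage.  Families
with no surviving gene are redrawn, mirroring the likelihood's survival
conditioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ccp import GeneSpeciesMap, TreeSample
from .rates import normalize_rates
from .sampling import GeneNode, ReconciliationEvent, ReconciledGeneTree
from .trees import Nested, SpeciesTree, canonical_nested, nested_leaves, random_rooted_topology


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for a simulated dataset."""

    n_species: int = 10
    species_tree: Optional[SpeciesTree] = None
    rates: tuple = (0.1, 0.05, 0.1)     # true (δ, τ, λ)
    n_families: int = 20
    sample_size: int = 100              # pseudo-posterior trees per family (m)
    perturbation: float = 0.1           # probability a sampled tree is NNI-perturbed (p)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates):
            raise SimulationError("rates must be >= 0")
        if self.sample_size < 1:
            raise SimulationError("sample_size must be >= 1")
        if not (0.0 <= self.perturbation <= 1.0):
            raise SimulationError("perturbation must be in [0, 1]")


@dataclass
class SimulatedFamily:
    family_id: str
    true_tree: Nested
    true_reconciliation: ReconciledGeneTree
    mapping: GeneSpeciesMap
    sample: Optional[TreeSample] = None
    rejected_draws: int = 0


@dataclass
class SimulatedDataset:
    species_tree: SpeciesTree
    families: list[SimulatedFamily]
    config: SimulationConfig


def simulate_family(
    S: SpeciesTree,
    rates: tuple,
    rng: np.random.Generator,
    family_id: str = "family",
    max_lineages: int = 10_000,
    reject_extinct: bool = True,
) -> SimulatedFamily:
    """Simulate one gene family; families with no surviving gene are redrawn."""
    import sys

    ep = normalize_rates(*rates, n_branches=S.n_branches)
    probs = np.stack([ep.p_S, ep.p_D, ep.p_T, ep.p_L], axis=1)
    N = S.n_branches
    rejected = 0
    # recursion depth is bounded by the lineage guard, which must fire first
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 3 * max_lineages))
    try:
        return _simulate_family_inner(
            S, probs, rng, family_id, max_lineages, reject_extinct, N
        )
    finally:
        sys.setrecursionlimit(old_limit)


def _simulate_family_inner(S, probs, rng, family_id, max_lineages, reject_extinct, N):
    rejected = 0
    while True:
        counter = [0]
        gene_counter = [0]
        mapping: dict[str, str] = {}

        def lineage(e: int) -> Optional[GeneNode]:
            counter[0] += 1
            if counter[0] > max_lineages:
                raise SimulationError(
                    "runaway family growth (>10000 lineages); "
                    "use smaller duplication/transfer rates"
                )
            ev = int(rng.choice(4, p=probs[e]))
            if ev == 0:  # speciation / observation
                if S.is_leaf(e):
                    gene_counter[0] += 1
                    label = f"{S.labels[e]}_g{gene_counter[0]}"
                    mapping[label] = S.labels[e]
                    return GeneNode(
                        clade=0,
                        terminal=ReconciliationEvent("leaf", e),
                        label=label,
                    )
                f, g = int(S.left[e]), int(S.right[e])
                a, b = lineage(f), lineage(g)
                if a is not None and b is not None:
                    return GeneNode(
                        clade=0,
                        terminal=ReconciliationEvent("S", e, child_branches=(f, g)),
                        children=[a, b],
                    )
                if a is None and b is None:
                    return None
                surv = a if a is not None else b
                lost = g if a is not None else f
                surv.chain.insert(0, ReconciliationEvent("SL", e, lost_branch=lost))
                return surv
            if ev == 1:  # duplication
                a, b = lineage(e), lineage(e)
                if a is not None and b is not None:
                    return GeneNode(
                        clade=0,
                        terminal=ReconciliationEvent("D", e, child_branches=(e, e)),
                        children=[a, b],
                    )
                if a is None and b is None:
                    return None
                surv = a if a is not None else b
                surv.chain.insert(0, ReconciliationEvent("D", e, lost_branch=e))
                return surv
            if ev == 2:  # transfer to a uniform recipient
                h = int(rng.integers(N))
                moved, stay = lineage(h), lineage(e)
                if moved is not None and stay is not None:
                    return GeneNode(
                        clade=0,
                        terminal=ReconciliationEvent(
                            "T", e, recipient=h, child_branches=(h, e)
                        ),
                        children=[moved, stay],
                    )
                if moved is None and stay is None:
                    return None
                if stay is not None:
                    stay.chain.insert(
                        0,
                        ReconciliationEvent(
                            "TL", e, recipient=h, survivor="donor", lost_branch=h
                        ),
                    )
                    return stay
                moved.chain.insert(
                    0,
                    ReconciliationEvent(
                        "TL", e, recipient=h, survivor="recipient", lost_branch=e
                    ),
                )
                return moved
            return None  # loss

        origin = int(rng.integers(N))
        root = lineage(origin)
        if root is None:
            if not reject_extinct:
                raise SimulationError(f"family {family_id}: extinct family")
            rejected += 1
            continue
        rec = ReconciledGeneTree(
            family_id=family_id,
            root=root,
            origination=origin,
            sample_index=0,
            log_weight=float("nan"),
            species_tree=S,
            ccp=None,
        )
        return SimulatedFamily(
            family_id=family_id,
            true_tree=rec.topology(),
            true_reconciliation=rec,
            mapping=GeneSpeciesMap(mapping),
            rejected_draws=rejected,
        )


def nni_perturb(tree: Nested, n_moves: int, rng: np.random.Generator) -> Nested:
    """Apply ``n_moves`` random nearest-neighbor interchanges to a rooted tree."""
    current = tree
    for _ in range(n_moves):
        edges = _internal_edges(current)
        if not edges:
            return current
        path, side = edges[int(rng.integers(len(edges)))]
        swap_child = int(rng.integers(2))
        current = _apply_nni(current, path, side, swap_child)
    return current


def _internal_edges(t: Nested, path: tuple = ()) -> list[tuple[tuple, int]]:
    """Edges (path-to-parent, child-side) whose both endpoints are internal."""
    out: list[tuple[tuple, int]] = []
    if isinstance(t, str):
        return out
    for side, child in enumerate(t):
        if not isinstance(child, str):
            out.append((path, side))
            out.extend(_internal_edges(child, path + (side,)))
    return out


def _apply_nni(t: Nested, path: tuple, side: int, swap_child: int) -> Nested:
    """Swap one child of the node at path+side with its sibling."""
    if path:
        head, rest = path[0], path[1:]
        kids = list(t)
        kids[head] = _apply_nni(kids[head], rest, side, swap_child)
        return tuple(kids)
    kids = list(t)
    inner = list(kids[side])
    sibling = kids[1 - side]
    moved = inner[swap_child]
    inner[swap_child] = sibling
    kids[1 - side] = moved
    kids[side] = tuple(inner)
    return tuple(kids)


def make_pseudo_sample(
    true_tree: Nested,
    m: int,
    p: float,
    rng: np.random.Generator,
    family_id: str = "family",
) -> TreeSample:
    """A pseudo-posterior: ``m`` trees, each NNI-perturbed with probability ``p``.

    The number of NNI moves of a perturbed tree is geometric with mean 1.5.
    Trees with fewer than four leaves admit no NNI; for those the true
    topology is replicated with a warning when ``p > 0``.
    """
    if m < 1:
        raise SimulationError("m must be >= 1")
    n_leaves = len(nested_leaves(true_tree))
    if n_leaves < 4 and p > 0:
        warnings.warn(
            f"family {family_id}: fewer than 4 leaves, NNI perturbation skipped",
            stacklevel=2,
        )
        return TreeSample(family_id, [true_tree] * m, rooted=True)
    trees: list[Nested] = []
    for _ in range(m):
        if p > 0 and rng.random() < p:
            n_moves = int(rng.geometric(1.0 / 1.5))
            trees.append(canonical_nested(nni_perturb(true_tree, n_moves, rng)))
        else:
            trees.append(true_tree)
    return TreeSample(family_id, trees, rooted=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a full dataset: species tree, families, pseudo-samples."""
    rng = np.random.default_rng(config.seed)
    S = config.species_tree
    if S is None:
        labels = [f"S{i + 1}" for i in range(config.n_species)]
        S = SpeciesTree.from_nested(random_rooted_topology(labels, rng))
    families = []
    width = max(3, len(str(config.n_families)))
    for i in range(config.n_families):
        fid = f"fam{i + 1:0{width}d}"
        fam = simulate_family(S, config.rates, rng, family_id=fid)
        fam.sample = make_pseudo_sample(
            fam.true_tree, config.sample_size, config.perturbation, rng, family_id=fid
        )
        families.append(fam)
    return SimulatedDataset(species_tree=S, families=families, config=config)
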