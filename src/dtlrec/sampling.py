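"""Stochastic backtracking of reconciled gene trees and event summaries.

Once the (clade, branch) dynamic program is finalized, reconciled gene
trees are drawn proportional to their joint likelihood by retracing the
table from the root cell: the origination branch is drawn proportional to
``O(e)·P(c_root, e)``, and at every state ``(c, e)`` one of the
recursion's additive terms is drawn proportional to its contribution to
``P(c, e)``, recursing into the chosen sub-states.  Each sample is an
explicit gene tree whose nodes carry chains of reconciliation events.

Event bookkeeping conventions (used by the summary tables):

* ``S``  — speciation at an internal branch, both sides surviving;
* ``SL`` — speciation where one side left no sampled descendant: counts
  one speciation on the branch and one loss on the extinct child branch;
* ``D``  — duplication; a duplication whose second copy died counts one
  duplication and one loss on the same branch;
* ``T``  — transfer with both copies surviving, counted on the donor;
* ``TL`` — transfer with exactly one surviving copy, counted on the
  donor, with a loss on whichever branch the dead copy occupied;
* ancestral gene copies on a branch = number of gene lineages whose event
  chain visits that branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ccp import CCPTable, tree_probability
from .likelihood import CladeProbabilityMatrix
from .trees import Nested, SpeciesTree, canonical_nested

EVENT_KINDS = ("S", "SL", "D", "T", "TL", "L", "leaf")


class SamplingError(RuntimeError):
    pass


@dataclass
class ReconciliationEvent:
    kind: str
    branch: int                       # species-tree node index
    recipient: Optional[int] = None   # T/TL: branch the transferred copy went to
    survivor: Optional[str] = None    # TL: "donor" | "recipient"
    lost_branch: Optional[int] = None # SL / duplication-loss / TL: where the lost copy died
    child_branches: Optional[tuple] = None  # terminal S/D/T: branches of the two children

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.recipient is None) == (self.kind in ("T", "TL")):
            raise ValueError(f"recipient must be set iff kind is T/TL (got {self.kind})")


@dataclass
class GeneNode:
    """One gene-tree node: a chain of single-survivor events, then a terminal."""

    clade: int
    chain: list[ReconciliationEvent] = field(default_factory=list)
    terminal: Optional[ReconciliationEvent] = None
    children: list["GeneNode"] = field(default_factory=list)
    label: Optional[str] = None  # gene leaf label at leaves


@dataclass
class ReconciledGeneTree:
    family_id: str
    root: GeneNode
    origination: int
    sample_index: int
    log_weight: float
    species_tree: SpeciesTree = field(repr=False)
    ccp: CCPTable = field(repr=False)

    def topology(self) -> Nested:
        def conv(n: GeneNode) -> Nested:
            if not n.children:
                return n.label
            return (conv(n.children[0]), conv(n.children[1]))

        return canonical_nested(conv(self.root))

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def family_rng(master_seed: int, family_index: int) -> np.random.Generator:
    """Per-family random stream: the family index is mixed into the master
    seed through a SeedSequence spawn key, so results do not depend on the
    order in which families are processed."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(family_index,))
    )


def sample_reconciliations(
    matrix: CladeProbabilityMatrix,
    ccp: Optional[CCPTable] = None,
    r: int = 100,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    max_states: int = 1_000_000,
) -> list[ReconciledGeneTree]:
    """Draw ``r`` reconciled gene trees proportional to their joint likelihood."""
    ccp = ccp or matrix.ccp
    S = matrix.species_tree
    if r < 1:
        raise ValueError("r must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)

    N = S.n_branches
    left, right = S.left, S.right
    ep = matrix.ep
    extended = matrix.representation == "extended"
    P = matrix.P
    Pbar = matrix.Pbar
    if extended:
        import decimal

        D = decimal.Decimal
        pS = [D(float(x)) for x in ep.p_S]
        pD = [D(float(x)) for x in ep.p_D]
        pT = [D(float(x)) for x in ep.p_T]
        Evec = [D(float(x)) for x in matrix.extinction.E]
        Ebar = sum(Evec, D(0)) / D(N)
        two = D(2)
    else:
        pS, pD, pT = ep.p_S, ep.p_D, ep.p_T
        Evec = matrix.extinction.E
        Ebar = matrix.extinction.mean
        two = 2.0
    leaf_node = {
        ccp.leaf_mask(g): S.node_of(sp) for g, sp in ccp.leaf_species.items()
    }

    root_mask = ccp.root_clade
    rootvec = P[root_mask]
    root_weights = np.array([float(x) for x in rootvec]) if extended else np.asarray(rootvec, dtype=float)
    if extended:
        # rescale before float conversion so tiny magnitudes survive
        mx = max(rootvec)
        if mx > 0:
            root_weights = np.array([float(x / mx) for x in rootvec])
    tot = root_weights.sum()
    if tot <= 0.0:
        raise SamplingError(
            f"family {ccp.family_id}: zero-probability root, nothing to sample"
        )
    root_probs = root_weights / tot

    def pick(weights: list[float], rnd: float) -> int:
        total = sum(weights)
        x = rnd * total
        acc = 0.0
        for i, w in enumerate(weights):
            acc += w
            if x <= acc:
                return i
        return len(weights) - 1

    def norm_weights(raw) -> list[float]:
        if not extended:
            return raw
        mx = max(raw)
        if mx == 0:
            return [0.0 for _ in raw]
        return [float(w / mx) for w in raw]

    def sample_one(index: int) -> ReconciledGeneTree:
        states = [0]
        logw = [math.log(1.0 / N)]

        e0 = int(rng.choice(N, p=root_probs))
        logw[0] += _logf(P[root_mask][e0])

        def descend(c: int, e: int) -> GeneNode:
            node = GeneNode(clade=c)
            while True:
                states[0] += 1
                if states[0] > max_states:
                    raise SamplingError("reconciliation sampling exceeded state guard")
                choices = []  # (weight, tag, payload)
                pc = P[c]
                pbc = Pbar[c]
                is_leaf_clade = c.bit_count() == 1
                if is_leaf_clade and leaf_node[c] == e:
                    choices.append((pS[e], "leaf", None))
                ls, rs = int(left[e]), int(right[e])
                for (m1, m2, q) in ccp.splits.get(c, ()):
                    if extended:
                        q = D(q)
                    P1, P2 = P[m1], P[m2]
                    if ls >= 0:
                        choices.append((q * pS[e] * P1[ls] * P2[rs], "S", (m1, ls, m2, rs)))
                        choices.append((q * pS[e] * P1[rs] * P2[ls], "S", (m1, rs, m2, ls)))
                    choices.append((q * pD[e] * P1[e] * P2[e], "D", (m1, m2)))
                    choices.append((q * pT[e] * Pbar[m1] * P2[e], "T", (m1, m2)))
                    choices.append((q * pT[e] * P1[e] * Pbar[m2], "T", (m2, m1)))
                if ls >= 0:
                    choices.append((pS[e] * pc[ls] * Evec[rs], "SL", (ls, rs)))
                    choices.append((pS[e] * pc[rs] * Evec[ls], "SL", (rs, ls)))
                choices.append((two * pD[e] * Evec[e] * pc[e], "DL", None))
                choices.append((pT[e] * Ebar * pc[e], "TLstay", None))
                choices.append((pT[e] * Evec[e] * pbc, "TLmove", None))

                raw = [float(w) if not extended else w for (w, _, _) in choices]
                weights = norm_weights(raw)
                if sum(weights) <= 0.0:
                    raise SamplingError(
                        f"family {ccp.family_id}: dead end at clade {c:#x} branch {e}"
                    )
                k = pick(weights, float(rng.random()))
                w, tag, payload = choices[k]
                logw[0] += _logf(w)

                if tag == "leaf":
                    node.terminal = ReconciliationEvent("leaf", e)
                    node.label = ccp.leaf_order[c.bit_length() - 1]
                    return node
                if tag == "S":
                    m1, e1, m2, e2 = payload
                    node.terminal = ReconciliationEvent("S", e, child_branches=(e1, e2))
                    logw[0] -= _logf(P[m1][e1]) + _logf(P[m2][e2])
                    node.children = [descend(m1, e1), descend(m2, e2)]
                    return node
                if tag == "D":
                    m1, m2 = payload
                    node.terminal = ReconciliationEvent("D", e, child_branches=(e, e))
                    logw[0] -= _logf(P[m1][e]) + _logf(P[m2][e])
                    node.children = [descend(m1, e), descend(m2, e)]
                    return node
                if tag == "T":
                    m_moved, m_stay = payload
                    h = _pick_branch(P[m_moved], rng, extended)
                    node.terminal = ReconciliationEvent(
                        "T", e, recipient=h, child_branches=(h, e)
                    )
                    logw[0] -= _logf(P[m_moved][h]) + _logf(P[m_stay][e])
                    node.children = [descend(m_moved, h), descend(m_stay, e)]
                    return node
                if tag == "SL":
                    surv, lost = payload
                    node.chain.append(
                        ReconciliationEvent("SL", e, lost_branch=lost)
                    )
                    logw[0] -= _logf(pc[surv])
                    e = surv
                    continue
                if tag == "DL":
                    node.chain.append(ReconciliationEvent("D", e, lost_branch=e))
                    logw[0] -= _logf(pc[e])
                    continue
                if tag == "TLstay":
                    h = _pick_branch(Evec, rng, extended)
                    node.chain.append(
                        ReconciliationEvent(
                            "TL", e, recipient=h, survivor="donor", lost_branch=h
                        )
                    )
                    logw[0] -= _logf(pc[e])
                    continue
                # TLmove
                h = _pick_branch(pc, rng, extended)
                node.chain.append(
                    ReconciliationEvent(
                        "TL", e, recipient=h, survivor="recipient", lost_branch=e
                    )
                )
                logw[0] -= _logf(pc[h])
                e = h

        root = descend(root_mask, e0)
        return ReconciledGeneTree(
            family_id=ccp.family_id,
            root=root,
            origination=e0,
            sample_index=index,
            log_weight=logw[0],
            species_tree=S,
            ccp=ccp,
        )

    return [sample_one(i) for i in range(r)]


def _logf(x) -> float:
    """log of a float or Decimal, -inf-safe."""
    import decimal

    if isinstance(x, decimal.Decimal):
        if x <= 0:
            return -math.inf
        with decimal.localcontext(decimal.Context(prec=40, Emin=-999_999_999, Emax=999_999_999)):
            return float(x.ln())
    x = float(x)
    return math.log(x) if x > 0.0 else -math.inf


def _pick_branch(vec, rng: np.random.Generator, extended: bool) -> int:
    if extended:
        mx = max(vec)
        arr = np.array([float(v / mx) for v in vec]) if mx > 0 else np.zeros(len(vec))
    else:
        arr = np.asarray(vec, dtype=float)
    tot = arr.sum()
    if tot <= 0:
        raise SamplingError("no feasible recipient branch")
    return int(rng.choice(len(arr), p=arr / tot))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNode:
    support: float
    children: list["ConsensusNode"] = field(default_factory=list)
    label: Optional[str] = None

    def to_newick(self, _root: bool = True) -> str:
        if not self.children:
            s = self.label or ""
        else:
            inner = ",".join(c.to_newick(_root=False) for c in self.children)
            s = f"({inner}){self.support:g}"
        return s + ";" if _root else s


def majority_consensus(samples: Sequence[ReconciledGeneTree]) -> ConsensusNode:
    """Rooted majority-rule (>50%) consensus of the sampled gene trees.

    Supports are sample fractions; clades at exactly 50% are excluded, so
    the consensus may contain polytomies.
    """
    if not samples:
        raise ValueError("majority_consensus of empty sample list")
    leaf_order = samples[0].ccp.leaf_order
    index = {lab: i for i, lab in enumerate(leaf_order)}
    n = len(samples)
    counts: dict[int, int] = {}

    def walk(t: Nested) -> int:
        if isinstance(t, str):
            return 1 << index[t]
        m = walk(t[0]) | walk(t[1])
        counts[m] = counts.get(m, 0) + 1
        return m

    for s in samples:
        topo = s.topology()
        if sorted(s.ccp.leaf_order) != leaf_order:
            raise ValueError("samples with differing leaf sets")
        walk(topo)

    full = (1 << len(leaf_order)) - 1
    kept = {m: c for m, c in counts.items() if 2 * c > n and m != full}
    nodes: dict[int, ConsensusNode] = {
        1 << i: ConsensusNode(support=1.0, label=lab) for i, lab in enumerate(leaf_order)
    }
    root = ConsensusNode(support=1.0)
    order = sorted(kept, key=lambda m: m.bit_count())
    for m in order:
        nodes[m] = ConsensusNode(support=kept[m] / n)
    # attach every node (leaves and kept clades) to its smallest strict superset
    masks = sorted(nodes, key=lambda m: m.bit_count())
    for m in masks:
        parent = None
        best = None
        for other in masks:
            if other != m and (m & other) == m and other.bit_count() > m.bit_count():
                if best is None or other.bit_count() < best:
                    best = other.bit_count()
                    parent = other
        (nodes[parent] if parent is not None else root).children.append(nodes[m])
    return root


# ---------------------------------------------------------------------------
# event and transfer summaries
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["S", "D", "T", "TL", "L", "copies"]


def summarize_events(
    samples: Sequence[ReconciledGeneTree], S: Optional[SpeciesTree] = None
) -> pd.DataFrame:
    """Mean per-branch event counts and ancestral gene copies over samples."""
    if not samples:
        raise ValueError("summarize_events of empty sample list")
    S = S or samples[0].species_tree
    N = S.n_branches
    acc = np.zeros((N, len(EVENT_COLUMNS)))
    col = {name: j for j, name in enumerate(EVENT_COLUMNS)}

    for sample in samples:
        # copies: lineage arrivals per branch
        def arrivals(node: GeneNode, e: int) -> None:
            acc[e, col["copies"]] += 1
            cur = e
            for ev in node.chain:
                if ev.kind == "SL":
                    acc[cur, col["S"]] += 1
                    acc[ev.lost_branch, col["L"]] += 1
                    cur = _sl_survivor(S, cur, ev.lost_branch)
                    acc[cur, col["copies"]] += 1
                elif ev.kind == "D":
                    acc[cur, col["D"]] += 1
                    acc[ev.lost_branch, col["L"]] += 1
                elif ev.kind == "TL":
                    acc[cur, col["TL"]] += 1
                    acc[ev.lost_branch, col["L"]] += 1
                    if ev.survivor == "recipient":
                        cur = ev.recipient
                        acc[cur, col["copies"]] += 1
            term = node.terminal
            if term.kind == "S":
                acc[cur, col["S"]] += 1
            elif term.kind == "D":
                acc[cur, col["D"]] += 1
            elif term.kind == "T":
                acc[cur, col["T"]] += 1
            if term.child_branches is not None:
                arrivals(node.children[0], term.child_branches[0])
                arrivals(node.children[1], term.child_branches[1])

        arrivals(sample.root, sample.origination)

    acc /= len(samples)
    return pd.DataFrame(acc, index=list(S.labels), columns=EVENT_COLUMNS)


def _sl_survivor(S: SpeciesTree, e: int, lost: int) -> int:
    ls, rs = int(S.left[e]), int(S.right[e])
    return rs if lost == ls else ls


@dataclass
class TransferTable:
    """Sampled transfer counts by (donor, recipient) species pair."""

    per_family: dict[str, pd.DataFrame]
    total: pd.DataFrame


def _transfer_frame(counter: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    return pd.DataFrame(
        [(d, r, c) for (d, r), c in rows], columns=["donor", "recipient", "count"]
    )


def summarize_transfers(
    samples_by_family: dict[str, Sequence[ReconciledGeneTree]],
) -> TransferTable:
    """Transfer counts (T and TL events) per family and summed over families,
    sorted by count descending with ties broken by donor then recipient."""
    per_family = {}
    total: dict[tuple[str, str], int] = {}
    for fid in sorted(samples_by_family):
        counter: dict[tuple[str, str], int] = {}
        for sample in samples_by_family[fid]:
            S = sample.species_tree
            for node in sample.iter_nodes():
                events = list(node.chain) + ([node.terminal] if node.terminal else [])
                for ev in events:
                    if ev.kind in ("T", "TL"):
                        key = (S.labels[ev.branch], S.labels[ev.recipient])
                        counter[key] = counter.get(key, 0) + 1
        per_family[fid] = _transfer_frame(counter)
        for key, c in counter.items():
            total[key] = total.get(key, 0) + c
    return TransferTable(per_family=per_family, total=_transfer_frame(total))


def query_families_by_event(
    event_tables: dict[str, pd.DataFrame],
    transfers: Optional[TransferTable] = None,
    event: Optional[tuple[str, str]] = None,
    transfer_pair: Optional[tuple[str, str]] = None,
) -> list[str]:
    """Family ids whose summaries match a filter.

    ``event=(kind, species)`` selects families with a positive mean count of
    that event kind on that species branch; ``transfer_pair=(donor,
    recipient)`` selects families with at least one sampled transfer between
    the pair.  Exactly one filter must be given.
    """
    if (event is None) == (transfer_pair is None):
        raise ValueError("give exactly one of event= or transfer_pair=")
    out = []
    if event is not None:
        kind, species = event
        if kind not in EVENT_COLUMNS:
            raise ValueError(f"unknown event kind {kind!r}")
        for fid in sorted(event_tables):
            table = event_tables[fid]
            if species not in table.index:
                raise KeyError(f"unknown species label {species!r}")
            if table.loc[species, kind] > 0:
                out.append(fid)
        return out
    donor, recipient = transfer_pair
    if transfers is None:
        raise ValueError("transfer_pair filter needs transfers=")
    for fid in sorted(transfers.per_family):
        df = transfers.per_family[fid]
        hit = df[(df["donor"] == donor) & (df["recipient"] == recipient)]
        if len(hit) and hit["count"].sum() > 0:
            out.append(fid)
    return out
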