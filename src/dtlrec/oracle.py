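"""Independent truncated-history oracle for the reconciliation likelihood.

The dynamic program in :mod:`dtlrec.likelihood` sums over *all*
reconciled histories, resolving the infinite chains of
duplication–loss / transfer–loss events analytically.  This module
computes the same quantity by explicit enumeration of histories with at
most ``max_events`` non-speciation events (duplications, transfers,
losses — in surviving and in extinct sub-lineages alike), grouped by
their exact event count.  Histories with k events are enumerated by a
direct recursion on the generative process: a history of the lineage is
its first event followed by independent sub-histories, whose event
counts add up; no fixed-point solve and no self-reference resolution is
involved, so the result is an algorithmically independent lower bound.

The truncated sum is non-decreasing in ``max_events`` and converges to
the dynamic-programming value from below, which makes it a sharp
correctness oracle on small instances.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .ccp import CCPTable
from .likelihood import ExtinctionVector, MappingError, _check_mapping
from .rates import EventProbabilities
from .trees import SpeciesTree


class OracleSizeError(ValueError):
    pass


def truncated_event_tables(
    ccp: CCPTable,
    S: SpeciesTree,
    ep: EventProbabilities,
    max_events: int,
    size_guard: bool = True,
):
    """Per-(clade, branch) probabilities split by exact non-speciation event count.

    Returns ``(F, ext)`` where ``F[mask]`` has shape ``(N, max_events+1)``:
    ``F[mask][e, k]`` is the probability that a single lineage entering
    branch ``e`` produces exactly clade ``mask`` through a history with
    exactly ``k`` non-speciation events; ``ext[e, k]`` likewise for
    extinction.  Summing over ``k ≤ K`` gives the truncated lower bound of
    the dynamic program's ``P(c, e)``.
    """
    if size_guard and (len(S.leaf_labels) > 4 or ccp.n_leaves > 4 or max_events > 3):
        raise OracleSizeError(
            "oracle guard: intended for ≤4 species, ≤4 genes, ≤3 events "
            "(pass size_guard=False to override)"
        )
    ep.validate()
    leaf_to_node = _check_mapping(ccp, S)
    N = S.n_branches
    K = max_events
    left, right = S.left, S.right
    pS, pD, pT, pL = ep.p_S, ep.p_D, ep.p_T, ep.p_L

    # extinction by exact event count
    ext = np.zeros((N, K + 1))
    extbar = np.zeros(K + 1)
    for k in range(1, K + 1):
        for e in range(N):  # postorder: children before parents
            v = pL[e] if k == 1 else 0.0
            for i in range(k):  # i + j = k - 1
                j = k - 1 - i
                v += pD[e] * ext[e, i] * ext[e, j]
                v += pT[e] * ext[e, i] * extbar[j]
            ls = left[e]
            if ls >= 0:
                rs = right[e]
                for i in range(k + 1):  # i + j = k
                    v += pS[e] * ext[ls, i] * ext[rs, k - i]
            ext[e, k] = v
        extbar[k] = ext[:, k].mean()

    F: dict[int, np.ndarray] = {}
    Fbar: dict[int, np.ndarray] = {}
    for c in ccp.clades_by_size():
        A = np.zeros((N, K + 1))
        Fbar[c] = np.zeros(K + 1)
        if c.bit_count() == 1:
            node = leaf_to_node[ccp.leaf_order[c.bit_length() - 1]]
            A[node, 0] = pS[node]
        splits = ccp.splits.get(c, ())
        for k in range(K + 1):
            for e in range(N):
                v = A[e, k]
                ls, rs = left[e], right[e]
                for (m1, m2, q) in splits:
                    F1, F2 = F[m1], F[m2]
                    term = 0.0
                    if ls >= 0:
                        for i in range(k + 1):
                            term += pS[e] * (
                                F1[ls, i] * F2[rs, k - i] + F1[rs, i] * F2[ls, k - i]
                            )
                    for i in range(k):  # i + j = k - 1
                        j = k - 1 - i
                        term += pD[e] * F1[e, i] * F2[e, j]
                        term += pT[e] * (
                            Fbar[m1][i] * F2[e, j] + F1[e, i] * Fbar[m2][j]
                        )
                    v += q * term
                if ls >= 0:
                    # speciation-loss: ext[·, 0] = 0, so only i < k contributes
                    for i in range(k + 1):
                        j = k - i
                        v += pS[e] * (
                            A[ls, i] * ext[rs, j] + ext[ls, i] * A[rs, j]
                        )
                for i in range(k):  # duplication-loss / transfer-loss, one event spent
                    j = k - 1 - i
                    v += pD[e] * 2.0 * ext[e, i] * A[e, j]
                    v += pT[e] * (extbar[i] * A[e, j] + ext[e, i] * Fbar[c][j])
                A[e, k] = v
            Fbar[c][k] = A[:, k].mean()
        F[c] = A
    return F, ext


def brute_force_likelihood(
    ccp: CCPTable,
    S: SpeciesTree,
    ep: EventProbabilities,
    E: Optional[ExtinctionVector] = None,
    max_events: int = 3,
    size_guard: bool = True,
) -> float:
    """Unconditioned family likelihood truncated at ``max_events`` DTL events.

    ``Σ_e O(e) · Σ_{k ≤ max_events} F(c_root, e, k)`` with uniform
    origination.  Monotone non-decreasing in ``max_events`` and a lower
    bound on (converging to) the dynamic-programming likelihood.  The
    extinction vector argument is accepted for signature parity with the
    dynamic program but is not used: the oracle derives its own truncated
    extinction terms.
    """
    F, _ext = truncated_event_tables(ccp, S, ep, max_events, size_guard=size_guard)
    root = F[ccp.root_clade]
    return float(root.sum()) / S.n_branches
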