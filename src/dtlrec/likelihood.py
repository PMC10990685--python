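"""Amalgamated reconciliation likelihood under the undated DTL model.

For one gene family compressed into a :class:`~dtlrec.ccp.CCPTable`, the
probability of the family given a rooted species tree ``S`` is the sum,
over every rooted gene tree that can be amalgamated from the observed
clades and over every reconciliation of that tree with ``S``, of the
tree's amalgamation probability times the reconciliation probability.
A dynamic program over (clade, species branch) pairs evaluates this sum
exactly for the clade set of the table.

Per species branch *e* the normalized event distribution is
``(p_S, p_D, p_T, p_L)``; transfers pick their recipient uniformly among
all N branches.  Writing ``E(e)`` for the probability that a single gene
copy entering branch *e* leaves no sampled descendant (the extinction
probability) and ``P(c, e)`` for the probability that it generates
exactly the observed clade ``c``, the recursions are

    E(e) = p_L + p_D·E(e)² + p_T·E(e)·Ē + [e internal] p_S·E(f)·E(g)

    P(c,e) = [c a gene leaf mapped to leaf e]·p_S
           + Σ_splits q(c1,c2|c) · ( [e internal] p_S·(P(c1,f)P(c2,g) + P(c1,g)P(c2,f))
                                     + p_D·P(c1,e)P(c2,e)
                                     + p_T·(P̄(c1)P(c2,e) + P(c1,e)P̄(c2)) )
           + [e internal] p_S·(P(c,f)E(g) + E(f)P(c,g))
           + p_D·2E(e)·P(c,e)
           + p_T·(Ē·P(c,e) + E(e)·P̄(c))

with f, g the children of e and the overbar denoting the average over all
branches (the uniform transfer recipient).  The self-referential terms
(a surviving lineage staying on its branch after a duplication–loss or
transfer–loss) are resolved analytically: collecting their coefficient
``b(e) = 2·p_D·E(e) + p_T·Ē`` gives ``P(c,e) = a(e)/(1 − b(e))``, with a
few refresh rounds for the coupling through P̄(c).

The family likelihood is ``P(A|S) = Σ_e O(e)·P(c_root, e)`` with a uniform
origination distribution ``O(e) = 1/N``, optionally conditioned on the
family being observed at all (division by ``1 − Σ_e O(e)·E(e)``).

Families whose dynamic-programming table underflows IEEE double range are
transparently recomputed with extended-precision decimal arithmetic, so a
family with any positive-probability history never reports a zero
likelihood.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ccp import CCPTable
from .rates import EventProbabilities, RateModel, normalize_rates
from .trees import SpeciesTree


class NumericalError(RuntimeError):
    pass


class MappingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# extinction
# ---------------------------------------------------------------------------

@dataclass
class ExtinctionVector:
    """Per-branch extinction probabilities with fixed-point diagnostics."""

    E: np.ndarray
    iterations: int
    residual: float
    converged: bool

    @property
    def mean(self) -> float:
        return float(self.E.mean())


def compute_extinction(
    ep: EventProbabilities,
    S: SpeciesTree,
    tol: float = 1e-13,
    max_iter: int = 10_000,
) -> ExtinctionVector:
    """Minimal fixed point of the extinction recursion.

    Synchronous iteration from E ≡ 0; starting at zero selects the minimal
    (probabilistically meaningful) fixed point.  At a leaf branch the
    speciation term contributes nothing: speciation at a leaf means the
    gene is sampled, which is not extinction.
    """
    ep.validate()
    N = ep.n_branches
    internal = S.internal_nodes
    lf = S.left[internal]
    rg = S.right[internal]
    E = np.zeros(N)
    residual = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        Ebar = E.mean()
        new = ep.p_L + ep.p_D * E * E + ep.p_T * E * Ebar
        new[internal] += ep.p_S[internal] * E[lf] * E[rg]
        residual = float(np.max(np.abs(new - E)))
        E = new
        if residual < tol:
            break
    return ExtinctionVector(E=E, iterations=it, residual=residual, converged=residual < tol)


# ---------------------------------------------------------------------------
# precision policy
# ---------------------------------------------------------------------------

@dataclass
class PrecisionPolicy:
    """When and how to fall back to extended-precision arithmetic.

    A family is recomputed with decimal arithmetic when any positive DP
    cell drops below ``underflow_threshold`` in the standard (float64)
    representation — close enough to the 1e-308 floor that the remaining
    headroom cannot be trusted for sums of products.
    """

    underflow_threshold: float = 1e-280
    decimal_precision: int = 40
    allow_extended: bool = True
    force_extended: bool = False


# ---------------------------------------------------------------------------
# clade-probability DP
# ---------------------------------------------------------------------------

@dataclass
class CladeProbabilityMatrix:
    """DP table P(clade, branch) plus transfer averages, for one family.

    ``P`` maps clade masks to per-branch vectors (float arrays in the
    standard representation, lists of :class:`decimal.Decimal` in the
    extended one); ``Pbar`` holds the per-clade branch averages.
    The object keeps references to the inputs it was computed from so the
    stochastic backtracking sampler can retrace it.
    """

    family_id: str
    P: dict
    Pbar: dict
    representation: str  # "standard" | "extended"
    ccp: CCPTable = field(repr=False)
    species_tree: SpeciesTree = field(repr=False)
    ep: EventProbabilities = field(repr=False)
    extinction: ExtinctionVector = field(repr=False)

    def root_vector(self) -> Sequence:
        return self.P[self.ccp.root_clade]


def _check_mapping(ccp: CCPTable, S: SpeciesTree) -> dict[str, int]:
    species_nodes = {lab: int(i) for i, lab in zip(S.leaf_nodes, S.leaf_labels)}
    leaf_to_node: dict[str, int] = {}
    for gene, sp in ccp.leaf_species.items():
        if sp not in species_nodes:
            raise MappingError(
                f"family {ccp.family_id}: gene {gene!r} maps to species {sp!r} "
                "absent from the species tree"
            )
        leaf_to_node[gene] = species_nodes[sp]
    return leaf_to_node


def clade_probabilities(
    ccp: CCPTable,
    S: SpeciesTree,
    ep: EventProbabilities,
    E: ExtinctionVector,
    policy: Optional[PrecisionPolicy] = None,
    refresh_rounds: int = 4,
    refresh_tol: float = 1e-12,
) -> CladeProbabilityMatrix:
    """Evaluate the (clade, branch) dynamic program for one family.

    Clades are processed in order of increasing size.  If any cell
    underflows the standard representation the whole family is recomputed
    in extended precision (see :class:`PrecisionPolicy`).
    """
    policy = policy or PrecisionPolicy()
    leaf_to_node = _check_mapping(ccp, S)
    if policy.force_extended:
        return _dp_extended(ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol)

    matrix, underflowed = _dp_float(
        ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol
    )
    if underflowed and policy.allow_extended:
        return _dp_extended(ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol)
    return matrix


try:  # optional JIT of the inner DP; the pure-Python path is the reference
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _dp_kernel(
        N, left, right, leaf_node, split_start, split_c1, split_c2, split_q,
        pS, pD, pT, E, Ebar, rounds, tol,
    ):  # pragma: no cover - exercised via clade_probabilities
        C = leaf_node.shape[0]
        P = np.zeros((C, N))
        Pbar = np.zeros(C)
        b = 2.0 * pD * E + pT * Ebar
        denom = 1.0 - b
        for e in range(N):
            if denom[e] <= 0.0:
                return P, Pbar, 0.0, 1
        minpos = 1e300
        new = np.empty(N)
        base = np.empty(N)
        for i in range(C):
            for e in range(N):
                base[e] = 0.0
            if leaf_node[i] >= 0:
                base[leaf_node[i]] = pS[leaf_node[i]]
            for j in range(split_start[i], split_start[i + 1]):
                c1 = split_c1[j]
                c2 = split_c2[j]
                q = split_q[j]
                for e in range(N):
                    t = pD[e] * P[c1, e] * P[c2, e] + pT[e] * (
                        Pbar[c1] * P[c2, e] + P[c1, e] * Pbar[c2]
                    )
                    ls = left[e]
                    if ls >= 0:
                        rs = right[e]
                        t += pS[e] * (
                            P[c1, ls] * P[c2, rs] + P[c1, rs] * P[c2, ls]
                        )
                    base[e] += q * t
            Pbc = 0.0
            for _r in range(rounds):
                for e in range(N):
                    a = base[e] + pT[e] * E[e] * Pbc
                    ls = left[e]
                    if ls >= 0:
                        rs = right[e]
                        a += pS[e] * (new[ls] * E[rs] + E[ls] * new[rs])
                    new[e] = a / denom[e]
                newbar = 0.0
                maxdelta = 0.0
                for e in range(N):
                    newbar += new[e]
                    d = abs(new[e] - P[i, e])
                    if d > maxdelta:
                        maxdelta = d
                    P[i, e] = new[e]
                newbar /= N
                Pbc = newbar
                if maxdelta <= tol * max(newbar, 1e-300):
                    break
            Pbar[i] = Pbc
            for e in range(N):
                v = P[i, e]
                if 0.0 < v < minpos:
                    minpos = v
        return P, Pbar, minpos, 0

except Exception:  # numba unavailable: fall back to the pure path
    _dp_kernel = None


def _ccp_arrays(ccp):
    """Flattened clade/split index arrays of a CCP table (cached)."""
    cached = getattr(ccp, "_dp_arrays", None)
    if cached is not None:
        return cached
    order = ccp.clades_by_size()
    index = {m: i for i, m in enumerate(order)}
    C = len(order)
    leaf_label = np.full(C, -1, dtype=np.int64)
    starts = np.zeros(C + 1, dtype=np.int64)
    c1s: list[int] = []
    c2s: list[int] = []
    qs: list[float] = []
    for i, m in enumerate(order):
        if m.bit_count() == 1:
            leaf_label[i] = m.bit_length() - 1
        for (m1, m2, q) in ccp.splits.get(m, ()):
            c1s.append(index[m1])
            c2s.append(index[m2])
            qs.append(q)
        starts[i + 1] = len(qs)
    arrays = (
        order,
        leaf_label,
        starts,
        np.asarray(c1s, dtype=np.int64),
        np.asarray(c2s, dtype=np.int64),
        np.asarray(qs, dtype=float),
    )
    ccp._dp_arrays = arrays
    return arrays


def _dp_float_jit(ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol):
    order, leaf_label, starts, c1s, c2s, qs = _ccp_arrays(ccp)
    N = S.n_branches
    leaf_node = np.array(
        [
            leaf_to_node[ccp.leaf_order[j]] if j >= 0 else -1
            for j in leaf_label
        ],
        dtype=np.int64,
    )
    tau_active = bool(np.any(ep.p_T > 0.0))
    rounds = refresh_rounds if tau_active else 1
    Pmat, Pbar_arr, minpos, status = _dp_kernel(
        N, S.left, S.right, leaf_node, starts, c1s, c2s, qs,
        ep.p_S, ep.p_D, ep.p_T, E.E, E.mean, rounds, refresh_tol,
    )
    if status == 1:
        raise NumericalError(
            f"family {ccp.family_id}: self-referential solve diverges "
            "(duplication/transfer-loss coefficient reaches 1)"
        )
    P = {m: Pmat[i] for i, m in enumerate(order)}
    Pbar = {m: float(Pbar_arr[i]) for i, m in enumerate(order)}
    matrix = CladeProbabilityMatrix(
        family_id=ccp.family_id,
        P=P,
        Pbar=Pbar,
        representation="standard",
        ccp=ccp,
        species_tree=S,
        ep=ep,
        extinction=E,
    )
    return matrix, bool(minpos < policy.underflow_threshold)


def _dp_float(ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol):
    if _dp_kernel is not None:
        return _dp_float_jit(
            ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol
        )
    return _dp_float_pure(
        ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol
    )


def _dp_float_pure(ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol):
    N = S.n_branches
    internal = S.internal_nodes
    lf = S.left[internal]
    rg = S.right[internal]
    Evec = E.E
    Ebar = E.mean
    b = 2.0 * ep.p_D * Evec + ep.p_T * Ebar
    denom = 1.0 - b
    if np.any(denom <= 0.0):
        raise NumericalError(
            f"family {ccp.family_id}: self-referential solve diverges "
            "(duplication/transfer-loss coefficient reaches 1)"
        )
    tau_active = bool(np.any(ep.p_T > 0.0))
    rounds = refresh_rounds if tau_active else 1

    left = S.left
    right = S.right
    P: dict[int, np.ndarray] = {}
    Pbar: dict[int, float] = {}
    underflowed = False

    for c in ccp.clades_by_size():
        base = np.zeros(N)
        if c.bit_count() == 1:
            gene = ccp.leaf_order[c.bit_length() - 1]
            node = leaf_to_node[gene]
            base[node] += ep.p_S[node]
        for (m1, m2, q) in ccp.splits.get(c, ()):
            P1, P2 = P[m1], P[m2]
            base += q * (ep.p_D * P1 * P2 + ep.p_T * (Pbar[m1] * P2 + P1 * Pbar[m2]))
            base[internal] += q * ep.p_S[internal] * (
                P1[lf] * P2[rg] + P1[rg] * P2[lf]
            )
        Pc = np.zeros(N)
        Pbc = 0.0
        for _ in range(rounds):
            new = np.empty(N)
            for e in range(N):  # postorder: children precede parents
                a = base[e] + ep.p_T[e] * Evec[e] * Pbc
                ls = left[e]
                if ls >= 0:
                    rs = right[e]
                    a += ep.p_S[e] * (new[ls] * Evec[rs] + Evec[ls] * new[rs])
                new[e] = a / denom[e]
            newbar = float(new.mean())
            delta = float(np.max(np.abs(new - Pc)))
            Pc, Pbc = new, newbar
            if delta <= refresh_tol * max(newbar, 1e-300):
                break
        P[c] = Pc
        Pbar[c] = Pbc
        pos = Pc[Pc > 0.0]
        if pos.size and float(pos.min()) < policy.underflow_threshold:
            underflowed = True

    matrix = CladeProbabilityMatrix(
        family_id=ccp.family_id,
        P=P,
        Pbar=Pbar,
        representation="standard",
        ccp=ccp,
        species_tree=S,
        ep=ep,
        extinction=E,
    )
    return matrix, underflowed


def _dp_extended(ccp, S, ep, E, leaf_to_node, policy, refresh_rounds, refresh_tol):
    """Same recursion with decimal arithmetic (huge exponent range)."""
    ctx = decimal.Context(prec=policy.decimal_precision, Emin=-999_999_999, Emax=999_999_999)
    with decimal.localcontext(ctx):
        D = lambda x: +decimal.Decimal(float(x))
        zero = D(0)
        one = D(1)

        N = S.n_branches
        left = S.left
        right = S.right
        pS = [D(x) for x in ep.p_S]
        pD = [D(x) for x in ep.p_D]
        pT = [D(x) for x in ep.p_T]
        Evec = [D(x) for x in E.E]
        Ebar = sum(Evec, zero) / D(N)
        b = [2 * pD[e] * Evec[e] + pT[e] * Ebar for e in range(N)]
        denom = [one - be for be in b]
        if any(d <= 0 for d in denom):
            raise NumericalError(
                f"family {ccp.family_id}: self-referential solve diverges"
            )
        tau_active = any(x > 0 for x in pT)
        rounds = refresh_rounds if tau_active else 1

        P: dict[int, list] = {}
        Pbar: dict[int, decimal.Decimal] = {}
        ND = D(N)
        tol = D(refresh_tol)
        for c in ccp.clades_by_size():
            base = [zero] * N
            if c.bit_count() == 1:
                gene = ccp.leaf_order[c.bit_length() - 1]
                node = leaf_to_node[gene]
                base[node] = pS[node]
            for (m1, m2, q) in ccp.splits.get(c, ()):
                qd = D(q)
                P1, P2 = P[m1], P[m2]
                Pb1, Pb2 = Pbar[m1], Pbar[m2]
                for e in range(N):
                    term = pD[e] * P1[e] * P2[e] + pT[e] * (Pb1 * P2[e] + P1[e] * Pb2)
                    ls = left[e]
                    if ls >= 0:
                        rs = right[e]
                        term += pS[e] * (P1[ls] * P2[rs] + P1[rs] * P2[ls])
                    base[e] += qd * term
            Pc = [zero] * N
            Pbc = zero
            for _ in range(rounds):
                new = [zero] * N
                for e in range(N):
                    a = base[e] + pT[e] * Evec[e] * Pbc
                    ls = left[e]
                    if ls >= 0:
                        rs = right[e]
                        a += pS[e] * (new[ls] * Evec[rs] + Evec[ls] * new[rs])
                    new[e] = a / denom[e]
                newbar = sum(new, zero) / ND
                delta = max(abs(x - y) for x, y in zip(new, Pc))
                Pc, Pbc = new, newbar
                if delta <= tol * max(newbar, D(1e-300)):
                    break
            P[c] = Pc
            Pbar[c] = Pbc

    return CladeProbabilityMatrix(
        family_id=ccp.family_id,
        P=P,
        Pbar=Pbar,
        representation="extended",
        ccp=ccp,
        species_tree=S,
        ep=ep,
        extinction=E,
    )


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

@dataclass
class FamilyLikelihood:
    family_id: str
    log_likelihood: float
    origination: str = "uniform"
    conditioning_constant: float = 1.0
    representation: str = "standard"
    diagnostic: str = ""


def family_likelihood(
    matrix: CladeProbabilityMatrix,
    E: Optional[ExtinctionVector] = None,
    condition_on_survival: bool = True,
) -> FamilyLikelihood:
    """P(family | S) from the finalized DP matrix, in log space.

    Origination is uniform over branches; with survival conditioning the
    likelihood is divided by the probability that an originated family
    leaves any sampled gene at all, ``1 − Ē``.
    """
    E = E or matrix.extinction
    root = matrix.root_vector()
    N = matrix.species_tree.n_branches
    cond = 1.0 - E.mean if condition_on_survival else 1.0
    if cond <= 0.0:
        raise NumericalError(
            f"family {matrix.family_id}: survival probability is zero; "
            "cannot condition on survival"
        )
    if matrix.representation == "standard":
        lik = float(np.sum(root)) / N
        if lik <= 0.0:
            return FamilyLikelihood(
                family_id=matrix.family_id,
                log_likelihood=-math.inf,
                conditioning_constant=cond,
                diagnostic=(
                    f"family {matrix.family_id}: zero amalgamated likelihood "
                    "on this species tree"
                ),
            )
        ll = math.log(lik) - math.log(cond)
        return FamilyLikelihood(
            family_id=matrix.family_id, log_likelihood=ll, conditioning_constant=cond
        )
    # extended representation
    ctx = decimal.Context(prec=40, Emin=-999_999_999, Emax=999_999_999)
    with decimal.localcontext(ctx):
        total = sum(root, decimal.Decimal(0))
        if total <= 0:
            return FamilyLikelihood(
                family_id=matrix.family_id,
                log_likelihood=-math.inf,
                conditioning_constant=cond,
                representation="extended",
                diagnostic=(
                    f"family {matrix.family_id}: zero amalgamated likelihood "
                    "on this species tree"
                ),
            )
        ll = float((total / decimal.Decimal(N)).ln()) - math.log(cond)
    return FamilyLikelihood(
        family_id=matrix.family_id,
        log_likelihood=ll,
        conditioning_constant=cond,
        representation="extended",
    )


def compute_family(
    ccp: CCPTable,
    S: SpeciesTree,
    delta,
    tau,
    lam,
    condition_on_survival: bool = True,
    policy: Optional[PrecisionPolicy] = None,
    extinction: Optional[ExtinctionVector] = None,
) -> tuple[FamilyLikelihood, CladeProbabilityMatrix]:
    """Convenience pipeline: normalize rates → extinction → DP → likelihood."""
    ep = normalize_rates(delta, tau, lam, n_branches=S.n_branches)
    E = extinction or compute_extinction(ep, S)
    matrix = clade_probabilities(ccp, S, ep, E, policy=policy)
    fl = family_likelihood(matrix, E, condition_on_survival=condition_on_survival)
    return fl, matrix


def joint_likelihood(
    families: Sequence[CCPTable],
    S: SpeciesTree,
    rm: RateModel,
    condition_on_survival: bool = True,
    policy: Optional[PrecisionPolicy] = None,
    return_details: bool = False,
):
    """Joint log-likelihood of the species tree: sum over families.

    Families are independent given (S, rates); the reduction order is fixed
    (sorted family ids) so the total is bitwise identical no matter how the
    input list is ordered or scheduled.
    """
    ids = [c.family_id for c in families]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family ids")
    by_id = {c.family_id: c for c in families}
    cache: dict = {}
    per_family: dict[str, FamilyLikelihood] = {}
    total = 0.0
    for fid in sorted(by_id):
        ccp = by_id[fid]
        key = rm.block_key(fid)
        if key not in cache:
            ep = rm.event_probabilities(fid, S)
            E = compute_extinction(ep, S)
            cache[key] = (ep, E)
        ep, E = cache[key]
        try:
            matrix = clade_probabilities(ccp, S, ep, E, policy=policy)
            fl = family_likelihood(matrix, E, condition_on_survival=condition_on_survival)
        except (NumericalError, MappingError) as exc:
            raise type(exc)(f"family {fid}: {exc}") from exc
        per_family[fid] = fl
        total += fl.log_likelihood
    if return_details:
        return total, per_family
    return total
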