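"""Duplication–transfer–loss rate parameterizations and event probabilities.

The undated DTL model attaches to every species-tree branch *e* a
duplication probability δ(e), a transfer probability τ(e) and a loss
probability λ(e).  Normalizing against the implicit speciation weight 1
turns them into a proper per-branch event distribution::

    (p_S, p_D, p_T, p_L) = (1, δ, τ, λ) / (1 + δ + τ + λ)

Three parameterization modes are supported: ``global`` (one (δ, τ, λ)
triple shared by all families and branches — 3 free parameters),
``per_family`` (one triple per gene family — 3K free parameters for K
families) and ``per_species`` (one triple per user-defined species
grouping — 3n free parameters for n groupings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .trees import SpeciesTree

MODES = ("global", "per_family", "per_species")
RATE_NAMES = ("delta", "tau", "lam")


class RateError(ValueError):
    pass


@dataclass
class EventProbabilities:
    """Normalized per-branch event distribution (p_S + p_D + p_T + p_L = 1)."""

    p_S: np.ndarray
    p_D: np.ndarray
    p_T: np.ndarray
    p_L: np.ndarray

    @property
    def n_branches(self) -> int:
        return len(self.p_S)

    def validate(self, tol: float = 1e-12) -> None:
        total = self.p_S + self.p_D + self.p_T + self.p_L
        if np.any(np.abs(total - 1.0) > tol):
            raise RateError("event probabilities do not sum to 1 per branch")


def normalize_rates(delta, tau, lam, n_branches: Optional[int] = None) -> EventProbabilities:
    """Turn raw (δ, τ, λ) per branch into normalized event probabilities.

    Scalars are broadcast over ``n_branches`` branches.
    """
    if np.isscalar(delta) and n_branches is not None:
        delta = np.full(n_branches, float(delta))
        tau = np.full(n_branches, float(tau))
        lam = np.full(n_branches, float(lam))
    delta = np.asarray(delta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    lam = np.asarray(lam, dtype=float)
    for name, arr in (("delta", delta), ("tau", tau), ("lam", lam)):
        if not np.all(np.isfinite(arr)):
            raise RateError(f"non-finite {name} rate")
        if np.any(arr < 0):
            raise RateError(f"negative {name} rate")
    total = 1.0 + delta + tau + lam
    return EventProbabilities(
        p_S=1.0 / total, p_D=delta / total, p_T=tau / total, p_L=lam / total
    )


@dataclass
class RateModel:
    """(δ, τ, λ) blocks organized by parameterization mode.

    ``params`` maps a block key to a (δ, τ, λ) triple:

    * ``global`` mode: single key ``None``;
    * ``per_family``: keys are family ids;
    * ``per_species``: keys are grouping ids, with ``grouping`` mapping
      species labels (and optionally internal node labels) to grouping ids.
      An internal branch not listed explicitly inherits the grouping held
      by the majority of its descendant species (ties broken by
      lexicographically smallest grouping id).
    """

    mode: str
    params: dict = field(default_factory=dict)
    grouping: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise RateError(f"unknown rate mode {self.mode!r}")
        if self.mode == "per_species" and self.grouping is None:
            raise RateError("per_species mode requires a species grouping map")
        for key, triple in self.params.items():
            d, t, l = triple
            for v in (d, t, l):
                if not np.isfinite(v) or v < 0:
                    raise RateError(f"invalid rate triple for block {key!r}: {triple}")

    # -- constructors --------------------------------------------------------

    @classmethod
    def global_rates(cls, delta: float, tau: float, lam: float) -> "RateModel":
        return cls(mode="global", params={None: (delta, tau, lam)})

    @classmethod
    def per_family(cls, triples: Mapping[str, tuple]) -> "RateModel":
        return cls(mode="per_family", params=dict(triples))

    @classmethod
    def per_species(
        cls, triples: Mapping[str, tuple], grouping: Mapping[str, str]
    ) -> "RateModel":
        return cls(mode="per_species", params=dict(triples), grouping=grouping)

    # -- resolution ----------------------------------------------------------

    def block_key(self, family_id: str):
        """Hashable key identifying the parameter block a family resolves to.

        Families sharing a key share event probabilities and extinction
        vectors, which callers may cache.
        """
        if self.mode == "per_family":
            return ("per_family", family_id)
        if self.mode == "global":
            return ("global",)
        return ("per_species",)

    def triple_for(self, family_id: str):
        """The (δ, τ, λ) triple of a family in global/per_family mode."""
        if self.mode == "global":
            return self.params[None]
        if self.mode == "per_family":
            try:
                return self.params[family_id]
            except KeyError:
                raise RateError(f"no rate block for family {family_id!r}") from None
        raise RateError("triple_for is undefined in per_species mode")

    def branch_grouping(self, S: SpeciesTree) -> list[str]:
        """Grouping id per species-tree branch (per_species mode)."""
        if self.grouping is None:
            raise RateError("no grouping map")
        out: list[str] = [""] * S.n_branches
        for e in S.postorder():
            label = S.labels[e]
            if label in self.grouping:
                out[e] = self.grouping[label]
            elif S.is_leaf(e):
                raise RateError(f"species {label!r} missing from grouping map")
            else:
                votes: dict[str, int] = {}
                for lab in S.clade_labels(e):
                    g = self.grouping.get(lab)
                    if g is None:
                        raise RateError(f"species {lab!r} missing from grouping map")
                    votes[g] = votes.get(g, 0) + 1
                best = max(votes.values())
                out[e] = min(g for g, v in votes.items() if v == best)
        return out

    def rates_for(self, family_id: str, S: SpeciesTree):
        """Per-branch (δ, τ, λ) arrays for one family on species tree ``S``."""
        n = S.n_branches
        if self.mode in ("global", "per_family"):
            d, t, l = self.triple_for(family_id)
            return (np.full(n, float(d)), np.full(n, float(t)), np.full(n, float(l)))
        gids = self.branch_grouping(S)
        delta = np.empty(n)
        tau = np.empty(n)
        lam = np.empty(n)
        for e, gid in enumerate(gids):
            try:
                d, t, l = self.params[gid]
            except KeyError:
                raise RateError(f"no rate block for grouping {gid!r}") from None
            delta[e], tau[e], lam[e] = d, t, l
        return delta, tau, lam

    def event_probabilities(self, family_id: str, S: SpeciesTree) -> EventProbabilities:
        return normalize_rates(*self.rates_for(family_id, S))


def read_grouping_file(path) -> dict[str, str]:
    """Read a TSV ``species<TAB>grouping`` file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RateError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out[parts[0].strip()] = parts[1].strip()
    return out
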