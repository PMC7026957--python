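"""Pareto domination, Fonseca–Fleming ranking, selection, elite archive.

All objectives are minimized.  A vector u2 dominates u1 when it is
"partially less than" u1: u2_i <= u1_i for every objective and strictly
less for at least one.  The Fonseca–Fleming rank of a population member is
simply the number of members that dominate it, so the Pareto front is the
rank-0 set and ranks run from 0 to k-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from molcycle.chem_eval import MoleculeRecord, ObjectiveVector

logger = logging.getLogger(__name__)


def dominates(u2, u1) -> bool:
    """True iff u2 dominates u1 under minimization (partially-less-than)."""
    u2 = np.asarray(u2, dtype=float)
    u1 = np.asarray(u1, dtype=float)
    if u2.shape != u1.shape:
        raise ValueError("objective vectors have different dimensions")
    return bool(np.all(u2 <= u1) and np.any(u2 < u1))


def fonseca_fleming_rank(objectives) -> np.ndarray:
    """Rank each member by the number of members dominating it.

    ``objectives`` is a (k, n) array-like of minimization vectors.  The
    O(k^2) pairwise count is computed row by row with vectorized
    comparisons; the result is deterministic and order-equivariant.
    """
    obj = np.asarray(
        [o.as_array() if isinstance(o, ObjectiveVector) else o for o in objectives],
        dtype=float,
    )
    if obj.ndim != 2 or obj.shape[0] == 0:
        raise ValueError("need a non-empty list of objective vectors")
    k = obj.shape[0]
    ranks = np.empty(k, dtype=np.int64)
    for i in range(k):
        le = np.all(obj <= obj[i], axis=1)
        lt = np.any(obj < obj[i], axis=1)
        ranks[i] = int(np.count_nonzero(le & lt))
    return ranks


@dataclass
class RankedPopulation:
    """Molecules paired with their objective vectors and Fonseca–Fleming ranks."""

    members: list[MoleculeRecord]
    objectives: np.ndarray  # (k, n_objectives)
    ranks: np.ndarray = field(init=False)

    def __post_init__(self):
        self.objectives = np.asarray(self.objectives, dtype=float)
        if len(self.members) != self.objectives.shape[0]:
            raise ValueError("members and objectives are misaligned")
        self.ranks = fonseca_fleming_rank(self.objectives)

    @property
    def k(self) -> int:
        return len(self.members)

    @classmethod
    def from_records(cls, records: list[MoleculeRecord]) -> "RankedPopulation":
        obj = np.array([r.descriptors.as_array() for r in records])
        return cls(members=records, objectives=obj)


def _take_best(ranks: np.ndarray, quota: int, rng) -> np.ndarray:
    """Indices of the ``quota`` best-ranked members.

    Whole rank classes are taken in increasing rank order; the boundary rank
    that does not fit entirely is filled by a uniform seeded draw.
    """
    order_ranks = np.sort(np.unique(ranks))
    chosen: list[np.ndarray] = []
    n_taken = 0
    for r in order_ranks:
        idx = np.flatnonzero(ranks == r)
        if n_taken + idx.size <= quota:
            chosen.append(idx)
            n_taken += idx.size
            if n_taken == quota:
                break
        else:
            need = quota - n_taken
            chosen.append(rng.choice(idx, size=need, replace=False))
            n_taken = quota
            break
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


def select_best_half(pop: RankedPopulation, seed: int = 0) -> list[MoleculeRecord]:
    """The floor(k/2) best-ranked members, boundary ties broken at random.

    The tie-break uses its own seeded stream so selection is reproducible
    independently of the sampler.
    """
    if pop.k < 2:
        raise ValueError("population must have at least 2 members")
    quota = pop.k // 2
    rng = np.random.default_rng(seed)
    idx = _take_best(pop.ranks, quota, rng)
    return [pop.members[i] for i in idx]


@dataclass
class Archive:
    """Capped running set of the best molecules across cycle iterations."""

    cap: int = 10_000
    members: list[MoleculeRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.cap < 1:
            raise ValueError("archive cap must be positive")

    @property
    def canonical_set(self) -> set[str]:
        return {m.canonical_smiles for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


def update_archive(
    archive: Archive, newcomers: list[MoleculeRecord], seed: int = 0
) -> Archive:
    """Merge newcomers into the archive, re-rank, and trim to the cap.

    Newcomers duplicating an archived canonical SMILES are dropped first;
    the merged set is re-ranked with the Fonseca–Fleming rule and the best
    ``cap`` members are kept, boundary ties broken by a seeded random draw.
    """
    known = archive.canonical_set
    fresh = []
    for rec in newcomers:
        if rec.canonical_smiles not in known:
            known.add(rec.canonical_smiles)
            fresh.append(rec)
    union = archive.members + fresh
    if len(union) <= archive.cap:
        return Archive(cap=archive.cap, members=union)
    pop = RankedPopulation.from_records(union)
    rng = np.random.default_rng(seed)
    idx = _take_best(pop.ranks, archive.cap, rng)
    return Archive(cap=archive.cap, members=[union[i] for i in idx])
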