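"""Pareto-front extraction and ranking of migration histories.

A candidate history survives Pareto filtering iff no other candidate is at
least as good in all three parsimony metrics (m, c, s) and strictly better
in one. Candidates with identical metrics but distinct labelings are
incomparable and all survive: they are genuinely different hypotheses of
spread. Ranking under a parsimony model sorts by the weighted score
p = wm*m + wc*c + ws*s; exact ties are broken by the genetic-distance
score, then the organotropism score, then a canonical labeling key, so the
order is deterministic and input-order invariant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .clone_tree import MigrationHistory
from .parsimony import ParsimonyModel, parsimony_score
from .priors import (GeneticDistanceMatrix, OrganotropismVector,
                     genetic_distance_score, organotropism_score)


@dataclass
class RankedSolution:
    rank: int
    history: MigrationHistory
    parsimony: float
    genetic_distance: float
    organotropism: Optional[float]

    @property
    def metrics(self) -> Tuple[int, int, int]:
        return self.history.metrics


def dominates(a: Tuple[int, int, int], b: Tuple[int, int, int]) -> bool:
    """True iff a is <= b componentwise and < in at least one metric."""
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def pareto_filter(candidates: Sequence[MigrationHistory]) -> List[MigrationHistory]:
    if not candidates:
        raise ValueError("empty candidate set")
    out = []
    for h in candidates:
        if not any(dominates(g.metrics, h.metrics) for g in candidates):
            out.append(h)
    return out


def _canonical_hash(history: MigrationHistory) -> str:
    return hashlib.sha256(repr(history.key()).encode()).hexdigest()


def rank_front(front: Sequence[MigrationHistory], model: ParsimonyModel,
               D: Optional[GeneticDistanceMatrix] = None,
               o: Optional[OrganotropismVector] = None,
               primary: Optional[str] = None) -> List[RankedSolution]:
    """Order a Pareto front under a parsimony model; priors break ties."""
    scored = []
    for h in front:
        p = parsimony_score(h.metrics, model)
        gd = genetic_distance_score(h, D) if D is not None else 0.0
        org = (organotropism_score(h, o, primary)
               if o is not None and primary is not None else None)
        scored.append((p, gd, org if org is not None else 0.0,
                       _canonical_hash(h), h, org))
    scored.sort(key=lambda t: t[:4])
    return [RankedSolution(rank=i + 1, history=h, parsimony=p,
                           genetic_distance=gd, organotropism=org)
            for i, (p, gd, _, _, h, org) in enumerate(scored)]
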