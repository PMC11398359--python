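"""Scoring inferred migration histories against a known ground truth.

Two F1 scores are used. The migration-graph score compares the multisets
of site-to-site migration edges: per ordered site pair the intersection
contributes min(multiplicity in G, multiplicity in G*), recall divides by
|E(G*)|, precision by |E(G)|. The seeding-clone score compares the sets of
subclones (mutation sets) attached to clones incident to migration edges —
by default the *source* clone u of each migration edge (the convention of
prior benchmarks), optionally the target clone v (a harder identification
problem since the target's private mutations may be unobserved).
"""

from __future__ import annotations

from typing import FrozenSet, Set, Tuple

from .clone_tree import CLONE, MigrationGraph, MigrationHistory
from .proportions import CloneMutationMatrix

SOURCE = "source"
TARGET = "target"


def _f1(recall: float, precision: float) -> float:
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


def migration_graph_f1(G: MigrationGraph, G_star: MigrationGraph,
                       ) -> Tuple[float, float, float]:
    """(recall, precision, F1) of G against the true graph G*."""
    total_true = G_star.total_multiplicity()
    if total_true == 0:
        raise ValueError("ground-truth migration graph has no edges (recall undefined)")
    inter = sum(min(n, G_star.multiplicity.get(pair, 0))
                for pair, n in G.multiplicity.items())
    recall = inter / total_true
    total_inf = G.total_multiplicity()
    precision = inter / total_inf if total_inf else 0.0
    return recall, precision, _f1(recall, precision)


def seeding_clone_sets(history: MigrationHistory, B: CloneMutationMatrix,
                       convention: str = SOURCE) -> Set[FrozenSet[str]]:
    """Subclones (mutation sets) of the clones incident to migration edges."""
    if convention not in (SOURCE, TARGET):
        raise ValueError(f"unknown convention {convention!r}")
    tree = history.tree
    out: Set[FrozenSet[str]] = set()
    for u, v in history.migration_edges:
        node = u if convention == SOURCE else v
        while tree.node_kind.get(node, CLONE) != CLONE:
            node = tree.parent[node]     # witness/resolver carry parent's mutations
        out.add(B.mutations_of(node))
    return out


def seeding_clone_f1(inferred: MigrationHistory, B_inferred: CloneMutationMatrix,
                     truth: MigrationHistory, B_truth: CloneMutationMatrix,
                     convention: str = SOURCE) -> Tuple[float, float, float]:
    """(recall, precision, F1) over seeding subclones, matched by mutation set."""
    ci = seeding_clone_sets(inferred, B_inferred, convention)
    ct = seeding_clone_sets(truth, B_truth, convention)
    inter = len(ci & ct)
    recall = inter / len(ct) if ct else 1.0
    precision = inter / len(ci) if ci else 1.0
    return recall, precision, _f1(recall, precision)
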