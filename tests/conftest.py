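"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: metrics
are recounted edge by edge, comigration grouping is found by exhaustive
partitioning, and Pareto fronts / minimum migration counts come from full
enumeration over all labelings.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pytest

from seedtrace import CloneTree, VertexLabeling, build_tree
from seedtrace.clone_tree import migration_edges_of


# ---------------------------------------------------------------------------
# independent per-edge metric oracle


def oracle_metrics(tree: CloneTree, labeling: VertexLabeling,
                   rule: str = "machina") -> Tuple[int, int, int]:
    """(m, c, s) recomputed naively, independent of seedtrace.parsimony."""
    mig = [(u, v) for u, v in tree.edges() if labeling[u] != labeling[v]]
    m = len(mig)
    s = len({labeling[u] for u, _ in mig})
    if rule == "simple":
        c = len({(labeling[u], labeling[v]) for u, v in mig})
        return m, c, s
    c = oracle_comigrations(tree, labeling, mig)
    return m, c, s


def _is_ancestor_edge(tree: CloneTree, e1, e2) -> bool:
    """True iff e1 lies on the root path of e2 (strictly above it)."""
    node = e2[0]
    while node != tree.root:
        parent = tree.parent[node]
        if (parent, node) == e1:
            return True
        node = parent
    return False


def oracle_comigrations(tree: CloneTree, labeling: VertexLabeling,
                        mig: Sequence[Tuple[str, str]]) -> int:
    """Minimum grouping by exhaustive partition search per site pair.

    Same-pair migration edges may share a group unless one is an ancestor of
    the other; the answer is summed over site pairs.
    """
    by_pair: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    for u, v in mig:
        by_pair.setdefault((labeling[u], labeling[v]), []).append((u, v))
    total = 0
    for edges in by_pair.values():
        n = len(edges)
        if n == 1:
            total += 1
            continue
        ordered = {(i, j) for i in range(n) for j in range(n) if i != j
                   and (_is_ancestor_edge(tree, edges[i], edges[j])
                        or _is_ancestor_edge(tree, edges[j], edges[i]))}
        best = n
        for assignment in itertools.product(range(n), repeat=n):
            groups: Dict[int, List[int]] = {}
            for idx, g in enumerate(assignment):
                groups.setdefault(g, []).append(idx)
            if any((i, j) in ordered for g in groups.values()
                   for i in g for j in g if i < j):
                continue
            best = min(best, len(groups))
        total += best
    return total


# ---------------------------------------------------------------------------
# exhaustive enumeration oracles


def enumerate_labelings(tree: CloneTree, sites: Sequence[str], primary: str,
                        fix_root: bool = True):
    free = [n for n in tree.nodes()
            if n not in tree.witness_site and not (fix_root and n == tree.root)]
    fixed = dict(tree.witness_site)
    if fix_root:
        fixed[tree.root] = primary
    for combo in itertools.product(sites, repeat=len(free)):
        lab = dict(fixed)
        lab.update(zip(free, combo))
        yield VertexLabeling(lab)


def oracle_front(tree: CloneTree, sites: Sequence[str], primary: str,
                 fix_root: bool = True) -> Set[Tuple[int, int, int]]:
    """Exact Pareto-optimal (m, c, s) set by full enumeration."""
    pts = {oracle_metrics(tree, lab)
           for lab in enumerate_labelings(tree, sites, primary, fix_root)}
    return {p for p in pts
            if not any(all(a <= b for a, b in zip(q, p)) and q != p for q in pts)}


def oracle_min_migrations(tree: CloneTree, sites: Sequence[str], primary: str,
                          fix_root: bool = True) -> int:
    return min(oracle_metrics(tree, lab)[0]
               for lab in enumerate_labelings(tree, sites, primary, fix_root))


# ---------------------------------------------------------------------------
# random instances


def random_labeled_tree(rng: np.random.Generator, n_nodes: int, n_sites: int,
                        ) -> Tuple[CloneTree, VertexLabeling, List[str]]:
    edges = [(str(rng.integers(0, i)), str(i)) for i in range(1, n_nodes)]
    counts = {e: int(rng.integers(0, 20)) for e in edges}
    tree = build_tree(edges, counts)
    sites = [f"S{i}" for i in range(n_sites)]
    lab = VertexLabeling({n: sites[rng.integers(0, n_sites)] for n in tree.nodes()})
    return tree, lab, sites


@pytest.fixture
def chain_tree() -> CloneTree:
    return build_tree([("0", "1"), ("1", "2")], {("0", "1"): 5, ("1", "2"): 3})


@pytest.fixture
def star_tree() -> CloneTree:
    return build_tree([("0", str(i)) for i in range(1, 5)],
                      {("0", str(i)): i for i in range(1, 5)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
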