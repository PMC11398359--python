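"""Parsimony metrics for labeled clone trees.

Three integer metrics score a migration history:

* ``m`` — migrations: edges (witness edges included) whose endpoints carry
  different site labels; each is one seeding event of a clone at a new site.
* ``c`` — comigrations: groups of migration edges that could have traveled
  together. Migration edges sharing the same ordered (source, target) site
  pair form one comigration unless one lies on the root path of the other
  (two ancestrally ordered migrations between the same pair of sites cannot
  have been one event). The count is the minimum number of such groups,
  which by Mirsky's theorem equals, per site pair, the length of the longest
  ancestrally ordered chain of same-pair migration edges.
* ``s`` — seeding sites: distinct source sites among migration edges.

For every labeling, s <= c <= m, and m = 0 iff c = 0 iff s = 0.

The weighted parsimony score is p = wm*m + wc*c + ws*s; different weightings
("parsimony models") favor different histories on the Pareto front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .clone_tree import CloneTree, VertexLabeling, migration_edges_of

MACHINA_RULE = "machina"
SIMPLE_RULE = "simple"


@dataclass
class ParsimonyModel:
    """Weights of the parsimony metrics plus optional prior weights.

    ``wm``, ``wc``, ``ws`` weight migrations, comigrations, and seeding
    sites; ``w_gen`` and ``w_org`` weight the genetic-distance and
    organotropism priors inside the search objective (ranking uses the
    priors only for tie-breaking).
    """

    wm: float = 1.0
    wc: float = 1.0
    ws: float = 1.0
    w_gen: float = 0.0
    w_org: float = 0.0

    def __post_init__(self) -> None:
        w = (self.wm, self.wc, self.ws)
        if any(x < 0 for x in w) or all(x == 0 for x in w):
            raise ValueError("parsimony weights must be nonnegative, one positive")

    def normalized(self) -> "ParsimonyModel":
        tot = self.wm + self.wc + self.ws
        return ParsimonyModel(self.wm / tot, self.wc / tot, self.ws / tot,
                              self.w_gen, self.w_org)

    @classmethod
    def hierarchical(cls) -> "ParsimonyModel":
        """MACHINA-style fixed hierarchy wm >> wc >> ws."""
        return cls(wm=100.0, wc=10.0, ws=1.0)


def count_migrations(tree: CloneTree, labeling: VertexLabeling) -> int:
    return len(migration_edges_of(tree, labeling))


def count_seeding_sites(tree: CloneTree, labeling: VertexLabeling) -> int:
    return len({labeling[u] for u, _ in migration_edges_of(tree, labeling)})


def count_comigrations(tree: CloneTree, labeling: VertexLabeling,
                       rule: str = MACHINA_RULE) -> int:
    """Number of comigration groups under the chosen rule.

    ``machina`` applies the temporal-consistency rule described in the module
    docstring; ``simple`` counts distinct ordered site pairs with at least
    one migration edge.
    """
    mig = set(migration_edges_of(tree, labeling))
    if not mig:
        return 0
    if rule == SIMPLE_RULE:
        return len({(labeling[u], labeling[v]) for u, v in mig})
    if rule != MACHINA_RULE:
        raise ValueError(f"unknown comigration rule {rule!r}")
    # Longest same-pair chain along each root path, via one DFS carrying a
    # per-pair depth counter.
    best: Dict[Tuple[str, str], int] = {}
    depth: Dict[Tuple[str, str], int] = {}

    def visit(node: str) -> None:
        for child in tree.children.get(node, []):
            pair = None
            if (node, child) in mig:
                pair = (labeling[node], labeling[child])
                depth[pair] = depth.get(pair, 0) + 1
                if depth[pair] > best.get(pair, 0):
                    best[pair] = depth[pair]
            visit(child)
            if pair is not None:
                depth[pair] -= 1

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, tree.n_nodes() + 100))
    try:
        visit(tree.root)
    finally:
        sys.setrecursionlimit(old)
    return sum(best.values())


def compute_metrics(tree: CloneTree, labeling: VertexLabeling,
                    rule: str = MACHINA_RULE) -> Tuple[int, int, int]:
    """(m, c, s) for one labeled tree."""
    return (count_migrations(tree, labeling),
            count_comigrations(tree, labeling, rule),
            count_seeding_sites(tree, labeling))


def parsimony_score(metrics: Sequence[float], model: ParsimonyModel) -> float:
    m, c, s = metrics
    return model.wm * m + model.wc * c + model.ws * s


# ---- matrix formulation ---------------------------------------------------
#
# The optimizer scores many labelings at once; m and s (and simple-rule c)
# are pure matrix functions of the node adjacency matrix A and the one-hot
# labeling stack V. The machina-rule c needs root-path structure, supplied
# as a per-edge ancestor relation.


def site_pair_counts(A: np.ndarray, V: np.ndarray) -> np.ndarray:
    """P[..., i, j] = number of edges from site i to site j.

    ``A`` is the (N, N) 0/1 adjacency over all nodes; ``V`` a (..., K, N)
    stack of one-hot labelings. Returns (..., K, K).
    """
    return np.einsum("...ku,uv,...lv->...kl", V, A, V)


def metrics_batch(labels: np.ndarray, edge_index: Sequence[Tuple[int, int]],
                  edge_ancestor: np.ndarray, K: int,
                  rule: str = MACHINA_RULE) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (m, c, s) for a batch of hard labelings of one tree.

    ``labels`` is (n, N) site indices; ``edge_index`` the tree's (u, v) node
    index pairs; ``edge_ancestor`` the (E, E) boolean edge-above-edge
    relation. The machina comigration count is a longest-chain dynamic
    program over the ancestor relation, run for the whole batch at once.
    """
    labels = np.atleast_2d(labels)
    n = labels.shape[0]
    eu = np.array([u for u, _ in edge_index])
    ev = np.array([v for _, v in edge_index])
    E = len(eu)
    lu, lv = labels[:, eu], labels[:, ev]            # (n, E)
    mig = lu != lv
    m = mig.sum(axis=1)
    # seeding sites: distinct source labels among migration edges
    src = np.zeros((n, K), dtype=bool)
    rows = np.arange(n)
    for e in range(E):
        sel = mig[:, e]
        src[rows[sel], lu[sel, e]] = True
    s = src.sum(axis=1)
    if rule == SIMPLE_RULE:
        pairs = np.zeros((n, K * K), dtype=bool)
        for e in range(E):
            sel = mig[:, e]
            pairs[rows[sel], lu[sel, e] * K + lv[sel, e]] = True
        return m.astype(int), pairs.sum(axis=1).astype(int), s.astype(int)
    if rule != MACHINA_RULE:
        raise ValueError(f"unknown comigration rule {rule!r}")
    order = np.argsort(edge_ancestor.sum(axis=0), kind="stable")
    anc_lists = [np.nonzero(edge_ancestor[:, e])[0] for e in range(E)]
    chain = np.zeros((n, E), dtype=np.int32)
    for e in order:
        best = np.zeros(n, dtype=np.int32)
        for a in anc_lists[e]:
            same = mig[:, a] & (lu[:, a] == lu[:, e]) & (lv[:, a] == lv[:, e])
            np.maximum(best, chain[:, a] * same, out=best)
        chain[:, e] = (best + 1) * mig[:, e]
    per_pair = np.zeros((n, K * K), dtype=np.int32)
    for e in range(E):
        code = lu[:, e] * K + lv[:, e]
        np.maximum.at(per_pair, (rows, code), chain[:, e])
    c = per_pair.sum(axis=1)
    return m.astype(int), c.astype(int), s.astype(int)


def metrics_matrix(A: np.ndarray, V: np.ndarray,
                   edge_index: Sequence[Tuple[int, int]] | None = None,
                   edge_ancestor: np.ndarray | None = None,
                   rule: str = MACHINA_RULE) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(m, c, s) as matrix functions of adjacency A and one-hot stack V.

    m and s come from the site-pair count matrix P = V A V^T; the machina
    comigration count additionally needs the edge-ancestor relation (see
    :func:`metrics_batch`), without which the simple rule is used.
    """
    P = site_pair_counts(A, V)
    K = P.shape[-1]
    off = ~np.eye(K, dtype=bool)
    Poff = P * off
    m = Poff.sum(axis=(-2, -1))
    s = (Poff.sum(axis=-1) > 0).sum(axis=-1)
    if rule == SIMPLE_RULE or edge_index is None:
        c = (Poff > 0).sum(axis=(-2, -1))
        return m.astype(int), c.astype(int), s.astype(int)
    lab = np.argmax(V, axis=-2)
    batch_shape = lab.shape[:-1]
    _, c, _ = metrics_batch(lab.reshape(-1, lab.shape[-1]), edge_index,
                            edge_ancestor, K, rule)
    return m.astype(int), c.reshape(batch_shape), s.astype(int)


def edge_structures(tree: CloneTree, node_index: Dict[str, int]
                    ) -> Tuple[np.ndarray, List[Tuple[int, int]], np.ndarray]:
    """Adjacency, edge index pairs, and edge-ancestor relation for a tree."""
    N = tree.n_nodes()
    A = np.zeros((N, N))
    edge_index: List[Tuple[int, int]] = []
    edges = sorted(tree.edges())
    for p, ch in edges:
        A[node_index[p], node_index[ch]] = 1.0
        edge_index.append((node_index[p], node_index[ch]))
    E = len(edges)
    # ancestor-of relation between edges: edge a=(pa,ca) above edge b=(pb,cb)
    # iff ca is an ancestor-or-equal of pb.
    anc_nodes = {n: set(tree.path_from_root(n)) for n in tree.nodes()}
    edge_anc = np.zeros((E, E), dtype=bool)
    for ia, (pa, ca) in enumerate(edges):
        for ib, (pb, cb) in enumerate(edges):
            if ia != ib and ca in anc_nodes[pb]:
                edge_anc[ia, ib] = True
    return A, edge_index, edge_anc
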