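"""Clone trees, witness nodes, vertex labelings, and migration histories.

A clone tree is a rooted directed tree whose nodes are genetically distinct
cancer cell populations; each edge carries the number of mutations gained by
the child clone. A *witness node* is an artificial leaf attached to a clone
for every anatomical site in which that clone was observed; its site label is
fixed and is what anchors the vertex-labeling problem. A *migration history*
is a clone tree together with a site label for every node; edges whose
endpoints carry different labels are *migration edges*, summarized by a
multigraph over sites (the *migration graph*).

All downstream parsimony math is expressed over these containers.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

# Node kinds. Resolver nodes are inserted during polytomy resolution and,
# like witness nodes, carry no mutations of their own.
CLONE = "clone"
WITNESS = "witness"
RESOLVER = "resolver"


class TreeStructureError(ValueError):
    """Raised when an edge list does not describe a rooted tree."""


@dataclass
class CloneTree:
    """Rooted directed tree over clones with per-edge mutation counts.

    Parameters
    ----------
    root:
        Identifier of the unique parentless node.
    parent:
        Mapping child -> parent for every non-root node.
    children:
        Mapping parent -> ordered list of children (leaves map to []).
    edge_mutation_count:
        Mapping (parent, child) -> number of mutations gained by the child.
        Witness and resolver edges carry 0 by construction.
    node_kind:
        Mapping node -> one of ``clone``, ``witness``, ``resolver``.
    witness_site:
        Mapping witness node -> its fixed anatomical site.
    """

    root: str
    parent: Dict[str, str]
    children: Dict[str, List[str]]
    edge_mutation_count: Dict[Tuple[str, str], int]
    node_kind: Dict[str, str] = field(default_factory=dict)
    witness_site: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.nodes():
            self.node_kind.setdefault(n, CLONE)

    # ---- basic accessors -------------------------------------------------

    def nodes(self) -> List[str]:
        return [self.root] + list(self.parent.keys())

    def edges(self) -> List[Tuple[str, str]]:
        return [(p, c) for c, p in self.parent.items()]

    def clone_nodes(self) -> List[str]:
        return [n for n in self.nodes() if self.node_kind.get(n, CLONE) == CLONE]

    def witness_nodes(self) -> List[Tuple[str, str]]:
        """(witness node id, site) pairs, in insertion order."""
        return list(self.witness_site.items())

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    def n_nodes(self) -> int:
        return 1 + len(self.parent)

    def preorder(self) -> List[str]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, [])))
        return out

    def subtree_nodes(self, node: str) -> List[str]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children.get(n, []))
        return out

    def path_from_root(self, node: str) -> List[str]:
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def copy(self) -> "CloneTree":
        return CloneTree(
            root=self.root,
            parent=dict(self.parent),
            children={k: list(v) for k, v in self.children.items()},
            edge_mutation_count=dict(self.edge_mutation_count),
            node_kind=dict(self.node_kind),
            witness_site=dict(self.witness_site),
        )

    # ---- mutation --------------------------------------------------------

    def add_leaf(self, parent: str, node: str, kind: str, mutation_count: int = 0,
                 site: Optional[str] = None) -> None:
        if node in self.parent or node == self.root:
            raise ValueError(f"node {node!r} already in tree")
        self.parent[node] = parent
        self.children.setdefault(parent, []).append(node)
        self.children[node] = []
        self.edge_mutation_count[(parent, node)] = mutation_count
        self.node_kind[node] = kind
        if kind == WITNESS:
            if site is None:
                raise ValueError("witness node requires a site")
            self.witness_site[node] = site

    def remove_leaf(self, node: str) -> None:
        if not self.is_leaf(node):
            raise ValueError(f"{node!r} is not a leaf")
        p = self.parent.pop(node)
        self.children[p].remove(node)
        self.children.pop(node, None)
        self.edge_mutation_count.pop((p, node), None)
        self.node_kind.pop(node, None)
        self.witness_site.pop(node, None)

    # ---- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "root": self.root,
                "edges": [
                    [p, c, int(self.edge_mutation_count.get((p, c), 0))]
                    for p, c in sorted(self.edges())
                ],
                "node_kind": {n: k for n, k in sorted(self.node_kind.items())},
                "witness_site": dict(sorted(self.witness_site.items())),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CloneTree":
        d = json.loads(text)
        tree = build_tree([(p, c) for p, c, _ in d["edges"]],
                          {(p, c): m for p, c, m in d["edges"]})
        tree.node_kind.update(d.get("node_kind", {}))
        tree.witness_site.update(d.get("witness_site", {}))
        return tree


def build_tree(edge_list: Sequence[Tuple[str, str]],
               edge_mutation_counts: Optional[Mapping[Tuple[str, str], int]] = None,
               ) -> CloneTree:
    """Build a :class:`CloneTree` from parent->child pairs.

    The root is auto-detected as the unique parentless node. Cycles, multiple
    roots, multiple parents, and disconnected inputs raise
    :class:`TreeStructureError` naming the offending nodes.
    """
    edge_list = [(str(p), str(c)) for p, c in edge_list]
    g = nx.DiGraph()
    g.add_edges_from(edge_list)
    if len(g) == 0:
        raise TreeStructureError("empty edge list")
    multi = [n for n in g if g.in_degree(n) > 1]
    if multi:
        raise TreeStructureError(f"nodes with multiple parents: {sorted(multi)}")
    roots = [n for n in g if g.in_degree(n) == 0]
    if not roots:
        cyc = [u for u, _ in nx.find_cycle(g)]
        raise TreeStructureError(f"cycle through nodes: {cyc}")
    if len(roots) > 1:
        raise TreeStructureError(
            f"disconnected input or multiple roots: {sorted(roots)}")
    if not nx.is_weakly_connected(g):
        comps = [sorted(c)[0] for c in nx.weakly_connected_components(g)]
        raise TreeStructureError(f"disconnected components containing: {comps}")
    try:
        cyc = [u for u, _ in nx.find_cycle(g)]
        raise TreeStructureError(f"cycle through nodes: {cyc}")
    except nx.NetworkXNoCycle:
        pass
    root = roots[0]
    counts = dict(edge_mutation_counts or {})
    parent: Dict[str, str] = {}
    children: Dict[str, List[str]] = {n: [] for n in g}
    emc: Dict[Tuple[str, str], int] = {}
    for p, c in edge_list:
        parent[c] = p
        children[p].append(c)
        m = int(counts.get((p, c), 0))
        if m < 0:
            raise ValueError(f"negative mutation count on edge ({p},{c})")
        emc[(p, c)] = m
    return CloneTree(root=root, parent=parent, children=children,
                     edge_mutation_count=emc)


def attach_witness_nodes(tree: CloneTree, presence, sites: Sequence[str],
                         clones: Sequence[str]) -> CloneTree:
    """Attach a witness leaf for every (site, clone) presence call.

    ``presence`` is a K x C boolean array aligned with ``sites`` and
    ``clones``. Witness edges carry mutation count 0. Returns a new tree;
    the input is not modified.
    """
    import numpy as np

    presence = np.asarray(presence, dtype=bool)
    if presence.shape != (len(sites), len(clones)):
        raise ValueError(
            f"presence shape {presence.shape} != ({len(sites)}, {len(clones)})")
    known = set(tree.nodes())
    unknown = [c for c in clones if c not in known]
    if unknown:
        raise ValueError(f"presence given for unknown clones: {unknown}")
    out = tree.copy()
    for j, clone in enumerate(clones):
        for i, site in enumerate(sites):
            if presence[i, j]:
                wid = f"{clone}__wit__{site}"
                out.add_leaf(clone, wid, WITNESS, 0, site=site)
    return out


# ---- labelings and histories ---------------------------------------------


@dataclass(frozen=True)
class VertexLabeling:
    """Assignment of an anatomical site to every tree node.

    Stored as a plain mapping node -> site. Witness-node labels equal their
    observed site and are never altered by optimization. The one-hot matrix
    view used inside the optimizer lives in :mod:`seedtrace.search`.
    """

    site_of: Mapping[str, str]

    def __getitem__(self, node: str) -> str:
        return self.site_of[node]

    def sites(self) -> List[str]:
        return sorted(set(self.site_of.values()))

    def key(self) -> Tuple[Tuple[str, str], ...]:
        """Canonical hashable form (used for dedup and tie-breaking)."""
        return tuple(sorted(self.site_of.items()))


@dataclass
class MigrationHistory:
    """A labeled (possibly polytomy-resolved) clone tree with its metrics."""

    tree: CloneTree
    labeling: VertexLabeling
    m: int
    c: int
    s: int
    migration_edges: List[Tuple[str, str]]

    @property
    def metrics(self) -> Tuple[int, int, int]:
        return (self.m, self.c, self.s)

    def key(self) -> Tuple:
        """Dedup key: labeling plus resolved topology (resolver attachments)."""
        return (self.labeling.key(), tuple(sorted(self.tree.edges())))


class MigrationGraph:
    """Directed multigraph over sites; multiplicity = number of migration edges."""

    def __init__(self, edge_multiplicity: Optional[Mapping[Tuple[str, str], int]] = None):
        self.multiplicity: Counter = Counter(edge_multiplicity or {})
        for k in list(self.multiplicity):
            if self.multiplicity[k] <= 0:
                del self.multiplicity[k]

    def total_multiplicity(self) -> int:
        return sum(self.multiplicity.values())

    def sites(self) -> List[str]:
        out = set()
        for a, b in self.multiplicity:
            out.update((a, b))
        return sorted(out)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for (a, b), n in self.multiplicity.items():
            for _ in range(n):
                g.add_edge(a, b)
        return g

    def __eq__(self, other) -> bool:
        return isinstance(other, MigrationGraph) and self.multiplicity == other.multiplicity

    def __repr__(self) -> str:
        inner = ", ".join(f"{a}->{b}x{n}" for (a, b), n in sorted(self.multiplicity.items()))
        return f"MigrationGraph({inner})"


def migration_edges_of(tree: CloneTree, labeling: VertexLabeling) -> List[Tuple[str, str]]:
    """Edges (u, v), witness edges included, whose endpoint labels differ."""
    return [(u, v) for u, v in tree.edges() if labeling[u] != labeling[v]]


def extract_migration_graph(history: MigrationHistory) -> MigrationGraph:
    """Summarize a history's migration edges as a site multigraph."""
    lab = history.labeling
    return MigrationGraph(Counter((lab[u], lab[v]) for u, v in history.migration_edges))


def migration_graph_from_labeling(tree: CloneTree, labeling: VertexLabeling) -> MigrationGraph:
    lab = labeling
    return MigrationGraph(
        Counter((lab[u], lab[v]) for u, v in migration_edges_of(tree, labeling)))
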