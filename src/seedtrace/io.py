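"""Format adapters: tree/reads/presence TSV input, DOT and JSON output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import pandas as pd

from .clone_tree import (CLONE, RESOLVER, WITNESS, CloneTree, MigrationGraph,
                         MigrationHistory)
# deterministic fill colors per site index (repeats if sites exceed palette)
_PALETTE = ["#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#ffff33",
            "#a65628", "#f781bf", "#999999", "#66c2a5", "#fc8d62", "#8da0cb"]


def load_tree_tsv(path) -> Tuple[CloneTree, Dict[Tuple[str, str], str]]:
    """Parent/child TSV with optional ``mutations`` and ``cluster`` columns.

    Returns the tree and an edge -> cluster map (empty if no cluster column).
    """
    from .clone_tree import build_tree
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "parent" not in cols or "child" not in cols:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        df.columns = ["parent", "child", "mutations", "cluster"][: len(df.columns)]
    edges = list(zip(df["parent"], df["child"]))
    counts = {}
    if "mutations" in df.columns:
        counts = {(p, c): int(m) for p, c, m in
                  zip(df["parent"], df["child"], df["mutations"])}
    tree = build_tree(edges, counts)
    e2c: Dict[Tuple[str, str], str] = {}
    if "cluster" in df.columns:
        e2c = {(p, c): cl for p, c, cl in
               zip(df["parent"], df["child"], df["cluster"]) if isinstance(cl, str)}
    return tree, e2c


def write_dot(history: MigrationHistory, site_order=None) -> str:
    """Render a migration history as DOT text.

    Nodes are colored by site label; witness leaves are dashed; resolver
    nodes are annotated; migration edges are bold red. Node ordering is
    deterministic so identical histories yield byte-identical output.
    """
    tree, lab = history.tree, history.labeling
    sites = site_order or sorted({lab[n] for n in tree.nodes()})
    color = {s: _PALETTE[i % len(_PALETTE)] for i, s in enumerate(sites)}
    mig = set(history.migration_edges)
    lines = ["digraph migration_history {", '  node [style=filled];']
    for n in sorted(tree.nodes()):
        kind = tree.node_kind.get(n, CLONE)
        attrs = [f'fillcolor="{color[lab[n]]}"', f'label="{n}\\n{lab[n]}"']
        if kind == WITNESS:
            attrs.append('style="filled,dashed"')
            attrs.append('shape=ellipse')
        elif kind == RESOLVER:
            attrs.append('shape=diamond')
            attrs.append('label="%s (resolver)\\n%s"' % (n, lab[n]))
        lines.append(f'  "{n}" [{", ".join(attrs)}];')
    for p, c in sorted(tree.edges()):
        attrs = [f'label="{tree.edge_mutation_count.get((p, c), 0)}"']
        if (p, c) in mig:
            attrs.append('color="red"')
            attrs.append("penwidth=2")
        lines.append(f'  "{p}" -> "{c}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_migration_graph_dot(graph: MigrationGraph) -> str:
    lines = ["digraph migration_graph {"]
    for (a, b), n in sorted(graph.multiplicity.items()):
        lines.append(f'  "{a}" -> "{b}" [label="{n}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def front_to_json(ranked, patient: str, primary: str) -> str:
    """Serialize a ranked Pareto front: rank, metrics, scores, labeling."""
    sols = []
    for r in ranked:
        h = r.history
        sols.append({
            "rank": r.rank,
            "m": h.m, "c": h.c, "s": h.s,
            "parsimony_score": r.parsimony,
            "genetic_distance_score": r.genetic_distance,
            "organotropism_score": r.organotropism,
            "labeling": dict(sorted(h.labeling.site_of.items())),
            "migration_edges": sorted(h.migration_edges),
        })
    return json.dumps({"patient": patient, "primary": primary,
                       "n_solutions": len(sols), "solutions": sols}, indent=1)


def result_to_json(result) -> str:
    """Full machine-readable record of a patient result (tree + front)."""
    d = {
        "patient": result.patient,
        "primary": result.primary,
        "tree": json.loads(result.witness_tree.to_json()),
        "front": json.loads(front_to_json(result.ranked, result.patient,
                                          result.primary)),
    }
    if result.U is not None:
        d["U"] = result.U.round(6).to_dict()
    return json.dumps(d, indent=1)


def load_result_history(path) -> MigrationHistory:
    """Load the top-ranked history from a result JSON written by
    :func:`result_to_json`."""
    from .clone_tree import CloneTree, VertexLabeling, migration_edges_of
    from .parsimony import compute_metrics
    d = json.loads(Path(path).read_text())
    tree = CloneTree.from_json(json.dumps(d["tree"]))
    sol = d["front"]["solutions"][0]
    lab = VertexLabeling(sol["labeling"])
    m, c, s = compute_metrics(tree, lab)
    return MigrationHistory(tree, lab, m, c, s, migration_edges_of(tree, lab))


# ---- output schema --------------------------------------------------------
#
# Machine-readable outputs validate against these models; validate_result
# raises pydantic.ValidationError on malformed documents.

from typing import List as _List, Optional as _Optional

from pydantic import BaseModel


class SolutionRecord(BaseModel):
    rank: int
    m: int
    c: int
    s: int
    parsimony_score: float
    genetic_distance_score: float
    organotropism_score: _Optional[float] = None
    labeling: Dict[str, str]
    migration_edges: _List[_List[str]]


class FrontRecord(BaseModel):
    patient: str
    primary: str
    n_solutions: int
    solutions: _List[SolutionRecord]


class TreeRecord(BaseModel):
    root: str
    edges: _List[_List]          # [parent, child, mutation count]
    node_kind: Dict[str, str]
    witness_site: Dict[str, str]


class ResultRecord(BaseModel):
    patient: str
    primary: str
    tree: TreeRecord
    front: FrontRecord
    U: _Optional[Dict[str, Dict[str, float]]] = None


def validate_result(text: str) -> ResultRecord:
    """Parse and validate a result JSON written by :func:`result_to_json`."""
    return ResultRecord.model_validate_json(text)
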