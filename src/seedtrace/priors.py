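"""Metastasis priors: genetic distance and organotropism.

Parsimony alone often leaves several migration histories tied or
incomparable. Two independent lines of evidence rank them:

* **Genetic distance** — migration edges tend to be long (many mutations):
  colonizing clones expand clonally at the new site, making their private
  mutations detectable, and metastasizing cells experience elevated mutation
  rates. A history is scored sum over migration edges of -log D, where D is
  the per-edge normalized mutation count; lower is better, favoring
  migrations on long edges.

* **Organotropism** — cancer types preferentially seed particular organs.
  Given a per-site seeding frequency vector o for the patient's cancer type,
  a history is scored sum_i -log(o_i) * g_i, where g_i counts migration
  edges from the primary site to site i. Only primary-outgoing migrations
  are scored, because population-level frequency data describe seeding from
  the primary only.

Both scores are nonnegative and are used to rank (and tie-break) histories
on the Pareto front, never to define it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .clone_tree import CLONE, CloneTree, MigrationHistory


@dataclass
class GeneticDistanceMatrix:
    """Normalized per-edge mutation distances for one clone tree.

    Each clone-clone edge's mutation count receives a pseudocount of 1, and
    all are divided by the maximum pseudocounted count in the tree, so
    D in (0, 1] with the longest edge mapped to 1. Witness and resolver
    edges carry no mutations and are excluded from scoring.
    """

    distance: Dict[tuple, float] = field(default_factory=dict)

    @classmethod
    def from_tree(cls, tree: CloneTree, pseudocount: float = 1.0) -> "GeneticDistanceMatrix":
        counts = {
            (p, c): tree.edge_mutation_count.get((p, c), 0) + pseudocount
            for p, c in tree.edges()
            if tree.node_kind.get(c, CLONE) == CLONE
        }
        if not counts:
            return cls({})
        mx = max(counts.values())
        return cls({e: v / mx for e, v in counts.items()})

    def neg_log(self, edge: tuple) -> float:
        return -float(np.log(self.distance[edge]))


def genetic_distance_score(history: MigrationHistory,
                           D: GeneticDistanceMatrix) -> float:
    """Sum of -log D over clone-clone migration edges (lower is better)."""
    total = 0.0
    for u, v in history.migration_edges:
        if (u, v) in D.distance:
            total += -np.log(D.distance[(u, v)])
    return float(total)


@dataclass
class OrganotropismVector:
    """Per-site frequency with which this patient's cancer type seeds each site."""

    freq: Dict[str, float]

    def smoothed(self, floor_fraction: float = 1e-4) -> "OrganotropismVector":
        vals = np.array(list(self.freq.values()), dtype=float)
        floor = floor_fraction * max(vals.sum(), 1.0)
        return OrganotropismVector(
            {k: max(v, floor) for k, v in self.freq.items()})


def organotropism_score(history: MigrationHistory, o: OrganotropismVector,
                        primary: str) -> float:
    """Sum_i -log(o_i) * (number of primary -> i migration edges)."""
    lab = history.labeling
    g_counts: Dict[str, int] = {}
    for u, v in history.migration_edges:
        if lab[u] == primary:
            tgt = lab[v]
            g_counts[tgt] = g_counts.get(tgt, 0) + 1
    missing = sorted(set(g_counts) - set(o.freq))
    if missing:
        raise KeyError(f"sites missing from organotropism vector: {missing}")
    return float(sum(-np.log(o.freq[t]) * n for t, n in g_counts.items()))


def build_organotropism_table(occurrence: pd.DataFrame,
                              floor_fraction: float = 1e-4) -> pd.DataFrame:
    """Row-normalize a cancer-type x metastatic-site occurrence matrix.

    Rows are cancer types, columns anatomical sites, cells nonnegative
    occurrence counts. Rows are normalized to frequencies; zero cells then
    receive a floor (``floor_fraction`` of the row mass) so that -log is
    finite. The negative log frequencies are interpretable as a relative
    time to metastasis.
    """
    vals = occurrence.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("occurrence counts must be nonnegative")
    sums = vals.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero occurrence rows: {list(occurrence.index[zero])}")
    freq = vals / sums[:, None]
    freq = np.maximum(freq, floor_fraction)
    return pd.DataFrame(freq, index=occurrence.index, columns=occurrence.columns)


def load_organotropism_csv(path, cancer_type: Optional[str] = None,
                           site_map: Optional[Mapping[str, str]] = None,
                           floor_fraction: float = 1e-4) -> OrganotropismVector:
    """Load an organotropism vector from a CSV.

    First column: cancer type; remaining columns: per-site counts or
    frequencies (frequencies detected by row sums ~ 1). ``site_map``
    translates user site labels to the table's column names; no fuzzy
    matching is attempted.
    """
    df = pd.read_csv(path, index_col=0)
    sums = df.sum(axis=1).to_numpy()
    if not np.allclose(sums, 1.0, atol=0.05):
        df = build_organotropism_table(df, floor_fraction)
    else:
        df = pd.DataFrame(np.maximum(df.to_numpy(dtype=float), floor_fraction),
                          index=df.index, columns=df.columns)
    if cancer_type is None:
        if len(df) != 1:
            raise ValueError("cancer_type required for multi-row tables")
        row = df.iloc[0]
    else:
        row = df.loc[cancer_type]
    freq = {str(k): float(v) for k, v in row.items()}
    if site_map:
        freq = {user: freq[ref] for user, ref in site_map.items()}
    return OrganotropismVector(freq)
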