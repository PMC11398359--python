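"""Biological classification of migration histories.

Given a ranked set of migration histories, these operations summarize each
patient's metastatic spread:

* **colonizing clones** — the mutation-bearing clones that established a
  tumor at a new site: the target of each migration edge, except that a
  witness or resolver target (which carries no mutations of its own) stands
  in for its parent clone.
* **seeding pattern** — single-source (from the primary or from another
  site), multi-source (two or more seeding sites), or reseeding (some
  migration returns to the primary).
* **clonality** — genetic: do all sites share one colonizing clone? site:
  is each individual site seeded by exactly one clone (not necessarily the
  same one)? Genetic monoclonality implies site monoclonality.
* **phyleticity** — monophyletic if metastatic potential arose once:
  either all colonizing clones descend from the colonizing clone closest to
  the root (the definition used throughout), or, under the alternative
  TRACERx-style definition, all colonizing clones lie on one simple path of
  the clone tree.
* **transition summary** — site-by-site migration probabilities aggregated
  over patients, from top solutions only or averaged across each front.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd

from .clone_tree import CLONE, MigrationHistory

PATTERN_NONE = "none"
PATTERN_SINGLE_PRIMARY = "single-source primary"
PATTERN_SINGLE_OTHER = "single-source other"
PATTERN_MULTI = "multi-source"
PATTERN_RESEEDING = "reseeding"

MONO = "mono"
POLY = "poly"
UNDEFINED = "undefined"


def colonizing_clones(history: MigrationHistory) -> Set[str]:
    """Clones that established a tumor at a new site."""
    return {clone for clone, _ in colonizing_events(history)}


def colonizing_events(history: MigrationHistory) -> List[Tuple[str, str]]:
    """(colonizing clone, destination site) per migration edge."""
    tree, lab = history.tree, history.labeling
    events = []
    for u, v in history.migration_edges:
        clone = v
        if tree.node_kind.get(v, CLONE) != CLONE:
            clone = tree.parent[v]     # witness/resolver: no mutations of its own
        events.append((clone, lab[v]))
    return events


def seeding_pattern(history: MigrationHistory, primary: str) -> str:
    if not history.migration_edges:
        return PATTERN_NONE
    lab = history.labeling
    targets = {lab[v] for _, v in history.migration_edges}
    sources = {lab[u] for u, _ in history.migration_edges}
    if primary in targets:
        return PATTERN_RESEEDING
    if len(sources) >= 2:
        return PATTERN_MULTI
    return PATTERN_SINGLE_PRIMARY if sources == {primary} else PATTERN_SINGLE_OTHER


def clonality(history: MigrationHistory) -> Tuple[str, str]:
    """(genetic clonality, site clonality)."""
    events = colonizing_events(history)
    if not events:
        return (UNDEFINED, UNDEFINED)
    clones = {c for c, _ in events}
    genetic = MONO if len(clones) == 1 else POLY
    per_site: Dict[str, Set[str]] = {}
    for c, site in events:
        per_site.setdefault(site, set()).add(c)
    site = MONO if all(len(v) == 1 for v in per_site.values()) else POLY
    return (genetic, site)


def phyleticity(history: MigrationHistory) -> str:
    """Monophyletic iff all colonizing clones descend from the colonizing
    clone closest to the root (ties: mono if any closest candidate works)."""
    clones = colonizing_clones(history)
    if not clones:
        return UNDEFINED
    tree = history.tree
    depth = {c: len(tree.path_from_root(c)) for c in clones}
    dmin = min(depth.values())
    for s in sorted(c for c in clones if depth[c] == dmin):
        sub = set(tree.subtree_nodes(s))
        if clones <= sub:
            return MONO
    return POLY


def phyleticity_tracerx(history: MigrationHistory) -> str:
    """Monophyletic iff one simple tree path visits every colonizing clone.

    On a tree, a node set lies on a simple path iff every member lies on
    the path between the set's two (undirected) diameter endpoints.
    """
    clones = sorted(colonizing_clones(history))
    if not clones:
        return UNDEFINED
    if len(clones) <= 2:
        return MONO
    tree = history.tree
    paths = {c: tree.path_from_root(c) for c in clones}

    def path_between(a: str, b: str) -> Set[str]:
        pa, pb = paths.get(a) or tree.path_from_root(a), paths.get(b) or tree.path_from_root(b)
        common = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            common += 1
        return set(pa[common - 1:]) | set(pb[common - 1:])

    def dist(a: str, b: str) -> int:
        return len(path_between(a, b)) - 1

    u = max(clones, key=lambda c: dist(clones[0], c))
    v = max(clones, key=lambda c: dist(u, c))
    return MONO if set(clones) <= path_between(u, v) else POLY


def transition_summary(fronts: Dict[str, Sequence[MigrationHistory]],
                       mode: str = "top") -> pd.DataFrame:
    """Site-to-site transition probability matrix over a cohort.

    ``fronts`` maps patient -> ranked histories (best first). ``mode='top'``
    counts migration edges of each patient's top solution; ``'front-averaged'``
    weights each solution of a front uniformly. Rows are source sites,
    normalized to probabilities (all-zero rows left at zero).
    """
    if not fronts:
        raise ValueError("no patients")
    counts: Counter = Counter()
    for hists in fronts.values():
        if not hists:
            continue
        use = hists[:1] if mode == "top" else hists
        wgt = 1.0 / len(use)
        for h in use:
            lab = h.labeling
            for u, v in h.migration_edges:
                counts[(lab[u], lab[v])] += wgt
    sites = sorted({s for pair in counts for s in pair})
    mat = pd.DataFrame(0.0, index=sites, columns=sites)
    for (a, b), n in counts.items():
        mat.loc[a, b] = n
    sums = mat.sum(axis=1)
    nz = sums > 0
    mat.loc[nz] = mat.loc[nz].div(sums[nz], axis=0)
    return mat


def classify(history: MigrationHistory, primary: str) -> Dict[str, str]:
    """Full per-history classification record."""
    genetic, site = clonality(history)
    return {
        "seeding_pattern": seeding_pattern(history, primary),
        "genetic_clonality": genetic,
        "site_clonality": site,
        "phyleticity": phyleticity(history),
        "phyleticity_tracerx": phyleticity_tracerx(history),
        "colonizing_clones": ",".join(sorted(colonizing_clones(history))),
    }
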