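"""Synthetic patient cohorts with known migration histories.

Every stage of the pipeline is testable against these fixtures: each
simulated patient has a random clone tree, a ground-truth anatomical
labeling drawn under a controllable seeding pattern (primary-only,
metastasis-to-metastasis, or reseeding), per-site clone proportions, and
bulk read counts generated from the same binomial model the estimator
inverts. Mutation counts on migration edges are drawn stochastically longer
than on non-migration edges, mirroring the empirical signal that makes the
genetic-distance prior informative. Cohort scale defaults (80 patients,
5-11 tumor sites each) mirror the standard migration-history benchmark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .clone_tree import (CloneTree, MigrationHistory, VertexLabeling,
                         attach_witness_nodes, build_tree, migration_edges_of)
from .parsimony import MACHINA_RULE, compute_metrics
from .proportions import (CloneMutationMatrix, ObservedProportions,
                          ReadCountTable, clone_mutation_matrix)

PRIMARY_ONLY = "primary-only"
MET_TO_MET = "met-to-met"
RESEEDING = "reseeding"
PATTERNS = (PRIMARY_ONLY, MET_TO_MET, RESEEDING)

# study-condition defaults
DEFAULT_DEPTH = 500
DEFAULT_OMEGA = 0.5
DEFAULT_POLYCLONAL_RATE = 0.2
MIGRATION_EDGE_MUTATIONS = 15.0   # Poisson mean; non-migration edges use 5
NONMIGRATION_EDGE_MUTATIONS = 5.0
PURITY = 0.95
MAX_CLONES_PER_SITE = 6


@dataclass
class SimulatedPatient:
    """One synthetic patient: inputs plus serialized ground truth."""

    name: str
    tree: CloneTree                    # clone tree, no witnesses
    edge_to_cluster: Dict[Tuple[str, str], str]
    root_clusters: Tuple[str, ...]
    primary: str
    sites: List[str]
    pattern: str
    truth_labeling: VertexLabeling
    truth_U: ObservedProportions
    reads: ReadCountTable

    def clone_mutation_matrix(self) -> CloneMutationMatrix:
        return clone_mutation_matrix(self.tree, self.edge_to_cluster,
                                     root_clusters=self.root_clusters)

    def witness_tree(self) -> CloneTree:
        """Clone tree with truth-presence witness leaves attached."""
        presence = self.truth_U.U > 0.05
        return attach_witness_nodes(self.tree, presence,
                                    self.truth_U.sites, self.truth_U.clones)

    def truth_history(self) -> MigrationHistory:
        wt = self.witness_tree()
        lab = dict(self.truth_labeling.site_of)
        for w, site in wt.witness_site.items():
            lab[w] = site
        labeling = VertexLabeling(lab)
        m, c, s = compute_metrics(wt, labeling, MACHINA_RULE)
        return MigrationHistory(wt, labeling, m, c, s,
                                migration_edges_of(wt, labeling))


def _grow_labeled_tree(C: int, sites: Sequence[str], pattern: str,
                       polyclonal_rate: float, rng: np.random.Generator,
                       ) -> Tuple[List[Tuple[str, str]], Dict[str, str]]:
    """Grow tree and labels jointly so the pattern is satisfiable by
    construction: each migration's source is drawn from the nodes already
    carrying an allowed source label."""
    primary, mets = sites[0], list(sites[1:])
    lab: Dict[str, str] = {"0": primary}
    edges: List[Tuple[str, str]] = []
    by_site: Dict[str, List[str]] = {s: [] for s in sites}
    by_site[primary].append("0")
    par: Dict[str, str] = {}
    unused = list(mets)
    want_mm = pattern == MET_TO_MET      # still owe a met-sourced migration
    want_reseed = pattern == RESEEDING   # still owe a migration into primary

    def deep_mets(exclude_site=None):
        # met clones whose parent sits in the same met site; a migration from
        # such a clone cannot be re-sourced to the primary at equal parsimony,
        # so met-to-met truths built on them stay on the Pareto front
        return [n for s in mets if s != exclude_site for n in by_site[s]
                if n in par and lab[par[n]] == s]

    for i in range(1, C):
        node = str(i)
        remaining = C - i
        need_deep = (want_mm or want_reseed) and not deep_mets()
        owed = len(unused) + int(want_mm) + int(want_reseed) + int(need_deep)
        must = owed >= remaining
        migrate = must or rng.random() < 0.35
        target = parent = None
        if migrate:
            met_nodes = [n for s in mets for n in by_site[s]]
            deep_pool = deep_mets()
            if want_reseed and deep_pool and (must or rng.random() < 0.5) \
                    and len(by_site[primary]) < MAX_CLONES_PER_SITE:
                target = primary
                parent = deep_pool[int(rng.integers(len(deep_pool)))]
                want_reseed = False
            elif need_deep and must and met_nodes:
                # extend a met chain so a deep source exists
                parent = met_nodes[int(rng.integers(len(met_nodes)))]
                target = lab[parent]
            else:
                if unused:
                    target = unused[int(rng.integers(len(unused)))]
                else:
                    open_mets = [s for s in mets
                                 if 0 < len(by_site[s]) < MAX_CLONES_PER_SITE]
                    if open_mets and rng.random() < polyclonal_rate:
                        target = open_mets[int(rng.integers(len(open_mets)))]
                if target is not None:
                    # met-sourced migrations only from "deep" met clones, so
                    # the truth cannot be re-sourced to the primary at equal
                    # or better parsimony (it stays on the Pareto front)
                    if pattern == PRIMARY_ONLY:
                        src_pool = list(by_site[primary])
                    else:
                        met_src = deep_mets(exclude_site=target)
                        src_pool = list(by_site[primary]) + met_src
                        if want_mm and met_src and (must or rng.random() < 0.6):
                            src_pool = met_src
                    if src_pool:
                        parent = src_pool[int(rng.integers(len(src_pool)))]
                        src_site = lab[parent]
                        deep = (src_site != primary and parent in par
                                and lab[par[parent]] == src_site)
                        if want_mm and target != primary and deep:
                            want_mm = False
                    else:
                        target = None
        if parent is None:     # stay in the parent's site
            pool = [n for n in lab
                    if len(by_site[lab[n]]) < MAX_CLONES_PER_SITE]
            parent = pool[int(rng.integers(len(pool)))] if pool else "0"
            target = lab[parent]
        edges.append((parent, node))
        par[node] = parent
        lab[node] = target
        by_site[target].append(node)
        if target in unused:
            unused.remove(target)
    if unused or want_mm or want_reseed:
        raise _RetryDraw
    return edges, lab


class _RetryDraw(Exception):
    pass


def simulate_history(K: int, C: int, pattern: str = PRIMARY_ONLY,
                     polyclonal_rate: float = DEFAULT_POLYCLONAL_RATE,
                     rng: Optional[np.random.Generator] = None,
                     max_tries: int = 400,
                     ) -> Tuple[CloneTree, VertexLabeling, ObservedProportions,
                                Dict[Tuple[str, str], str], Tuple[str, ...]]:
    """Draw one ground-truth labeled clone tree and its clone proportions.

    Returns (tree, labeling, U, edge_to_cluster, root_clusters). Sites are
    named P, M1..M{K-1} with P the primary. Raises if the requested pattern
    is infeasible for (K, C).
    """
    if K < 2:
        raise ValueError("need at least 2 sites")
    if C < K:
        raise ValueError(f"pattern infeasible: C={C} clones cannot cover K={K} sites")
    if pattern == MET_TO_MET and (K < 3 or C < K + 1):
        raise ValueError("met-to-met seeding needs >= 2 metastatic sites and a "
                         "clone extending a metastatic chain")
    if pattern == RESEEDING and C < K + 2:
        raise ValueError("reseeding needs extra clones for a deep metastatic "
                         "chain and the return to the primary")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = rng or np.random.default_rng(0)
    sites = ["P"] + [f"M{i}" for i in range(1, K)]
    for _ in range(max_tries):
        try:
            edges, lab = _grow_labeled_tree(C, sites, pattern, polyclonal_rate, rng)
        except _RetryDraw:
            continue
        tree = build_tree(edges)
        labeling = VertexLabeling(lab)
        # migration edges carry more mutations (informative genetic distance)
        for p, c in tree.edges():
            mean = (MIGRATION_EDGE_MUTATIONS if lab[p] != lab[c]
                    else NONMIGRATION_EDGE_MUTATIONS)
            tree.edge_mutation_count[(p, c)] = 1 + int(rng.poisson(mean))
        edge_to_cluster = {(p, c): f"mut_{c}" for p, c in tree.edges()}
        root_clusters = ("mut_trunk",)
        U = _draw_proportions(tree, labeling, sites, rng)
        return tree, labeling, U, edge_to_cluster, root_clusters
    raise ValueError(f"could not draw a {pattern} labeling with K={K}, C={C}")


def _draw_proportions(tree: CloneTree, labeling: VertexLabeling,
                      sites: Sequence[str], rng: np.random.Generator,
                      ) -> ObservedProportions:
    """Dirichlet within-site mixing, floored so every present clone exceeds
    the 5% presence threshold with margin."""
    clones = tree.clone_nodes()
    U = np.zeros((len(sites), len(clones)))
    for i, site in enumerate(sites):
        members = [j for j, c in enumerate(clones) if labeling[c] == site]
        if not members:
            continue
        n = len(members)
        mix = 0.35 * rng.dirichlet(np.full(n, 1.5)) + 0.65 / n
        U[i, members] = PURITY * mix
    return ObservedProportions(list(sites), clones, U)


def simulate_reads(U: ObservedProportions, B: CloneMutationMatrix,
                   depth: int = DEFAULT_DEPTH, omega: float = DEFAULT_OMEGA,
                   rng: Optional[np.random.Generator] = None) -> ReadCountTable:
    """Binomial read counts: A_kj ~ Binom(depth, omega * (U B)_kj)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng or np.random.default_rng(0)
    F = np.clip(U.U @ B.B, 0.0, 1.0)
    p = np.clip(omega * F, 0.0, 1.0)
    A = rng.binomial(depth, p)
    R = depth - A
    om = np.full(F.shape, omega)
    return ReadCountTable(U.sites, list(B.clusters), A.astype(float),
                          R.astype(float), om)


def simulate_patient(name: str, K: int, C: int, pattern: str,
                     polyclonal_rate: float = DEFAULT_POLYCLONAL_RATE,
                     depth: int = DEFAULT_DEPTH, omega: float = DEFAULT_OMEGA,
                     rng: Optional[np.random.Generator] = None) -> SimulatedPatient:
    rng = rng or np.random.default_rng(0)
    tree, labeling, U, e2c, root_clusters = simulate_history(
        K, C, pattern, polyclonal_rate, rng)
    B = clone_mutation_matrix(tree, e2c, root_clusters=root_clusters)
    reads = simulate_reads(U, B, depth, omega, rng)
    return SimulatedPatient(name=name, tree=tree, edge_to_cluster=e2c,
                            root_clusters=tuple(root_clusters), primary="P",
                            sites=list(U.sites), pattern=pattern,
                            truth_labeling=labeling, truth_U=U, reads=reads)


def generate_cohort(n_patients: int = 80,
                    regime_mix: Optional[Dict[str, float]] = None,
                    seed: int = 0,
                    site_range: Tuple[int, int] = (5, 11),
                    extra_clones: Tuple[int, int] = (1, 5),
                    depth: int = DEFAULT_DEPTH,
                    polyclonal_rate: float = DEFAULT_POLYCLONAL_RATE,
                    out_dir: Optional[Path] = None) -> List[SimulatedPatient]:
    """Simulate a cohort; optionally write the on-disk layout.

    ``regime_mix`` maps pattern name -> fraction (default: all primary-only).
    Each patient gets K ~ U[site_range] sites and C = K + U[extra_clones]
    clones. With ``out_dir`` set, writes per-patient tree.tsv / reads.tsv /
    truth.json plus a cohort manifest.json recording seeds and parameters.
    """
    regime_mix = regime_mix or {PRIMARY_ONLY: 1.0}
    tot = sum(regime_mix.values())
    patterns, probs = zip(*[(k, v / tot) for k, v in regime_mix.items()])
    master = np.random.SeedSequence(seed)
    seeds = master.spawn(n_patients)
    pattern_rng = np.random.default_rng(master.spawn(1)[0])
    patients = []
    for i in range(n_patients):
        rng = np.random.default_rng(seeds[i])
        pattern = patterns[int(pattern_rng.choice(len(patterns), p=probs))]
        K = int(rng.integers(site_range[0], site_range[1] + 1))
        min_extra = {PRIMARY_ONLY: 1, MET_TO_MET: 1, RESEEDING: 2}[pattern]
        extra = max(min_extra, int(rng.integers(extra_clones[0],
                                                extra_clones[1] + 1)))
        C = K + extra
        patients.append(simulate_patient(f"sim{i:03d}", K, C, pattern,
                                         polyclonal_rate, depth, rng=rng))
    if out_dir is not None:
        _write_cohort(patients, Path(out_dir), seed, depth, regime_mix)
    return patients


def cohort_organotropism(patients: Sequence[SimulatedPatient],
                         floor_fraction: float = 1e-4) -> Dict[str, float]:
    """Empirical primary-to-site seeding frequencies of a cohort (the
    synthetic analogue of a cancer-type organotropism vector)."""
    from collections import Counter
    counts: Counter = Counter()
    for pt in patients:
        lab = pt.truth_labeling
        for u, v in pt.tree.edges():
            if lab[u] == pt.primary and lab[v] != lab[u]:
                counts[lab[v]] += 1
    sites = sorted({s for pt in patients for s in pt.sites if s != pt.primary})
    total = max(sum(counts.values()), 1)
    freq = {s: counts.get(s, 0) / total for s in sites}
    floor = floor_fraction
    return {s: max(f, floor) for s, f in freq.items()}


def _write_cohort(patients: Sequence[SimulatedPatient], out_dir: Path,
                  seed: int, depth: int, regime_mix: Dict[str, float]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "depth": depth, "regime_mix": regime_mix,
                "patients": []}
    for pt in patients:
        pdir = out_dir / pt.name
        pdir.mkdir(exist_ok=True)
        with open(pdir / "tree.tsv", "w") as fh:
            fh.write("parent\tchild\tmutations\tcluster\n")
            for p, c in sorted(pt.tree.edges()):
                fh.write(f"{p}\t{c}\t{pt.tree.edge_mutation_count[(p, c)]}\t"
                         f"{pt.edge_to_cluster[(p, c)]}\n")
        pt.reads.to_tsv(pdir / "reads.tsv")
        truth = {
            "primary": pt.primary,
            "pattern": pt.pattern,
            "labeling": dict(sorted(pt.truth_labeling.site_of.items())),
            "U": pt.truth_U.as_frame().round(6).to_dict(),
            "root_clusters": list(pt.root_clusters),
        }
        (pdir / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest["patients"].append({"name": pt.name, "pattern": pt.pattern,
                                     "K": len(pt.sites),
                                     "C": len(pt.tree.clone_nodes())})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
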