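"""Classification of histories: colonizers, seeding patterns, clonality, phyleticity."""

import itertools

import numpy as np
import pytest

from seedtrace import (VertexLabeling, build_tree, clonality,
                       colonizing_clones, phyleticity, phyleticity_tracerx,
                       seeding_pattern, transition_summary)
from seedtrace.analysis import MONO, POLY, UNDEFINED, colonizing_events
from seedtrace.clone_tree import (WITNESS, MigrationHistory,
                                  migration_edges_of)
from seedtrace.parsimony import compute_metrics
from conftest import random_labeled_tree


def hist(tree, lab):
    v = VertexLabeling(lab)
    m, c, s = compute_metrics(tree, v)
    return MigrationHistory(tree, v, m, c, s, migration_edges_of(tree, v))


def hist_with_witness(edges, lab, witness):
    """witness: list of (clone, site)."""
    tree = build_tree(edges)
    for clone, site in witness:
        tree.add_leaf(clone, f"{clone}__w__{site}", WITNESS, 0, site=site)
        lab = {**lab, f"{clone}__w__{site}": site}
    return hist(tree, lab)


class TestColonizingClones:
    def test_ordinary_migration_target(self):
        h = hist(build_tree([("0", "1"), ("1", "3")]),
                 {"0": "P", "1": "P", "3": "M1"})
        assert colonizing_clones(h) == {"3"}

    def test_witness_target_maps_to_parent(self):
        h = hist_with_witness([("0", "2")], {"0": "P", "2": "P"},
                              [("2", "M1")])
        assert colonizing_clones(h) == {"2"}

    def test_no_migrations_empty(self, chain_tree):
        h = hist(chain_tree, {n: "P" for n in chain_tree.nodes()})
        assert colonizing_clones(h) == set()


class TestSeedingPattern:
    def test_all_from_primary(self):
        h = hist(build_tree([("0", "1"), ("0", "2")]),
                 {"0": "P", "1": "M1", "2": "M2"})
        assert seeding_pattern(h, "P") == "single-source primary"

    def test_single_source_other(self):
        h = hist(build_tree([("0", "1"), ("1", "2"), ("1", "3")]),
                 {"0": "M1", "1": "M1", "2": "M2", "3": "M3"})
        assert seeding_pattern(h, "P") == "single-source other"

    def test_multi_source(self):
        h = hist(build_tree([("0", "1"), ("1", "2")]),
                 {"0": "P", "1": "M1", "2": "M2"})
        assert seeding_pattern(h, "P") == "multi-source"

    def test_reseeding_overrides(self):
        h = hist(build_tree([("0", "1"), ("1", "2")]),
                 {"0": "P", "1": "M1", "2": "P"})
        assert seeding_pattern(h, "P") == "reseeding"

    def test_no_migrations_sentinel(self, chain_tree):
        h = hist(chain_tree, {n: "P" for n in chain_tree.nodes()})
        assert seeding_pattern(h, "P") == "none"


class TestClonality:
    def test_one_clone_two_sites_is_mono_mono(self):
        h = hist_with_witness([("0", "1")], {"0": "P", "1": "P"},
                              [("1", "M1"), ("1", "M2")])
        assert clonality(h) == (MONO, MONO)

    def test_different_clones_different_sites(self):
        h = hist(build_tree([("0", "1"), ("0", "2")]),
                 {"0": "P", "1": "M1", "2": "M2"})
        assert clonality(h) == (POLY, MONO)

    def test_two_clones_same_site_site_poly(self):
        h = hist(build_tree([("0", "1"), ("0", "2")]),
                 {"0": "P", "1": "M1", "2": "M1"})
        assert clonality(h) == (POLY, POLY)

    def test_genetic_mono_implies_site_mono_on_random_trees(self, rng):
        for _ in range(50):
            tree, lab, _ = random_labeled_tree(rng, int(rng.integers(3, 10)), 3)
            h = hist(tree, dict(lab.site_of))
            g, s = clonality(h)
            if g == MONO:
                assert s == MONO

    def test_zero_migrations_undefined(self, chain_tree):
        h = hist(chain_tree, {n: "P" for n in chain_tree.nodes()})
        assert clonality(h) == (UNDEFINED, UNDEFINED)


def oracle_tracerx(tree, colonizers):
    """Exhaustive check: does some simple path contain all colonizers?"""
    nodes = tree.nodes()
    if len(colonizers) <= 1:
        return MONO
    paths = {n: tree.path_from_root(n) for n in nodes}

    def upath(a, b):
        pa, pb = paths[a], paths[b]
        i = 0
        while i < min(len(pa), len(pb)) and pa[i] == pb[i]:
            i += 1
        return set(pa[i - 1:]) | set(pb[i - 1:])

    return MONO if any(set(colonizers) <= upath(a, b)
                       for a, b in itertools.combinations_with_replacement(nodes, 2)) \
        else POLY


class TestPhyleticity:
    def test_single_subtree_is_monophyletic(self):
        h = hist(build_tree([("0", "1"), ("1", "2"), ("1", "3")]),
                 {"0": "P", "1": "M1", "2": "M2", "3": "M3"})
        assert phyleticity(h) == MONO

    def test_sibling_colonizers_polyphyletic(self):
        h = hist(build_tree([("0", "1"), ("0", "2"), ("1", "3"), ("2", "4")]),
                 {"0": "P", "1": "P", "2": "P", "3": "M1", "4": "M2"})
        assert phyleticity(h) == POLY

    def test_single_colonizer_mono(self):
        h = hist(build_tree([("0", "1")]), {"0": "P", "1": "M1"})
        assert phyleticity(h) == MONO
        assert phyleticity_tracerx(h) == MONO

    def test_chain_colonizers_are_tracerx_mono(self):
        h = hist(build_tree([("0", "1"), ("1", "2"), ("2", "3")]),
                 {"0": "P", "1": "M1", "2": "M2", "3": "M3"})
        assert phyleticity_tracerx(h) == MONO

    def test_three_star_leaves_not_on_a_path(self):
        h = hist(build_tree([("0", "1"), ("0", "2"), ("0", "3")]),
                 {"0": "P", "1": "M1", "2": "M2", "3": "M3"})
        assert phyleticity_tracerx(h) == POLY

    def test_sibling_pair_mono_by_path_but_poly_by_subtree(self):
        h = hist(build_tree([("0", "1"), ("0", "2")]),
                 {"0": "P", "1": "M1", "2": "M2"})
        assert phyleticity_tracerx(h) == MONO    # path 1-0-2
        assert phyleticity(h) == POLY

    def test_tracerx_matches_exhaustive_path_search(self, rng):
        for _ in range(60):
            tree, lab, _ = random_labeled_tree(rng, int(rng.integers(4, 11)), 4)
            h = hist(tree, dict(lab.site_of))
            cols = colonizing_clones(h)
            if not cols or len(cols) > 10:
                continue
            assert phyleticity_tracerx(h) == oracle_tracerx(tree, cols)

    def test_subtree_definition_checked_exhaustively(self, rng):
        for _ in range(60):
            tree, lab, _ = random_labeled_tree(rng, int(rng.integers(4, 11)), 3)
            h = hist(tree, dict(lab.site_of))
            cols = colonizing_clones(h)
            if not cols:
                continue
            depth = {c: len(tree.path_from_root(c)) for c in cols}
            dmin = min(depth.values())
            expected = MONO if any(
                cols <= set(tree.subtree_nodes(s))
                for s in cols if depth[s] == dmin) else POLY
            assert phyleticity(h) == expected


class TestTransitionSummary:
    def test_single_history_rows_normalized(self):
        h = hist(build_tree([("0", "1"), ("0", "2")]),
                 {"0": "P", "1": "M1", "2": "M1"})
        mat = transition_summary({"p": [h]})
        assert mat.loc["P", "M1"] == 1.0

    def test_no_migrations_zero_matrix(self, chain_tree):
        h = hist(chain_tree, {n: "P" for n in chain_tree.nodes()})
        mat = transition_summary({"p": [h]})
        assert mat.to_numpy().sum() == 0

    def test_front_average_is_mean_of_disjoint_solutions(self):
        h1 = hist(build_tree([("0", "1")]), {"0": "P", "1": "M1"})
        h2 = hist(build_tree([("0", "1")]), {"0": "P", "1": "M2"})
        mat = transition_summary({"p": [h1, h2]}, mode="front-averaged")
        assert mat.loc["P", "M1"] == pytest.approx(0.5)
        assert mat.loc["P", "M2"] == pytest.approx(0.5)

    def test_rows_sum_to_one_or_zero(self, rng):
        hists = {}
        for i in range(6):
            tree, lab, _ = random_labeled_tree(rng, 8, 3)
            hists[f"p{i}"] = [hist(tree, dict(lab.site_of))]
        mat = transition_summary(hists)
        sums = mat.sum(axis=1).to_numpy()
        assert all(abs(s - 1) < 1e-9 or s == 0 for s in sums)
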