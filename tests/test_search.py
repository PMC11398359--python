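"""Labeling search: ELBO, minimum-migration guarantee, polytomies, determinism."""

import numpy as np
import pytest

from seedtrace import (ParsimonyModel, SearchConfig, VertexLabeling,
                       attach_witness_nodes, build_tree, elbo,
                       guarantee_min_migrations, pareto_filter,
                       resolve_polytomies, search)
from seedtrace.clone_tree import RESOLVER
from seedtrace.parsimony import compute_metrics, parsimony_score
from conftest import oracle_front, oracle_min_migrations, random_labeled_tree
from seedtrace.simulate import simulate_patient


def witnessed(tree, site_of_clone, sites):
    """Attach one witness per clone at its given site."""
    clones = tree.clone_nodes()
    pres = np.zeros((len(sites), len(clones)), dtype=bool)
    for j, c in enumerate(clones):
        pres[sites.index(site_of_clone[c]), j] = True
    return attach_witness_nodes(tree, pres, sites, clones)


class TestElbo:
    def test_zero_migration_labeling_with_uniform_logits(self, chain_tree):
        lab = VertexLabeling({n: "P" for n in chain_tree.nodes()})
        psi = np.zeros((3, 3))        # uniform over 3 sites, 3 columns
        val = elbo(lab, chain_tree, ParsimonyModel(1, 1, 1), psi=psi)
        assert val == pytest.approx(3 * np.log(3))

    def test_deterministic_labeling_is_minus_score(self, chain_tree):
        lab = VertexLabeling({"0": "P", "1": "M1", "2": "M1"})
        model = ParsimonyModel(2, 1, 1)
        expected = -parsimony_score(compute_metrics(chain_tree, lab), model)
        assert elbo(lab, chain_tree, model) == pytest.approx(expected)

    def test_increasing_wm_decreases_elbo_of_migratory_labeling(self, chain_tree):
        lab = VertexLabeling({"0": "P", "1": "M1", "2": "M2"})
        vals = [elbo(lab, chain_tree, ParsimonyModel(wm, 1, 1))
                for wm in (1, 2, 5)]
        assert vals[0] > vals[1] > vals[2]


class TestMinMigrationGuarantee:
    def test_star_with_distinct_witness_sites(self):
        tree = build_tree([("0", str(i)) for i in range(1, 4)])
        sites = ["P", "A", "B", "C"]
        wt = witnessed(tree, {"0": "P", "1": "A", "2": "B", "3": "C"}, sites)
        lab = guarantee_min_migrations(wt, "P")
        assert compute_metrics(wt, lab)[0] == 3

    def test_chain_interior_takes_metastatic_label(self):
        tree = build_tree([("0", "1"), ("1", "2")])
        wt = witnessed(tree, {"0": "P", "1": "M1", "2": "M1"}, ["P", "M1"])
        lab = guarantee_min_migrations(wt, "P")
        assert compute_metrics(wt, lab)[0] == 1
        assert lab["1"] == lab["2"] == "M1"

    def test_single_site_needs_no_migrations(self, chain_tree):
        wt = witnessed(chain_tree, {n: "P" for n in chain_tree.nodes()}, ["P"])
        lab = guarantee_min_migrations(wt, "P")
        assert compute_metrics(wt, lab)[0] == 0

    def test_matches_brute_force_on_random_instances(self, rng):
        for i in range(20):
            pt = simulate_patient(f"g{i}", int(rng.integers(2, 4)),
                                  int(rng.integers(4, 8)), "primary-only",
                                  rng=np.random.default_rng(300 + i))
            wt = pt.witness_tree()
            sites = sorted({pt.primary} | set(wt.witness_site.values()))
            lab = guarantee_min_migrations(wt, pt.primary, sites=sites)
            assert compute_metrics(wt, lab)[0] == \
                oracle_min_migrations(wt, sites, pt.primary)


class TestPolytomyResolution:
    def test_four_children_get_two_resolvers(self):
        tree = build_tree([("0", str(i)) for i in range(1, 5)])
        out, movable = resolve_polytomies(tree)
        res = [n for n, k in out.node_kind.items() if k == RESOLVER]
        assert len(res) == 2
        assert all(out.edge_mutation_count[(out.parent[r], r)] == 0 for r in res)
        assert {c for c, _ in movable} == {"1", "2", "3", "4"}

    def test_binary_tree_unchanged(self, chain_tree):
        out, movable = resolve_polytomies(chain_tree)
        assert sorted(out.edges()) == sorted(chain_tree.edges())
        assert movable == []

    def test_search_output_has_no_childless_resolvers(self):
        tree = build_tree([("0", str(i)) for i in range(1, 5)])
        wt = witnessed(tree, {"0": "P", "1": "M1", "2": "M1", "3": "M2",
                              "4": "M2"}, ["P", "M1", "M2"])
        cands = search(wt, "P", ParsimonyModel(1, 1, 1),
                       config=SearchConfig(seed=5, resolve_polytomies=True))
        for h in cands:
            for n, k in h.tree.node_kind.items():
                if k == RESOLVER:
                    assert h.tree.children.get(n)

    def test_resolution_never_worsens_best_score(self):
        model = ParsimonyModel(1, 1, 1)
        tree = build_tree([("0", str(i)) for i in range(1, 6)])
        wt = witnessed(tree, {"0": "P", "1": "M1", "2": "M1", "3": "M1",
                              "4": "M2", "5": "M2"}, ["P", "M1", "M2"])
        best = {}
        for poly in (False, True):
            cands = search(wt, "P", model,
                           config=SearchConfig(seed=2, resolve_polytomies=poly))
            best[poly] = min(parsimony_score(h.metrics, model) for h in cands)
        assert best[True] <= best[False]


class TestSearch:
    def test_same_seed_reproduces_candidate_set(self):
        pt = simulate_patient("d", 3, 6, "met-to-met",
                              rng=np.random.default_rng(42))
        wt = pt.witness_tree()
        runs = []
        for _ in range(2):
            cands = search(wt, "P", ParsimonyModel(1, 1, 1),
                           config=SearchConfig(seed=11))
            runs.append(sorted(h.key() for h in cands))
        assert runs[0] == runs[1]

    def test_witness_and_root_labels_fixed_in_all_candidates(self):
        pt = simulate_patient("w", 3, 6, "primary-only",
                              rng=np.random.default_rng(8))
        wt = pt.witness_tree()
        cands = search(wt, "P", ParsimonyModel(1, 1, 1),
                       config=SearchConfig(seed=1))
        for h in cands:
            assert h.labeling[wt.root] == "P"
            for w, site in wt.witness_site.items():
                assert h.labeling[w] == site

    def test_candidates_cover_exact_front_on_small_instance(self, rng):
        pt = simulate_patient("f", 3, 6, "met-to-met",
                              rng=np.random.default_rng(77))
        wt = pt.witness_tree()
        sites = sorted({"P"} | set(wt.witness_site.values()))
        cands = search(wt, "P", ParsimonyModel(1, 1, 1),
                       config=SearchConfig(seed=3))
        assert oracle_front(wt, sites, "P") <= {h.metrics for h in cands}

    def test_restarts_enlarge_or_preserve_candidate_set(self):
        pt = simulate_patient("r", 3, 7, "primary-only",
                              rng=np.random.default_rng(55))
        wt = pt.witness_tree()
        one = search(wt, "P", ParsimonyModel(1, 1, 1),
                     config=SearchConfig(seed=4, restarts=1))
        four = search(wt, "P", ParsimonyModel(1, 1, 1),
                      config=SearchConfig(seed=4, restarts=4))
        front_one = {h.metrics for h in pareto_filter(one)}
        front_four = {h.metrics for h in pareto_filter(four)}
        for t in front_four:
            assert not any(all(a <= b for a, b in zip(u, t)) and u != t
                           for u in front_one)


class TestGumbelSoftmaxSample:
    def test_high_temperature_relaxes_to_uniform(self, rng):
        from seedtrace import gumbel_softmax_sample
        psi = rng.normal(size=(4, 3))
        nus = [gumbel_softmax_sample(psi, 1e5, rng)[1] for _ in range(200)]
        assert np.allclose(np.mean(nus, axis=0), 0.25, atol=0.02)

    def test_low_temperature_relaxation_matches_hard_sample(self, rng):
        from seedtrace import gumbel_softmax_sample
        psi = rng.normal(size=(4, 3))
        for _ in range(20):
            V, nu = gumbel_softmax_sample(psi, 1e-3, rng)
            assert np.allclose(V, nu, atol=1e-6)
            assert np.allclose(V.sum(axis=0), 1.0)

    def test_fixed_seed_identical_draws(self):
        from seedtrace import gumbel_softmax_sample
        psi = np.zeros((3, 5))
        a = gumbel_softmax_sample(psi, 0.5, np.random.default_rng(3))
        b = gumbel_softmax_sample(psi, 0.5, np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.allclose(a[1], b[1])

    def test_nonpositive_temperature_rejected(self, rng):
        from seedtrace import gumbel_softmax_sample
        with pytest.raises(ValueError):
            gumbel_softmax_sample(np.zeros((2, 2)), 0.0, rng)
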