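"""Clone-proportion estimation: closed forms, constraints, recovery, presence."""

import numpy as np
import pandas as pd
import pytest

from seedtrace import (ReadCountTable, build_tree, call_presence,
                       clone_mutation_matrix, estimate_U_binomial,
                       estimate_U_quadratic)
from seedtrace.proportions import ObservedProportions
from seedtrace.simulate import simulate_patient


def single_clone_reads(A=25, R=75, omega=0.5):
    return ReadCountTable(["S"], ["m0"], np.array([[A]], dtype=float),
                          np.array([[R]], dtype=float), np.array([[omega]]))


def single_clone_B():
    tree = build_tree([("r", "c")])
    return clone_mutation_matrix(tree, {("r", "c"): "m0"})


class TestCloneMutationMatrix:
    def test_chain_accumulates_clusters(self):
        tree = build_tree([("0", "1"), ("1", "2")])
        B = clone_mutation_matrix(tree, {("0", "1"): "a", ("1", "2"): "b"})
        assert B.mutations_of("0") == frozenset()
        assert B.mutations_of("1") == {"a"}
        assert B.mutations_of("2") == {"a", "b"}

    def test_single_node_tree_zero_row(self):
        tree = build_tree([("0", "1")])
        tree.remove_leaf("1")
        B = clone_mutation_matrix(tree, {}, clusters=["x"])
        assert B.B.shape == (1, 1)
        assert B.B.sum() == 0

    def test_star_siblings_share_only_root_clusters(self):
        tree = build_tree([("0", "1"), ("0", "2")])
        B = clone_mutation_matrix(tree, {("0", "1"): "a", ("0", "2"): "b"},
                                  root_clusters=["t"])
        assert B.mutations_of("1") == {"t", "a"}
        assert B.mutations_of("2") == {"t", "b"}
        assert B.mutations_of("1") & B.mutations_of("2") == {"t"}

    def test_cluster_on_two_edges_violates_infinite_sites(self):
        tree = build_tree([("0", "1"), ("1", "2")])
        with pytest.raises(ValueError, match="infinite-sites"):
            clone_mutation_matrix(tree, {("0", "1"): "a", ("1", "2"): "a"})


class TestEstimators:
    def test_quadratic_single_clone_closed_form(self):
        # MLE p = 25/100 = 0.25; F = p / omega = 0.5
        # clone "c" carries the cluster; root "r" carries nothing
        U = estimate_U_quadratic(single_clone_reads(), single_clone_B(),
                                 l1_strength=0.0)
        j = U.clones.index("c")
        assert U.U[0, j] == pytest.approx(0.5, abs=1e-3)

    def test_binomial_single_clone_matches_mle(self):
        U = estimate_U_binomial(single_clone_reads(), single_clone_B(),
                                l1_strength=0.0)
        assert U.U[0, U.clones.index("c")] == pytest.approx(0.5, abs=1e-2)

    def test_all_zero_variant_reads_give_zero_U(self):
        reads = single_clone_reads(A=0, R=100)
        for est in (estimate_U_quadratic, estimate_U_binomial):
            U = est(reads, single_clone_B())
            assert np.allclose(U.U[0, U.clones.index("c")], 0.0, atol=1e-3)

    def test_constraints_hold_after_projection(self, rng):
        pt = simulate_patient("p", 4, 6, "primary-only", rng=rng)
        for est in (estimate_U_quadratic, estimate_U_binomial):
            U = est(pt.reads, pt.clone_mutation_matrix())
            assert U.U.min() >= 0
            assert U.U.sum(axis=1).max() <= 1 + 1e-9

    def test_estimators_agree_at_high_depth(self):
        rng = np.random.default_rng(5)
        pt = simulate_patient("p", 3, 5, "primary-only", depth=2000, rng=rng)
        B = pt.clone_mutation_matrix()
        Uq = estimate_U_quadratic(pt.reads, B).U
        Ub = estimate_U_binomial(pt.reads, B).U
        assert np.abs(Uq - Ub).max() < 0.05

    def test_sparsity_monotone_in_l1(self):
        rng = np.random.default_rng(9)
        pt = simulate_patient("p", 3, 5, "primary-only", depth=100, rng=rng)
        B = pt.clone_mutation_matrix()
        nnz = [int((estimate_U_quadratic(pt.reads, B, l1_strength=lam).U > 1e-3).sum())
               for lam in (0.0, 10.0, 1e4, 1e6)]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_parameter_recovery_at_depth_200(self):
        rng = np.random.default_rng(17)
        errs = []
        for i in range(5):
            pt = simulate_patient(f"p{i}", 4, 6, "primary-only", depth=200,
                                  rng=np.random.default_rng(100 + i))
            U = estimate_U_quadratic(pt.reads, pt.clone_mutation_matrix())
            Uhat = U.as_frame().reindex(index=pt.truth_U.sites,
                                        columns=pt.truth_U.clones).to_numpy()
            errs.append(np.abs(Uhat - pt.truth_U.U).mean())
        assert np.mean(errs) < 0.05


class TestPresenceCalls:
    def _props(self, vals, tree, clones):
        return ObservedProportions(["k"], clones, np.array([vals]))

    def test_threshold_is_strict(self):
        tree = build_tree([("0", "1")])
        props = self._props([0.5, 0.06], tree, ["0", "1"])
        pres, _ = call_presence(props, tree)
        assert bool(pres.loc["k", "1"]) is True
        props = self._props([0.5, 0.05], tree, ["0", "1"])
        pres, pruned = call_presence(props, tree)
        assert "1" not in pres.columns        # pruned as an absent leaf

    def test_absent_leaf_clone_removed(self):
        tree = build_tree([("0", "1"), ("1", "2")])
        props = self._props([0.5, 0.4, 0.01], tree, ["0", "1", "2"])
        _, pruned = call_presence(props, tree)
        assert "2" not in pruned.nodes()

    def test_pruning_iterates_up_exposed_leaves(self):
        tree = build_tree([("0", "1"), ("1", "2")])
        props = self._props([0.9, 0.01, 0.01], tree, ["0", "1", "2"])
        _, pruned = call_presence(props, tree)
        assert pruned.nodes() == ["0"]

    def test_absent_internal_clone_kept(self):
        tree = build_tree([("0", "1"), ("1", "2")])
        props = self._props([0.5, 0.01, 0.4], tree, ["0", "1", "2"])
        _, pruned = call_presence(props, tree)
        assert "1" in pruned.nodes()


class TestReadCountTable:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        pt = simulate_patient("p", 3, 4, "primary-only", rng=rng)
        path = tmp_path / "reads.tsv"
        pt.reads.to_tsv(path)
        back = ReadCountTable.from_tsv(path)
        assert back.sites == pt.reads.sites
        assert np.array_equal(back.var_reads, pt.reads.var_reads)

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            ReadCountTable(["s"], ["m"], np.array([[1.0]]), np.array([[1.0]]),
                           np.array([[1.5]]))


class TestCappedSimplexProjection:
    """The projection behind both estimators' proximal step."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_projection_is_feasible_and_idempotent(self, vals):
        from seedtrace.proportions import _project_capped_simplex
        v = np.array([vals])
        u = _project_capped_simplex(v)
        assert (u >= -1e-12).all()
        assert u.sum() <= 1 + 1e-9
        assert np.allclose(_project_capped_simplex(u), u, atol=1e-9)

    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=8),
           st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_projection_is_nearest_feasible_point(self, vals, seed):
        from seedtrace.proportions import _project_capped_simplex
        v = np.array(vals)
        u = _project_capped_simplex(v[None])[0]
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(len(vals))) * rng.uniform(0, 1)
        assert np.linalg.norm(u - v) <= np.linalg.norm(w - v) + 1e-9
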