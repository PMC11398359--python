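"""Synthetic-cohort generator: pattern constraints, reads model, determinism."""

import json

import numpy as np
import pytest

from seedtrace import simulate_history, simulate_patient, simulate_reads
from seedtrace.simulate import (MET_TO_MET, PRIMARY_ONLY, RESEEDING,
                                cohort_organotropism, generate_cohort)


class TestSimulateHistory:
    def test_primary_only_sources_all_primary(self, rng):
        tree, lab, U, _, _ = simulate_history(4, 7, PRIMARY_ONLY, rng=rng)
        for u, v in tree.edges():
            if lab[u] != lab[v]:
                assert lab[u] == "P"

    def test_met_to_met_has_met_source(self, rng):
        tree, lab, _, _, _ = simulate_history(4, 7, MET_TO_MET, rng=rng)
        migs = [(lab[u], lab[v]) for u, v in tree.edges() if lab[u] != lab[v]]
        assert any(a != "P" and b != "P" for a, b in migs)
        assert not any(b == "P" for _, b in migs)

    def test_reseeding_targets_primary(self, rng):
        tree, lab, _, _, _ = simulate_history(3, 6, RESEEDING, rng=rng)
        migs = [(lab[u], lab[v]) for u, v in tree.edges() if lab[u] != lab[v]]
        assert any(b == "P" for _, b in migs)

    def test_all_sites_covered(self, rng):
        for K in (2, 5, 9):
            _, lab, _, _, _ = simulate_history(K, K + 4, PRIMARY_ONLY, rng=rng)
            assert len(set(lab.site_of.values())) == K

    def test_infeasible_patterns_raise(self):
        with pytest.raises(ValueError):
            simulate_history(5, 3, PRIMARY_ONLY)     # C < K
        with pytest.raises(ValueError):
            simulate_history(2, 6, MET_TO_MET)       # no second met site

    def test_fixed_seed_reproducible(self):
        a = simulate_history(4, 7, PRIMARY_ONLY, rng=np.random.default_rng(5))
        b = simulate_history(4, 7, PRIMARY_ONLY, rng=np.random.default_rng(5))
        assert sorted(a[0].edges()) == sorted(b[0].edges())
        assert a[1].site_of == b[1].site_of
        assert np.array_equal(a[2].U, b[2].U)

    def test_migration_edges_carry_more_mutations_on_average(self):
        mig, non = [], []
        for i in range(10):
            tree, lab, _, _, _ = simulate_history(
                4, 8, PRIMARY_ONLY, rng=np.random.default_rng(i))
            for e in tree.edges():
                (mig if lab[e[0]] != lab[e[1]] else non).append(
                    tree.edge_mutation_count[e])
        assert np.mean(mig) > np.mean(non)

    def test_present_clones_exceed_presence_threshold(self, rng):
        _, lab, U, _, _ = simulate_history(5, 9, PRIMARY_ONLY, rng=rng)
        present = U.U[U.U > 0]
        assert present.min() > 0.05


class TestSimulateReads:
    def test_zero_frequency_means_zero_variant_reads(self, rng):
        pt = simulate_patient("p", 3, 5, PRIMARY_ONLY, rng=rng)
        B = pt.clone_mutation_matrix()
        F = pt.truth_U.U @ B.B
        assert np.all(pt.reads.var_reads[F == 0] == 0)

    def test_deep_coverage_concentrates_on_expected_vaf(self):
        rng = np.random.default_rng(2)
        tree, lab, U, e2c, rc = simulate_history(3, 5, PRIMARY_ONLY, rng=rng)
        from seedtrace import clone_mutation_matrix
        B = clone_mutation_matrix(tree, e2c, root_clusters=rc)
        reads = simulate_reads(U, B, depth=100000, omega=0.5, rng=rng)
        F = np.clip(U.U @ B.B, 0, 1)
        vaf = reads.var_reads / np.maximum(reads.depth, 1)
        assert np.abs(vaf - 0.5 * F).max() < 0.01

    def test_seeded_reproducibility(self, rng):
        tree, lab, U, e2c, rc = simulate_history(3, 5, PRIMARY_ONLY, rng=rng)
        from seedtrace import clone_mutation_matrix
        B = clone_mutation_matrix(tree, e2c, root_clusters=rc)
        r1 = simulate_reads(U, B, rng=np.random.default_rng(3))
        r2 = simulate_reads(U, B, rng=np.random.default_rng(3))
        assert np.array_equal(r1.var_reads, r2.var_reads)

    def test_bad_depth_rejected(self, rng):
        tree, lab, U, e2c, rc = simulate_history(3, 5, PRIMARY_ONLY, rng=rng)
        from seedtrace import clone_mutation_matrix
        B = clone_mutation_matrix(tree, e2c, root_clusters=rc)
        with pytest.raises(ValueError):
            simulate_reads(U, B, depth=0)


class TestGenerateCohort:
    def test_cohort_layout_written(self, tmp_path):
        generate_cohort(2, {PRIMARY_ONLY: 1.0}, seed=1, site_range=(3, 4),
                        out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert len(manifest["patients"]) == 2
        for rec in manifest["patients"]:
            pdir = tmp_path / rec["name"]
            assert (pdir / "tree.tsv").exists()
            assert (pdir / "reads.tsv").exists()
            truth = json.loads((pdir / "truth.json").read_text())
            assert truth["primary"] == "P"

    def test_single_patient_cohort(self):
        pts = generate_cohort(1, seed=2, site_range=(3, 3))
        assert len(pts) == 1

    def test_regime_mix_recorded(self):
        pts = generate_cohort(12, {PRIMARY_ONLY: 0.5, MET_TO_MET: 0.5}, seed=3,
                              site_range=(4, 5))
        patterns = {pt.pattern for pt in pts}
        assert patterns == {PRIMARY_ONLY, MET_TO_MET}

    def test_benchmark_scale_site_range(self):
        pts = generate_cohort(8, seed=4)
        Ks = [len(pt.sites) for pt in pts]
        assert all(5 <= k <= 11 for k in Ks)

    def test_cohort_seeded_reproducibility(self):
        a = generate_cohort(3, seed=9, site_range=(3, 4))
        b = generate_cohort(3, seed=9, site_range=(3, 4))
        for x, y in zip(a, b):
            assert x.truth_labeling.site_of == y.truth_labeling.site_of
            assert np.array_equal(x.reads.var_reads, y.reads.var_reads)


class TestCohortOrganotropism:
    def test_frequencies_positive_and_normalized(self):
        pts = generate_cohort(6, seed=5, site_range=(4, 5))
        freq = cohort_organotropism(pts)
        assert all(v > 0 for v in freq.values())
        assert sum(freq.values()) == pytest.approx(1.0, abs=0.01)
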