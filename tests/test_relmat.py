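"""GRM formula, IBS distance conventions, and classical MDS geometry."""

import numpy as np
import pytest

from gwsel.io import CODOMINANT, DOMINANT
from gwsel.relmat import (RelationshipMatrix, classical_mds,
                          compute_grm, compute_ibs_distance)
from gwsel.simdata import SimConfig, sim_founder_genotypes

from conftest import tiny_matrix


class TestGRM:
    def test_single_marker_hand_example(self):
        # doses (0, 2), p = 0.5: G = ZZ'/(2 p q) = [[2,-2],[-2,2]]
        g = tiny_matrix([[0.0], [2.0]])
        G = compute_grm(g, ridge=0.0).values
        assert np.allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_plants_equal_rows(self):
        g = tiny_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        G = compute_grm(g).values
        assert np.allclose(G[0], G[1])
        off = G - np.diag(np.diag(G))
        assert off[0, 1] == pytest.approx(off.max())

    def test_diagonal_mean_under_hwe(self):
        cfg = SimConfig(n_founders=500, n_markers=2000, n_qtl=0, seed=8,
                        dominant_fraction=0.0)
        g = sim_founder_genotypes(cfg)
        G = compute_grm(g, ridge=1e-6)
        # E[mean diag] = 1 under HWE with observed-frequency centering
        assert np.mean(np.diag(G.values)) == pytest.approx(1.0 + 1e-6, abs=0.02)

    def test_monomorphic_panel_rejected(self):
        g = tiny_matrix([[0.0], [0.0]])
        with pytest.raises(ZeroDivisionError):
            compute_grm(g)


class TestIBS:
    def test_identity_and_maximal(self):
        g = tiny_matrix([[0, 2], [0, 2], [2, 0]])
        D = compute_ibs_distance(g).values
        assert D[0, 1] == pytest.approx(0.0)     # identical plants
        assert D[0, 2] == pytest.approx(1.0)     # opposite homozygotes
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_codominant_hand_example(self):
        # plants (0,1) vs (2,1): sharing (0 + 1)/2 -> d = 0.5
        g = tiny_matrix([[0, 1], [2, 1]])
        D = compute_ibs_distance(g).values
        assert D[0, 1] == pytest.approx(0.5)

    def test_dominant_all_or_nothing(self):
        g = tiny_matrix([[0, 1], [1, 1]], marker_type=[DOMINANT, DOMINANT])
        D = compute_ibs_distance(g).values
        assert D[0, 1] == pytest.approx(0.5)     # one agrees, one differs

    def test_entries_in_unit_interval(self, small_sim):
        geno, _, _ = small_sim
        D = compute_ibs_distance(geno).values
        assert D.min() >= 0.0 and D.max() <= 1.0


class TestMDS:
    def test_collinear_three_points(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        dist = RelationshipMatrix(D, ["a", "b", "c"], "ibs_distance")
        res = classical_mds(dist, k=2)
        # second axis collapses; first recovers -1, 0, 1 up to sign
        assert res.coordinates.shape[1] == 1
        axis = np.sort(res.coordinates[:, 0])
        assert np.allclose(axis, [-1.0, 0.0, 1.0], atol=1e-10)

    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dist = RelationshipMatrix(D, [f"p{i}" for i in range(15)], "ibs_distance")
        res = classical_mds(dist, k=2)
        # Procrustes: optimal rotation of recovered onto planted coordinates
        A = res.coordinates - res.coordinates.mean(0)
        B = pts - pts.mean(0)
        U, _, Vt = np.linalg.svd(A.T @ B)
        err = np.linalg.norm(A @ (U @ Vt) - B)
        assert err < 1e-8

    def test_duplicate_points_identical_coordinates(self):
        g = tiny_matrix([[0, 2, 1], [0, 2, 1], [2, 0, 1], [1, 1, 1]])
        res = classical_mds(compute_ibs_distance(g))
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-10)

    def test_row_order_invariance(self, small_sim):
        geno, _, _ = small_sim
        res1 = classical_mds(compute_ibs_distance(geno))
        perm = np.random.default_rng(1).permutation(geno.n_plants)
        res2 = classical_mds(compute_ibs_distance(geno.select_plants(perm)))
        # same embedding up to permutation and axis sign
        for ax in range(2):
            c1 = res1.coordinates[perm, ax]
            c2 = res2.coordinates[:, ax]
            assert min(np.max(np.abs(c1 - c2)), np.max(np.abs(c1 + c2))) < 1e-8

    def test_centered_and_sorted(self, small_sim):
        geno, _, _ = small_sim
        res = classical_mds(compute_ibs_distance(geno))
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-10)

    def test_against_skbio_pcoa(self, small_sim):
        skbio = pytest.importorskip("skbio")
        geno, _, _ = small_sim
        dist = compute_ibs_distance(geno)
        res = classical_mds(dist, k=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dist.values, ids=dist.plant_ids))
        for ax in range(2):
            c1 = res.coordinates[:, ax]
            c2 = ref.samples.iloc[:, ax].to_numpy()
            assert min(np.max(np.abs(c1 - c2)), np.max(np.abs(c1 + c2))) < 1e-6


class TestIBSProperties:
    def test_symmetry_and_identity_property(self):
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra import numpy as hnp

        @settings(max_examples=30, deadline=None, derandomize=True)
        @given(hnp.arrays(np.int64, (5, 8), elements=st.integers(0, 2)))
        def check(vals):
            g = tiny_matrix(vals.astype(float))
            D = compute_ibs_distance(g).values
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0.0)
            assert D.min() >= -1e-12 and D.max() <= 1.0 + 1e-12
            # identity of indiscernibles: equal rows <=> zero distance
            for i in range(5):
                for j in range(5):
                    if np.array_equal(vals[i], vals[j]):
                        assert D[i, j] == pytest.approx(0.0)

        check()
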