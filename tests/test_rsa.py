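import dataclasses

import numpy as np
import pytest
from scipy import sparse

import neurosem as ns
from neurosem.rsa import (
    DSM,
    build_patches,
    cluster_permutation_test,
    dsm_correlation,
    dsm_euclidean,
    mantel_test,
    neural_dsms,
    rsa_partial,
    rsa_spearman,
    searchlight_rsa,
)
from neurosem.synthetic import SourceEstimateSet


def _dsm_from_triangle(tri, n):
    m = np.zeros((n, n))
    m[np.triu_indices(n, k=1)] = tri
    return DSM(values=m + m.T, metric="euclidean")


class TestDSMConstruction:
    def test_duplicate_rows_give_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        dsm = dsm_correlation(X)
        assert dsm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_give_two(self):
        X = np.array([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        assert dsm_correlation(X).values[0, 1] == pytest.approx(2.0)

    def test_hand_computed_pearson(self):
        dsm = dsm_correlation(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]))
        assert dsm.values[0, 1] == pytest.approx(1 - 0.9819805, abs=1e-6)

    def test_constant_row_named_in_error(self):
        X = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="itemB"):
            dsm_correlation(X, items=["itemA", "itemB"])

    def test_euclidean_cases(self):
        dsm = dsm_euclidean([1.0, 4.0, 6.0])
        assert dsm.values[0, 2] == 5.0
        shifted = dsm_euclidean([101.0, 104.0, 106.0])
        np.testing.assert_allclose(dsm.values, shifted.values)
        np.testing.assert_array_equal(dsm_euclidean([2.0, 2.0, 2.0]).values, 0.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DSM(values=np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DSM(values=np.array([[0.1, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            DSM(values=np.array([[0.0, 3.0], [3.0, 0.0]]), metric="correlation")


class TestSearchlightPatches:
    def test_tiny_radius_gives_singletons(self, small_mesh):
        patches = build_patches(small_mesh, radius=1e-6)
        assert all(len(m) == 1 for m in patches.members)

    def test_huge_radius_gives_whole_hemisphere(self, small_mesh):
        patches = build_patches(small_mesh, radius=1e3)
        left = set(np.flatnonzero(small_mesh.hemispheres == "L"))
        assert set(patches.members[min(left)].tolist()) == left

    def test_regular_grid_patch_membership(self):
        """On a 1-cm planar grid a 2-cm searchlight holds 13 lattice points."""
        xs, ys = np.meshgrid(np.arange(-5, 6), np.arange(-5, 6))
        coords = np.column_stack(
            [np.full(xs.size, -1.0), xs.ravel().astype(float), ys.ravel().astype(float)]
        )
        mesh = ns.VertexMesh(
            coordinates=coords,
            hemispheres=np.array(["L"] * len(coords)),
            adjacency=sparse.csr_matrix((len(coords), len(coords)), dtype=bool),
        )
        patches = build_patches(mesh, radius=2.0)
        center = np.flatnonzero((coords[:, 1] == 0) & (coords[:, 2] == 0))[0]
        assert len(patches.members[center]) == 13

    def test_patches_stay_in_hemisphere(self, small_mesh):
        patches = build_patches(small_mesh, radius=5.0)
        for v, members in enumerate(patches.members):
            assert v in members
            assert (
                small_mesh.hemispheres[members] == small_mesh.hemispheres[v]
            ).all()


class TestNeuralDsms:
    def test_identical_patterns_give_zero_entry(self, small_mesh):
        patches = build_patches(small_mesh, radius=4.0)
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, small_mesh.n_vertices, 2))
        data[1] = data[0]
        dsms = neural_dsms(data, patches, bin=0)
        assert dsms[0].values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_patch_advises_larger_radius(self, small_mesh):
        patches = build_patches(small_mesh, radius=1e-6)
        data = np.zeros((4, small_mesh.n_vertices, 1))
        with pytest.raises(ValueError, match="radius"):
            neural_dsms(data, patches, bin=0)


class TestSpearmanComparison:
    def test_self_and_negation(self):
        tri = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        dsm = _dsm_from_triangle(tri, 4)
        assert rsa_spearman(dsm, dsm) == pytest.approx(1.0)
        neg = _dsm_from_triangle(7.0 - tri, 4)
        assert rsa_spearman(dsm, neg) == pytest.approx(-1.0)

    def test_hand_ranked_case(self):
        a = _dsm_from_triangle(np.array([1.0, 2, 3, 4, 5, 6]), 4)
        b = _dsm_from_triangle(np.array([2.0, 1, 3, 4, 5, 6]), 4)
        assert rsa_spearman(a, b) == pytest.approx(0.942857, abs=1e-6)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        tri = rng.random(45)
        a = _dsm_from_triangle(tri, 10)
        b = _dsm_from_triangle(rng.random(45), 10)
        warped = _dsm_from_triangle(np.exp(3 * tri), 10)
        assert rsa_spearman(a, b) == pytest.approx(rsa_spearman(warped, b), abs=1e-12)

    def test_constant_triangle_rejected(self):
        flat = _dsm_from_triangle(np.ones(6), 4)
        other = _dsm_from_triangle(np.arange(6.0), 4)
        with pytest.raises(ValueError, match="constant"):
            rsa_spearman(flat, other)


class TestPartialSpearman:
    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        n = 12
        k = n * (n - 1) // 2
        x, y, z = rng.random(k), rng.random(k), rng.random(k)
        ours = rsa_partial(
            _dsm_from_triangle(x, n), _dsm_from_triangle(y, n), _dsm_from_triangle(z, n)
        )
        ref = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman",
        )["r"].iloc[0]
        assert ours == pytest.approx(float(ref), abs=1e-10)

    def test_uncorrelated_covariate_changes_nothing(self):
        # covariate ranks exactly orthogonal to both: plain and partial agree
        x = np.arange(1.0, 16.0)
        y = x.copy()
        y[[0, 1]] = y[[1, 0]]
        y[[13, 14]] = y[[14, 13]]
        z = np.array([10.0, 3, 15, 8, 6, 11, 4, 7, 5, 1, 13, 12, 14, 2, 9])
        assert abs(np.corrcoef(x, z)[0, 1]) < 1e-12
        assert abs(np.corrcoef(y, z)[0, 1]) < 1e-12
        a, b, c = (_dsm_from_triangle(v, 6) for v in (x, y, z))
        assert rsa_partial(a, b, c) == pytest.approx(rsa_spearman(a, b), abs=1e-12)

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(3)
        x = _dsm_from_triangle(rng.random(6), 4)
        y = _dsm_from_triangle(rng.random(6), 4)
        with pytest.raises(ValueError, match="collinear"):
            rsa_partial(x, y, y)


class TestSearchlightRsa:
    def test_noiseless_recovery_inside_and_outside_patch(
        self, signal_config, small_mesh
    ):
        cfg = dataclasses.replace(signal_config, snr=np.inf)
        table = ns.gen_embedding_table(cfg)
        source, truth = ns.simulate_source_estimates(table, small_mesh, cfg)
        patches = build_patches(small_mesh, radius=4.0)
        model = dsm_correlation(table.vectors)
        active_bins = np.flatnonzero(truth.temporal_profile > 0)
        maps = searchlight_rsa(source, patches, model, bins=active_bins)
        center = truth.active_vertices[0]
        covered = {
            v for v in range(small_mesh.n_vertices)
            if set(patches.members[v]) & set(truth.active_vertices)
        }
        assert maps.data[0, center, 0] > 0.5
        # fully-zero patches outside the active set are undefined markers
        uncovered = sorted(set(range(small_mesh.n_vertices)) - covered)
        assert np.isnan(maps.data[:, uncovered, :]).all()
        group = maps.data.mean(axis=0)
        top_vertex = np.unravel_index(np.nanargmax(group), group.shape)[0]
        assert top_vertex in covered

    def test_deterministic(self, simulated, small_mesh):
        _, source, truth, _ = simulated
        patches = build_patches(small_mesh, radius=4.0)
        model = dsm_correlation(simulated[0].vectors)
        a = searchlight_rsa(source, patches, model, bins=np.array([0]))
        b = searchlight_rsa(source, patches, model, bins=np.array([0]))
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_maps_hover_near_zero(self, small_config, small_mesh):
        cfg = dataclasses.replace(small_config, snr=0.0, n_subjects=20)
        table = ns.gen_embedding_table(cfg)
        source, _ = ns.simulate_source_estimates(table, small_mesh, cfg)
        patches = build_patches(small_mesh, radius=4.0)
        model = dsm_correlation(table.vectors)
        maps = searchlight_rsa(source, patches, model, bins=np.array([0, 5]))
        assert abs(maps.data.mean()) < 0.05


def _enumerate_clusters(t_map, threshold, spatial_adj):
    """Exhaustive oracle: BFS over suprathreshold (vertex, bin) elements with
    mesh-edge spatial moves and same-vertex consecutive-bin temporal moves."""
    n_vert, n_bins = t_map.shape
    above = {(v, b) for v in range(n_vert) for b in range(n_bins)
             if t_map[v, b] > threshold}
    seen, clusters = set(), []
    spatial = {v: set(spatial_adj[v].nonzero()[1]) for v in range(n_vert)}
    for start in sorted(above):
        if start in seen:
            continue
        stack, members = [start], set()
        while stack:
            v, b = stack.pop()
            if (v, b) in seen:
                continue
            seen.add((v, b))
            members.add((v, b))
            for nb in spatial[v]:
                if (nb, b) in above and (nb, b) not in seen:
                    stack.append((nb, b))
            for tb in (b - 1, b + 1):
                if (v, tb) in above and (v, tb) not in seen:
                    stack.append((v, tb))
        clusters.append((members, sum(t_map[v, b] for v, b in members)))
    return clusters


class TestClusterPermutation:
    @staticmethod
    def _chain_adjacency(n):
        adj = sparse.diags([True] * (n - 1), 1, shape=(n, n), dtype=bool)
        return (adj + adj.T).astype(bool).tocsr()

    def test_all_zero_maps_give_empty_set(self):
        maps = np.zeros((5, 6, 3))
        result = cluster_permutation_test(
            maps, self._chain_adjacency(6), n_perm=50, seed=0
        )
        assert result.clusters == []
        assert result.retained == []

    def test_strong_block_is_the_single_retained_cluster(self):
        rng = np.random.default_rng(4)
        maps = 0.1 * rng.standard_normal((10, 12, 6))
        maps[:, 3:6, 2:5] += 2.0  # constant strong positive block
        result = cluster_permutation_test(
            maps, self._chain_adjacency(12), n_perm=300, seed=1
        )
        retained = result.retained
        assert len(retained) == 1
        block = {(v, b) for v in range(3, 6) for b in range(2, 5)}
        found = set(zip(retained[0].vertices.tolist(), retained[0].bins.tolist()))
        assert block <= found

    def test_matches_exhaustive_enumeration_oracle(self):
        """10-vertex, 3-bin, 4-subject toy: cluster membership and statistics
        agree exactly with brute-force connected-component enumeration."""
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((4, 10, 3))
        adj = self._chain_adjacency(10)
        result = cluster_permutation_test(maps, adj, cluster_p=0.2, n_perm=20, seed=2)
        oracle = _enumerate_clusters(
            _observed_t(maps), result.t_threshold, adj
        )
        ours = {
            frozenset(zip(c.vertices.tolist(), c.bins.tolist())): c.stat
            for c in result.clusters
        }
        theirs = {frozenset(m): s for m, s in oracle}
        assert set(ours) == set(theirs)
        for members, stat in theirs.items():
            assert ours[members] == pytest.approx(stat, abs=1e-10)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            cluster_permutation_test(
                np.zeros((1, 4, 2)), self._chain_adjacency(4), n_perm=10
            )


def _observed_t(maps):
    from scipy import stats as sps

    return sps.ttest_1samp(maps, 0.0, axis=0).statistic


class TestMantel:
    def test_identical_dsms(self):
        rng = np.random.default_rng(6)
        dsm = dsm_correlation(rng.standard_normal((15, 8)))
        rho, p = mantel_test(dsm, dsm, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_permuted_copy_consistency(self):
        rng = np.random.default_rng(7)
        dsm = dsm_correlation(rng.standard_normal((12, 6)))
        perm = rng.permutation(12)
        permuted = DSM(values=dsm.values[np.ix_(perm, perm)], metric="correlation")
        rho, _ = mantel_test(dsm, permuted, n_perm=10, seed=0)
        expected = rsa_spearman(dsm, permuted)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_bio(self):
        """Independent oracle for the observed statistic (same Spearman form)."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        a = dsm_correlation(rng.standard_normal((14, 9)))
        b = dsm_correlation(rng.standard_normal((14, 9)))
        rho, _ = mantel_test(a, b, n_perm=10, seed=0)
        ref_rho, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a.values),
            skbio_distance.DistanceMatrix(b.values),
            method="spearman", permutations=0,
        )
        assert rho == pytest.approx(float(ref_rho), abs=1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        a = dsm_correlation(rng.standard_normal((10, 5)))
        b = dsm_correlation(rng.standard_normal((10, 5)))
        assert mantel_test(a, b, n_perm=50, seed=3) == mantel_test(
            a, b, n_perm=50, seed=3
        )
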