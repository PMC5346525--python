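"""Gray-matter cube networks: extraction, similarity, label aggregation."""

import numpy as np
import pytest

from connectodyn import (
    BinaryGraph,
    GrayMatterMap,
    build_similarity_matrix,
    cube_similarity,
    extract_cubes,
    nodal_clustering_by_label,
)
from connectodyn.structural import CUBE_INCLUSION_MIN_VOXELS, CubeSet, _rotation_permutations


def _gm(volume, subject="s", mask=None):
    return GrayMatterMap(subject, np.asarray(volume, float), mask=mask)


def _brute_force_cube_count(vol, threshold):
    count = 0
    nx, ny, nz = (s // 3 for s in vol.shape)
    for cx in range(nx):
        for cy in range(ny):
            for cz in range(nz):
                block = vol[cx * 3 : cx * 3 + 3, cy * 3 : cy * 3 + 3, cz * 3 : cz * 3 + 3]
                if (block > threshold).sum() >= CUBE_INCLUSION_MIN_VOXELS:
                    count += 1
    return count


class TestExtractCubes:
    def test_all_ones_cube_tiling(self):
        cubes = extract_cubes(_gm(np.ones((6, 6, 6))), 0.1)
        assert cubes.n_nodes == 8

    def test_all_zero_volume_raises(self):
        with pytest.raises(ValueError, match="no gray-matter cubes"):
            extract_cubes(_gm(np.zeros((6, 6, 6))), 0.1)

    def test_half_filled_volume_matches_brute_force(self, rng):
        vol = rng.random((12, 9, 15))
        vol[:6] = 0.0  # one hemisphere empty
        cubes = extract_cubes(_gm(vol), 0.1)
        assert cubes.n_nodes == _brute_force_cube_count(vol, 0.1)

    def test_inclusion_rule_boundary(self):
        vol = np.zeros((3, 3, 3))
        flat = vol.reshape(-1)
        flat[: CUBE_INCLUSION_MIN_VOXELS - 1] = 0.5
        with pytest.raises(ValueError):
            extract_cubes(_gm(vol), 0.1)
        flat[CUBE_INCLUSION_MIN_VOXELS - 1] = 0.5
        assert extract_cubes(_gm(vol), 0.1).n_nodes == 1

    def test_value_ordering_is_x_fastest_raster(self):
        vol = np.arange(27.0).reshape(3, 3, 3) / 27.0  # vol[x,y,z]
        cubes = extract_cubes(_gm(vol), 0.0)
        expected = [vol[x, y, z] for z in range(3) for y in range(3) for x in range(3)]
        np.testing.assert_allclose(cubes.values[0], expected)
        np.testing.assert_array_equal(cubes.centers[0], [1, 1, 1])

    def test_mask_excludes_voxels(self):
        vol = np.ones((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        mask[:3, :3, :3] = False  # kills one cube entirely
        cubes = extract_cubes(_gm(vol, mask=mask), 0.1)
        assert cubes.n_nodes == 7


class TestCubeSimilarity:
    def test_identical_and_anticorrelated(self, rng):
        a = rng.random(27)
        assert cube_similarity(a, a) == pytest.approx(1.0)
        assert cube_similarity(a, -a + 2 * a.mean()) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, rng):
        for _ in range(20):
            a, b = rng.random(27), rng.random(27)
            expected = (
                np.sum((a - a.mean()) * (b - b.mean()))
                / (27 * a.std() * b.std())
            )
            assert cube_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self, rng):
        a, b = rng.random(27), rng.random(27)
        base = cube_similarity(a, b)
        assert cube_similarity(3.0 * a + 1.0, b) == pytest.approx(base, abs=1e-10)
        assert cube_similarity(a, 0.2 * b - 5.0) == pytest.approx(base, abs=1e-10)

    def test_zero_variance_cube_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cube_similarity(np.ones(27), np.arange(27.0))

    def test_rotation_group_has_48_elements(self):
        perms = _rotation_permutations()
        assert perms.shape == (48, 27)
        assert all(sorted(p) == list(range(27)) for p in perms)

    def test_rotation_maximization_dominates(self, rng):
        for _ in range(10):
            a, b = rng.random(27), rng.random(27)
            assert cube_similarity(a, b, use_rotations=True) >= cube_similarity(a, b) - 1e-12

    def test_rotated_copy_recovers_unity(self, rng):
        a = rng.random(27)
        perm = _rotation_permutations()[17]
        assert cube_similarity(a, a[perm], use_rotations=True) == pytest.approx(1.0)


class TestSimilarityMatrix:
    def _cubes(self, rng, n=50):
        return CubeSet("s", rng.random((n, 27)), np.zeros((n, 3), int))

    def test_identical_cubes_all_ones(self, rng):
        v = np.tile(rng.random(27), (3, 1))
        m, _ = build_similarity_matrix(CubeSet("s", v, np.zeros((3, 3), int)))
        off = m.weights[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_matches_naive_double_loop(self, rng):
        cubes = self._cubes(rng)
        m, kept = build_similarity_matrix(cubes)
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                if i != j:
                    assert m.weights[i, j] == pytest.approx(
                        cube_similarity(cubes.values[i], cubes.values[j]), abs=1e-12
                    )
        assert np.array_equal(m.weights, m.weights.T)

    def test_rotation_matrix_matches_pairwise_calls(self, rng):
        cubes = self._cubes(rng, n=12)
        m, _ = build_similarity_matrix(cubes, use_rotations=True)
        for i in range(12):
            for j in range(i + 1, 12):
                expected = cube_similarity(
                    cubes.values[i], cubes.values[j], use_rotations=True
                )
                assert m.weights[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_cubes_dropped(self, rng):
        v = rng.random((5, 27))
        v[2] = 0.7
        m, kept = build_similarity_matrix(CubeSet("s", v, np.zeros((5, 3), int)))
        assert m.n_nodes == 4
        assert kept.n_nodes == 4


class TestNodalAggregation:
    def test_single_label_complete_graph(self):
        adj = ~np.eye(4, dtype=bool)
        g = BinaryGraph(adj, density=1.0, subject_id="s")
        centers = np.array([[1, 1, 1]] * 4)
        parc = np.ones((3, 3, 3), int)
        res = nodal_clustering_by_label(g, centers, parc)
        assert res.values[1] == pytest.approx(1.0)

    def test_edgeless_graph_gives_zero(self):
        g = BinaryGraph(np.zeros((4, 4), bool), density=0.0, subject_id="s")
        parc = np.zeros((3, 3, 6), int)
        parc[:, :, :3] = 1
        parc[:, :, 3:] = 2
        centers = np.array([[1, 1, 1], [1, 1, 1], [1, 1, 4], [1, 1, 4]])
        res = nodal_clustering_by_label(g, centers, parc)
        assert res.values[1] == 0.0
        assert res.values[2] == 0.0

    def test_three_parcel_fixture_matches_hand_average(self):
        from connectodyn import clustering_coefficients

        rng = np.random.default_rng(11)
        a = rng.random((9, 9)) < 0.5
        a = np.triu(a, 1)
        a = a | a.T
        g = BinaryGraph(a, density=0.5, subject_id="s")
        parc = np.zeros((9, 3, 3), int)
        parc[0:3] = 1
        parc[3:6] = 2
        parc[6:9] = 3
        centers = np.array([[x, 1, 1] for x in [0, 1, 2, 3, 4, 5, 6, 7, 8]])
        res = nodal_clustering_by_label(g, centers, parc)
        local = clustering_coefficients(g).local
        assert res.values[1] == pytest.approx(local[0:3].mean())
        assert res.values[2] == pytest.approx(local[3:6].mean())
        assert res.values[3] == pytest.approx(local[6:9].mean())

    def test_background_cubes_excluded_and_empty_label_nan(self):
        adj = ~np.eye(3, dtype=bool)
        g = BinaryGraph(adj, density=1.0, subject_id="s")
        parc = np.zeros((3, 3, 3), int)
        parc[2, 2, 2] = 5  # label 5 exists but no cube center there
        centers = np.array([[0, 0, 0], [0, 0, 1], [1, 1, 1]])  # all background
        res = nodal_clustering_by_label(g, centers, parc)
        assert 0 not in res.values
        assert np.isnan(res.values[5])
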