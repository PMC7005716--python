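"""Filtration matrix constructions and weight functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_cloud
from oracles import k_distance_via_power_distance, vr_edges_from_set_definition

from lwph.filtrations import (
    FiltrationMatrix,
    KernelSpec,
    WeightedPointCloud,
    euclidean_matrix,
    infer_bonds,
    interactive_matrix,
    k_distance,
    localized_weighted_matrix,
    multilevel_matrix,
    radius_weighted_matrix,
    rigidity_value,
    superlevel_edge_matrix,
)

TRIANGLE_345 = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float)


class TestEuclidean:
    def test_3_4_5_triangle(self):
        M = euclidean_matrix(WeightedPointCloud(TRIANGLE_345))
        assert sorted(M.values[np.triu_indices(3, 1)]) == [3.0, 4.0, 5.0]

    def test_single_point(self):
        M = euclidean_matrix(WeightedPointCloud([[1.0, 2.0, 3.0]]))
        assert M.values.shape == (1, 1) and M.values[0, 0] == 0

    def test_duplicate_points_allowed(self):
        M = euclidean_matrix(WeightedPointCloud([[0, 0, 0], [0, 0, 0]]))
        assert M.values[0, 1] == 0.0


class TestLocalized:
    def test_same_residue_infinite(self):
        cloud = WeightedPointCloud(TRIANGLE_345, residue_labels=["r1", "r1", "r2"])
        M = localized_weighted_matrix(cloud).values
        assert np.isinf(M[0, 1])
        assert M[0, 2] == 4.0 and M[1, 2] == pytest.approx(np.hypot(3, 4))

    def test_all_one_residue(self):
        cloud = WeightedPointCloud(TRIANGLE_345, residue_labels=["r"] * 3)
        M = localized_weighted_matrix(cloud).values
        assert np.isinf(M[np.triu_indices(3, 1)]).all()

    def test_singleton_residues_reduce_to_euclidean(self):
        cloud = WeightedPointCloud(TRIANGLE_345, residue_labels=["a", "b", "c"])
        assert np.array_equal(
            localized_weighted_matrix(cloud).values, euclidean_matrix(cloud).values
        )

    def test_missing_labels(self):
        with pytest.raises(ValueError):
            localized_weighted_matrix(WeightedPointCloud(TRIANGLE_345))

    def test_entries_dominate_euclidean(self, rng):
        cloud = random_cloud(rng, 12)
        L = localized_weighted_matrix(cloud).values
        E = euclidean_matrix(cloud).values
        assert np.all(L >= E - 1e-12)


class TestMultilevelInteractive:
    def test_bonded_chain(self):
        pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        cloud = WeightedPointCloud(pts, bonds=[(0, 1), (1, 2)])
        M = multilevel_matrix(cloud, "bonded").values
        assert np.isinf(M[0, 1]) and np.isinf(M[1, 2]) and M[0, 2] == 2.0

    def test_level_zero_is_euclidean(self):
        cloud = WeightedPointCloud(TRIANGLE_345)
        assert np.array_equal(
            multilevel_matrix(cloud, "level-n", n=0.0).values, euclidean_matrix(cloud).values
        )

    def test_level_above_diameter_all_infinite(self):
        cloud = WeightedPointCloud(TRIANGLE_345)
        M = multilevel_matrix(cloud, "level-n", n=10.0).values
        assert np.isinf(M[np.triu_indices(3, 1)]).all()

    def test_bonded_requires_bond_list(self):
        with pytest.raises(ValueError):
            multilevel_matrix(WeightedPointCloud(TRIANGLE_345), "bonded")

    def test_interactive_two_molecules(self):
        cloud = WeightedPointCloud([[0, 0, 0], [2, 0, 0]], molecule_labels=["p", "q"])
        assert interactive_matrix(cloud).values[0, 1] == 2.0

    def test_interactive_single_molecule_warns(self):
        cloud = WeightedPointCloud(TRIANGLE_345, molecule_labels=["m"] * 3)
        with pytest.warns(UserWarning):
            M = interactive_matrix(cloud).values
        assert np.isinf(M[np.triu_indices(3, 1)]).all()

    def test_interactive_equals_localized_when_labels_match(self, rng):
        cloud = random_cloud(rng, 10)
        cloud.molecule_labels = cloud.residue_labels
        assert np.array_equal(
            interactive_matrix(cloud).values, localized_weighted_matrix(cloud).values
        )


class TestRadiusWeighted:
    def test_direct_formula(self):
        cloud = WeightedPointCloud([[0, 0, 0], [6, 0, 0]], weights=[1.0, 2.0])
        assert radius_weighted_matrix(cloud).values[0, 1] == pytest.approx(2.0)

    def test_half_weights_reduce_to_euclidean(self, rng):
        cloud = random_cloud(rng, 8)
        cloud.weights = np.full(8, 0.5)
        assert np.allclose(radius_weighted_matrix(cloud).values, euclidean_matrix(cloud).values)

    def test_zero_weight_pair_raises(self):
        cloud = WeightedPointCloud([[0, 0, 0], [1, 0, 0]], weights=[0.0, 0.0])
        with pytest.raises(ZeroDivisionError):
            radius_weighted_matrix(cloud)

    def test_thresholding_matches_set_definition(self, rng):
        for _ in range(5):
            cloud = random_cloud(rng, 10)
            M = radius_weighted_matrix(cloud).values
            for t in rng.uniform(0.5, 6.0, 4):
                ours = {(i, j) for i, j in zip(*np.triu_indices(10, 1)) if M[i, j] <= t}
                brute = vr_edges_from_set_definition(cloud.points, cloud.weights, t)
                assert ours == brute

    def test_rigid_motion_invariance(self, rng):
        from lwph.cehs import rot_axis

        cloud = random_cloud(rng, 9)
        moved = WeightedPointCloud(
            cloud.points @ rot_axis([1, 1, 2], 33.0).T + np.array([5.0, -2.0, 1.0]),
            weights=cloud.weights,
        )
        assert np.allclose(
            radius_weighted_matrix(moved).values,
            radius_weighted_matrix(WeightedPointCloud(cloud.points, weights=cloud.weights)).values,
        )


class TestKDistance:
    def test_line_example(self):
        cloud = WeightedPointCloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert k_distance([0, 0, 0], cloud, 2) == pytest.approx(np.sqrt(0.5))

    def test_k1_is_nearest_neighbor(self, rng):
        cloud = random_cloud(rng, 10)
        q = rng.uniform(0, 4, 3)
        nn = np.min(np.linalg.norm(cloud.points - q, axis=1))
        assert k_distance(q, cloud, 1) == pytest.approx(nn)

    def test_matches_power_distance_identity(self, rng):
        for _ in range(3):
            pts = rng.uniform(0, 3, (8, 3))
            cloud = WeightedPointCloud(pts)
            q = rng.uniform(0, 3, 3)
            for k in (1, 2, 3):
                assert k_distance(q, cloud, k) == pytest.approx(
                    k_distance_via_power_distance(q, pts, k), abs=1e-9
                )

    def test_bad_k(self):
        cloud = WeightedPointCloud([[0, 0, 0]])
        for k in (0, 2):
            with pytest.raises(ValueError):
                k_distance([0, 0, 0], cloud, k)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_lipschitz_in_query(self, seed):
        rng = np.random.default_rng(seed)
        cloud = WeightedPointCloud(rng.uniform(0, 5, (7, 3)))
        q1, q2 = rng.uniform(0, 5, 3), rng.uniform(0, 5, 3)
        lhs = abs(k_distance(q1, cloud, 3) - k_distance(q2, cloud, 3))
        assert lhs <= np.linalg.norm(q1 - q2) + 1e-9


class TestRigidity:
    def test_lorentz_at_eta(self):
        cloud = WeightedPointCloud([[0, 0, 0]], weights=[1.0])
        assert rigidity_value([2.0, 0, 0], cloud, KernelSpec("lorentz", eta=2.0, nu=3)) == pytest.approx(0.5)

    def test_exponential_at_zero_distance(self):
        cloud = WeightedPointCloud([[0, 0, 0], [0, 0, 0]], weights=[1.5, 2.5])
        assert rigidity_value([0, 0, 0], cloud, KernelSpec("exponential")) == pytest.approx(4.0)

    def test_midpoint_of_two_unit_points(self):
        cloud = WeightedPointCloud([[0, 0, 0], [2, 0, 0]], weights=[1.0, 1.0])
        spec = KernelSpec("lorentz", eta=1.0, nu=2.0)
        assert rigidity_value([1, 0, 0], cloud, spec) == pytest.approx(2 * (1 / (1 + 1.0)))

    def test_kernel_validation(self):
        with pytest.raises(ValueError):
            KernelSpec("gauss")
        with pytest.raises(ValueError):
            KernelSpec("lorentz", eta=0.0)


class TestSuperlevelEdges:
    def test_triangle_transform(self):
        W = np.array([[0, 3, 2], [3, 0, 1], [2, 1, 0]], dtype=float)
        M = superlevel_edge_matrix(W)
        assert M.params["w_max"] == 3.0
        assert M.values[0, 1] == 0.0 and M.values[0, 2] == 1.0 and M.values[1, 2] == 2.0
        # at original threshold 2 (transformed scale 1) only weight-3 and weight-2 edges exist
        present = {(i, j) for i, j in zip(*np.triu_indices(3, 1)) if M.values[i, j] <= 1.0}
        assert present == {(0, 1), (0, 2)}

    def test_uniform_weights_enter_together(self):
        W = np.full((4, 4), 2.0)
        np.fill_diagonal(W, 0)
        M = superlevel_edge_matrix(W).values
        assert np.all(M[np.triu_indices(4, 1)] == 0.0)

    def test_beta0_equals_vertex_count_at_start(self):
        from lwph.rips_persistence import barcodes_from_matrix

        W = np.array([[0, 5, np.inf], [5, 0, 2], [np.inf, 2, 0]])
        bc = barcodes_from_matrix(superlevel_edge_matrix(W), max_scale=10)
        assert bc.n_intervals(0) == 3

    def test_negative_weights_rejected(self):
        W = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            superlevel_edge_matrix(W)


class TestMatrixType:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_constructors_produce_valid_matrices(self, seed):
        rng = np.random.default_rng(seed)
        cloud = random_cloud(rng, int(rng.integers(2, 9)))
        cloud.bonds = infer_bonds(cloud, 2.0)
        for M in (
            euclidean_matrix(cloud),
            localized_weighted_matrix(cloud),
            multilevel_matrix(cloud, "bonded"),
            multilevel_matrix(cloud, "level-n", n=1.0),
            radius_weighted_matrix(cloud),
        ):
            v = M.values
            assert np.array_equal(v, v.T)
            assert np.all(np.diag(v) == 0)
            assert np.all(v[np.isfinite(v)] >= 0)

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(ValueError):
            FiltrationMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_csv_round_trip_with_inf(self, tmp_path):
        cloud = WeightedPointCloud(TRIANGLE_345, residue_labels=["r", "r", "s"])
        M = localized_weighted_matrix(cloud)
        path = tmp_path / "m.csv"
        M.save(path)
        R = FiltrationMatrix.load(path)
        assert np.array_equal(R.values, M.values)
        assert R.provenance == "lwph"
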