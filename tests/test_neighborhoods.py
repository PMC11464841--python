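"""Tests for CN windows, compositions, K-means and the Voronoi map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

from imccn import (ValidationError, assign_neighborhoods, composition_vectors,
                   kmeans_cn, knn_windows, voronoi_map)


class TestWindows:
    def test_three_collinear_cells_w1(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        wins = knn_windows(pts, w=1)
        assert [sorted(w.tolist()) for w in wins] == [[0, 1], [0, 1], [1, 2]]
        # the center cell leads each window
        assert [w[0] for w in wins] == [0, 1, 2]

    def test_w_at_least_n_minus_1_includes_everyone(self):
        pts = np.random.default_rng(0).uniform(0, 10, (6, 2))
        wins = knn_windows(pts, w=5)
        assert all(sorted(w.tolist()) == list(range(6)) for w in wins)

    def test_oversized_w_reduced_with_warning(self):
        pts = np.random.default_rng(1).uniform(0, 10, (4, 2))
        with pytest.warns(UserWarning, match="reduced"):
            wins = knn_windows(pts, w=10)
        assert all(len(w) == 4 for w in wins)

    def test_single_cell_image_window_is_self(self):
        with pytest.warns(UserWarning):
            wins = knn_windows(np.array([[3.0, 3.0]]), w=20)
        assert wins[0].tolist() == [0]

    def test_distance_ties_broken_by_cell_index(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        wins = knn_windows(pts, w=1)
        assert wins[0].tolist() == [0, 1]

    def test_windows_do_not_cross_images(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.0], [0.6, 0.0]])
        ids = np.array(["a", "a", "b", "b"])
        wins = knn_windows(pts, w=1, image_ids=ids)
        assert wins[0].tolist() == [0, 1]
        assert wins[2].tolist() == [2, 3]


class TestCompositions:
    def test_hand_fraction(self):
        window = [np.arange(21)]
        types = np.array([0] * 15 + [1] * 6)
        comp = composition_vectors(window, types, 2)
        np.testing.assert_allclose(comp[0], [15 / 21, 6 / 21])

    def test_single_type_rows_one_hot(self):
        pts = np.random.default_rng(2).uniform(0, 50, (10, 2))
        wins = knn_windows(pts, w=3)
        comp = composition_vectors(wins, np.ones(10, dtype=int), 3)
        np.testing.assert_allclose(comp, np.tile([0, 1, 0], (10, 1)))

    @given(seed=st.integers(0, 100))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (15, 2))
        types = rng.integers(0, 4, 15)
        comp = composition_vectors(knn_windows(pts, w=5), types, 4)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)

    def test_out_of_range_type_rejected(self):
        with pytest.raises(ValidationError):
            composition_vectors([np.array([0])], np.array([5]), 2)


class TestKMeansCN:
    def test_two_disjoint_palettes_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.dirichlet([10, 10, 0.2, 0.2], 100)
        b = rng.dirichlet([0.2, 0.2, 10, 10], 100)
        comp = np.vstack([a, b])
        model = kmeans_cn(comp, k=2, seed=4)
        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_k1_single_neighborhood(self):
        comp = np.random.default_rng(5).dirichlet([1, 1, 1], 30)
        model = kmeans_cn(comp, k=1, seed=0)
        assert set(model.labels) == {0}

    def test_fixed_seed_reproducible(self):
        comp = np.random.default_rng(6).dirichlet([1, 1], 50)
        a = kmeans_cn(comp, k=3, seed=11)
        b = kmeans_cn(comp, k=3, seed=11)
        assert np.array_equal(a.labels, b.labels)

    def test_centroids_are_probability_vectors(self):
        comp = np.random.default_rng(7).dirichlet([2, 1, 1], 60)
        model = kmeans_cn(comp, k=4, seed=1)
        assert model.centroids.min() >= 0
        np.testing.assert_allclose(model.centroids.sum(axis=1), 1.0)

    def test_degenerate_compositions_compact_labels(self):
        comp = np.tile([0.5, 0.5], (10, 1))
        with pytest.warns(UserWarning):
            model = kmeans_cn(comp, k=3, seed=0)
        assert model.k == len(np.unique(model.labels))
        assert model.labels.max() == model.k - 1


def test_cn_assignment_invariant_under_rigid_motion():
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 200, (120, 2))
    types = rng.integers(0, 3, 120)
    table = pd.DataFrame({"cell_id": np.arange(120), "image_id": "i",
                          "x": pts[:, 0], "y": pts[:, 1], "phenotype": types})
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = pts @ R.T + [500.0, -40.0]
    table2 = table.assign(x=moved[:, 0], y=moved[:, 1])
    _, m1 = assign_neighborhoods(table, w=10, k=3, seed=5)
    _, m2 = assign_neighborhoods(table2, w=10, k=3, seed=5)
    assert np.array_equal(m1.labels, m2.labels)


class TestVoronoi:
    def test_unit_square_corners_quarter_areas(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        cells = voronoi_map(pts, np.arange(4), (0, 0, 1, 1))
        for c in cells:
            assert c.polygon.area == pytest.approx(0.25)

    def test_partition_sums_to_field_area(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 10, (25, 2))
        cells = voronoi_map(pts, np.zeros(25, dtype=int), (0, 0, 10, 10))
        assert sum(c.polygon.area for c in cells) == pytest.approx(100.0)

    def test_each_cell_covers_its_centroid(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(1, 9, (15, 2))
        cells = voronoi_map(pts, np.zeros(15, dtype=int), (0, 0, 10, 10))
        from shapely.geometry import Point

        for i, c in enumerate(cells):
            assert c.polygon.covers(Point(*pts[i]))

    def test_too_few_or_collinear_suggest_scatter(self):
        with pytest.raises(ValidationError, match="scatter"):
            voronoi_map(np.array([[0.0, 0.0], [1.0, 1.0]]), [0, 1], (0, 0, 2, 2))
        with pytest.raises(ValidationError, match="scatter"):
            voronoi_map(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]),
                        [0, 1, 2], (0, 0, 3, 3))
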