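"""Tests for the permutation interaction test and group tensors."""

import numpy as np
import pandas as pd
import pytest

from imccn import (ValidationError, bh_adjust, group_tensor, knn_windows,
                   neighbor_pairs, permutation_test)


class TestNeighborPairs:
    def test_two_cells_within_radius(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert len(neighbor_pairs(pts, radius=2.0)) == 1

    def test_triangle_gives_three_pairs(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        assert len(neighbor_pairs(pts, radius=2.0)) == 3

    def test_zero_radius_empty(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert len(neighbor_pairs(pts, radius=0.0)) == 0

    def test_window_rule_unique_undirected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        wins = knn_windows(pts, w=1)
        pairs = neighbor_pairs(pts, windows=wins)
        assert pairs.tolist() == [[0, 1], [1, 2]]

    def test_exactly_one_rule_required(self):
        with pytest.raises(ValidationError):
            neighbor_pairs(np.zeros((2, 2)))


def _random_table(n=60, seed=0, n_types=2, extent=100.0, image_id="i"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "x": rng.uniform(0, extent, n), "y": rng.uniform(0, extent, n),
        "phenotype": rng.integers(0, n_types, n), "image_id": image_id,
    })


class TestPermutationTest:
    def test_single_permutation_forces_half_or_one(self):
        tab = _random_table(40, seed=1)
        with pytest.warns(UserWarning, match="low"):
            res = permutation_test(tab, radius=20.0, n_perm=1, seed=2)
        finite = res.p_enrich[np.isfinite(res.p_enrich)]
        assert set(np.round(finite, 6)) <= {0.5, 1.0}

    def test_p_values_never_zero_and_at_most_one(self):
        tab = _random_table(80, seed=3)
        res = permutation_test(tab, radius=15.0, n_perm=199, seed=4)
        for p in (res.p_enrich, res.p_avoid):
            finite = p[np.isfinite(p)]
            assert (finite > 0).all() and (finite <= 1).all()

    def test_separated_blocks_show_avoidance(self):
        """Two spatially separated type blocks: cross-type avoidance."""
        rng = np.random.default_rng(5)
        a = rng.uniform([0, 0], [40, 100], (60, 2))
        b = rng.uniform([200, 0], [240, 100], (60, 2))
        tab = pd.DataFrame({
            "x": np.r_[a[:, 0], b[:, 0]], "y": np.r_[a[:, 1], b[:, 1]],
            "phenotype": np.repeat([0, 1], 60), "image_id": "i"})
        res = permutation_test(tab, radius=25.0, n_perm=999, seed=6)
        assert res.p_avoid[0, 1] <= 0.01
        assert res.p_avoid[1, 0] <= 0.01
        # and same-type contacts are enriched
        assert res.p_enrich[0, 0] <= 0.01

    def test_shuffling_is_stratified_within_image(self):
        # two images with exclusive types: cross-image pairs never exist and
        # within-image shuffles keep each image's type counts
        t1 = _random_table(30, seed=7, image_id="i1").assign(phenotype=0)
        t2 = _random_table(30, seed=8, image_id="i2").assign(phenotype=1)
        tab = pd.concat([t1, t2], ignore_index=True)
        res = permutation_test(tab, radius=20.0, n_perm=99, seed=9)
        # types never co-occur in an image -> cross entries observed 0 with a
        # degenerate null that is also always 0
        assert res.observed[0, 1] == 0
        assert res.null_mean[0, 1] == 0

    def test_absent_type_reported_missing_per_image(self):
        t1 = _random_table(30, seed=10, image_id="i1")
        t2 = _random_table(30, seed=11, image_id="i2").assign(phenotype=0)
        tab = pd.concat([t1, t2], ignore_index=True)
        res = permutation_test(tab, radius=20.0, n_perm=99, seed=12)
        assert np.isnan(res.per_image["i2"][1]).all()
        assert np.isfinite(res.per_image["i1"]).all()

    def test_fixed_seed_reproducible(self):
        tab = _random_table(50, seed=13)
        a = permutation_test(tab, radius=20.0, n_perm=199, seed=14)
        b = permutation_test(tab, radius=20.0, n_perm=199, seed=14)
        np.testing.assert_array_equal(a.p_enrich, b.p_enrich)


def test_bh_adjust_monotone_and_bounded():
    p = np.array([[0.001, 0.02], [0.5, np.nan]])
    adj = bh_adjust(p)
    finite = np.isfinite(p)
    assert (adj[finite] >= p[finite]).all()
    assert np.isnan(adj[~finite]).all()


def _cells(patient, group, cns, types):
    return pd.DataFrame({"patient_id": patient, "group": group,
                         "cn": cns, "phenotype": types})


class TestGroupTensor:
    def test_single_patient_single_entry(self):
        ts = group_tensor(_cells("p1", "punPR", [0] * 10, [0] * 10))
        assert ts.counts.shape == (1, 1, 1)
        assert ts.counts[0, 0, 0] == 10

    def test_marginal_over_cn_equals_type_counts(self):
        rng = np.random.default_rng(15)
        cns = rng.integers(0, 4, 200)
        types = rng.integers(0, 5, 200)
        ts = group_tensor(_cells("p1", "punPD", cns, types))
        np.testing.assert_array_equal(ts.type_marginal()[0],
                                      np.bincount(types, minlength=5))

    def test_unlabeled_cells_excluded_with_warning(self):
        df = _cells("p1", "surPR", [0.0, 1.0, np.nan], [0, 1, 0])
        with pytest.warns(UserWarning, match="unlabeled"):
            ts = group_tensor(df)
        assert ts.counts.sum() == 2

    def test_planted_group_difference_separates_means(self):
        """Two groups with different CN compositions: the group means differ
        in the planted CN by more than the pooled patient SD."""
        rng = np.random.default_rng(16)
        frames = []
        for g, p_cn0 in [("punPR", 0.8), ("punPD", 0.2)]:
            for i in range(4):
                n = 200
                cns = rng.binomial(1, 1 - p_cn0, n)
                types = rng.integers(0, 3, n)
                frames.append(_cells(f"{g}_{i}", g, cns, types))
        ts = group_tensor(pd.concat(frames, ignore_index=True))
        fractions = ts.counts.sum(axis=2) / ts.counts.sum(axis=(1, 2), keepdims=False)[:, None]
        groups = np.array(ts.groups)
        pr = fractions[groups == "punPR", 0]
        pd_ = fractions[groups == "punPD", 0]
        pooled_sd = np.sqrt((pr.var(ddof=1) + pd_.var(ddof=1)) / 2)
        assert abs(pr.mean() - pd_.mean()) > pooled_sd
        means = ts.group_mean_composition()
        assert means["punPR"][0].sum() > means["punPD"][0].sum()

    def test_long_frame_roundtrip(self):
        ts = group_tensor(_cells("p1", "punPR", [0, 1, 1], [0, 0, 1]))
        long = ts.to_long_frame()
        assert long["count"].sum() == 3
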