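import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from topomaps.clustering import (
    dynamic_tree_cut,
    embed_2d,
    hierarchical_average,
    impute_downshift,
    valid_fraction_filter,
    voxel_distance_matrix,
)

from conftest import make_matrix


class TestVoxelDistance:
    def test_complete_profiles_plain_euclidean(self):
        m = make_matrix([[3.0, 0.0], [4.0, 0.0]])
        d = voxel_distance_matrix(m)
        assert d.iloc[0, 1] == pytest.approx(5.0)
        assert d.iloc[0, 0] == 0.0

    def test_pairwise_complete_rescaling(self):
        # 4 proteins, 2 jointly observed, squared diffs sum to 2
        m = make_matrix(
            [
                [1.0, 2.0],
                [2.0, 1.0],
                [np.nan, 5.0],
                [7.0, np.nan],
            ]
        )
        d = voxel_distance_matrix(m)
        assert d.iloc[0, 1] == pytest.approx(2.0)  # sqrt(4/2 * 2)

    def test_identical_profiles_zero(self):
        m = make_matrix([[1.0, 1.0], [2.0, 2.0]])
        assert voxel_distance_matrix(m).iloc[0, 1] == 0.0

    def test_disjoint_observation_named_error(self):
        m = make_matrix([[1.0, np.nan], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="v0.*v1"):
            voxel_distance_matrix(m)


def upgma_oracle(d):
    """Brute-force O(n^3) average-linkage agglomeration; returns merge heights."""
    d = d.astype(float).copy()
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for i, ki in enumerate(keys):
            for kj in keys[i + 1 :]:
                h = np.mean([d[a, b] for a in clusters[ki] for b in clusters[kj]])
                if best is None or h < best[0]:
                    best = (h, ki, kj)
        h, ki, kj = best
        heights.append(h)
        clusters[ki] = clusters[ki] + clusters.pop(kj)
    return heights


class TestUPGMA:
    def test_three_point_hand_example(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        dend = hierarchical_average(d)
        np.testing.assert_allclose(dend.linkage[:, 2], [1.0, 10.0])

    def test_two_points_single_merge(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        dend = hierarchical_average(d)
        assert dend.linkage.shape == (1, 4)
        assert dend.linkage[0, 2] == 3.0

    def test_duplicate_points_merge_at_zero(self):
        d = np.zeros((3, 3))
        dend = hierarchical_average(d)
        assert dend.linkage[0, 2] == 0.0

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            pts = rng.standard_normal((8, 4))
            d = squareform(pdist(pts))
            dend = hierarchical_average(d)
            np.testing.assert_allclose(
                sorted(dend.linkage[:, 2]), sorted(upgma_oracle(d)), rtol=1e-10
            )

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_average(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestDynamicTreeCut:
    def two_blob_dendrogram(self, rng=None):
        rng = rng or np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal(0, 0.5, (20, 3)), rng.normal(20, 0.5, (20, 3))]
        )
        return hierarchical_average(squareform(pdist(pts)))

    def test_two_blobs_recovered_exactly(self):
        dend = self.two_blob_dendrogram()
        ca = dynamic_tree_cut(dend, cut_height=10.0)
        labels = [ca.labels[v] for v in dend.leaves]
        assert ca.n_clusters == 2
        assert adjusted_rand_score([0] * 20 + [1] * 20, labels) == 1.0

    def test_cut_above_root_gives_one_cluster(self):
        dend = self.two_blob_dendrogram()
        ca = dynamic_tree_cut(dend, cut_height=dend.root_height * 2)
        assert ca.n_clusters == 1

    def test_small_branch_absorbed_into_sibling(self):
        # blob of 6 plus an outlying pair: pair < min_cluster_size=3 is absorbed
        d = squareform(
            pdist(np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [0.5], [9.0], [9.1]]))
        )
        dend = hierarchical_average(d)
        ca = dynamic_tree_cut(dend, cut_height=2.0, min_cluster_size=3)
        assert ca.n_clusters == 1
        assert set(ca.labels.values()) == {1}

    def test_min_size_one_equals_static_cut(self):
        dend = self.two_blob_dendrogram(np.random.default_rng(3))
        for h in (0.5, 1.5, 5.0):
            ca = dynamic_tree_cut(dend, cut_height=h, min_cluster_size=1)
            static = hierarchy.fcluster(dend.linkage, t=h, criterion="distance")
            got = [ca.labels[v] for v in dend.leaves]
            assert adjusted_rand_score(static, got) == 1.0

    def test_labels_ordered_by_decreasing_size(self):
        d = squareform(
            pdist(np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2], [5.3], [5.4]]))
        )
        dend = hierarchical_average(d)
        ca = dynamic_tree_cut(dend, cut_height=2.0, min_cluster_size=3)
        sizes = pd.Series(list(ca.labels.values())).value_counts()
        assert sizes[1] >= sizes[2]

    def test_cut_height_validated(self):
        dend = self.two_blob_dendrogram()
        with pytest.raises(ValueError):
            dynamic_tree_cut(dend, cut_height=0)


class TestValidFractionFilter:
    @pytest.mark.parametrize("n_obs,kept", [(69, False), (70, True)])
    def test_seventy_percent_boundary(self, n_obs, kept):
        row = [0.0] * n_obs + [np.nan] * (100 - n_obs)
        out = valid_fraction_filter(make_matrix([row]))
        assert (out.n_proteins == 1) is kept

    def test_zero_fraction_is_identity(self):
        m = make_matrix([[np.nan] * 4, [1.0] * 4])
        assert valid_fraction_filter(m, min_fraction=0).n_proteins == 2

    def test_fully_observed_identity(self):
        m = make_matrix(np.zeros((5, 4)))
        assert valid_fraction_filter(m).n_proteins == 5


class TestImputeDownshift:
    def test_imputed_moments_match_downshifted_normal(self):
        rng = np.random.default_rng(0)
        observed = rng.normal(0.0, 1.0, 200)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        m = make_matrix(col[:, None], normalized=True)
        out = impute_downshift(m, seed=1)
        mu, sigma = observed.mean(), observed.std(ddof=1)
        imputed = out.data.iloc[200:, 0]
        se_mean = 0.3 * sigma / np.sqrt(10_000)
        assert abs(imputed.mean() - (mu - 1.8 * sigma)) < 3 * se_mean
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sigma, rel=0.05)

    def test_observed_entries_bit_identical_and_deterministic(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(30, 5))
        vals[rng.uniform(size=vals.shape) < 0.3] = np.nan
        m = make_matrix(vals)
        out1 = impute_downshift(m, seed=9)
        out2 = impute_downshift(m, seed=9)
        obs = m.data.notna()
        assert out1.data.where(obs).equals(m.data.where(obs))
        assert out1.data.equals(out2.data)

    def test_no_missing_is_identity(self):
        m = make_matrix(np.ones((4, 3)) * 2.5)
        assert impute_downshift(m, seed=0).data.equals(m.data)

    def test_column_with_single_observation_rejected(self):
        m = make_matrix([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="sd undefined"):
            impute_downshift(m, seed=0)


class TestEmbed2D:
    def test_shape_contract(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 3)))
        coords = embed_2d(m, method="pca")
        assert coords.shape == (3, 2)
        assert list(coords.columns) == ["dim1", "dim2"]

    def test_pca_separates_far_blobs(self):
        rng = np.random.default_rng(1)
        blob_a = rng.normal(0, 0.5, (20, 10))
        blob_b = rng.normal(30, 0.5, (20, 10))
        m = make_matrix(np.vstack([blob_a, blob_b]).T)  # proteins x voxels
        coords = embed_2d(m, method="pca").to_numpy()
        a, b = coords[:10], coords[10:]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = np.mean(
            [np.linalg.norm(p - a.mean(0)) for p in a]
            + [np.linalg.norm(p - b.mean(0)) for p in b]
        )
        assert between > within

    def test_pca_preserves_distances_of_rank2_data(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=(12, 2))
        basis = rng.normal(size=(2, 40))
        m = make_matrix((latent @ basis).T)
        coords = embed_2d(m, method="pca").to_numpy()
        np.testing.assert_allclose(
            pdist(coords), pdist(latent @ basis), rtol=1e-8, atol=1e-8
        )

    def test_incomplete_matrix_rejected(self):
        m = make_matrix([[1.0, np.nan], [0.0, 2.0]])
        with pytest.raises(ValueError, match="complete"):
            embed_2d(m, method="pca")
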