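import itertools
import math

import numpy as np
import pytest

from topomaps import markers
from topomaps.clustering import ClusterAssignment
from topomaps.markers import (
    hypergeometric_ora,
    pairwise_volcano,
    read_gmt,
    wilcoxon_one_vs_rest,
)

from conftest import make_matrix


def exact_rank_sum_p(x, y):
    """Enumerate all label assignments of the pooled sample (no ties)."""
    pooled = sorted(x + y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n1n2 = n1 * len(y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    # two-sided: double the smaller tail, capped at 1
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


def two_cluster_assignment(n_a, n_b, voxels):
    labels = {v: (1 if i < n_a else 2) for i, v in enumerate(voxels)}
    return ClusterAssignment(labels, method="test")


class TestWilcoxonOneVsRest:
    def test_extreme_separation_exact_p(self):
        # cluster {6..10} vs rest {1..5}: two-sided exact p = 2/252
        vals = [[6.0, 7, 8, 9, 10, 1, 2, 3, 4, 5]]
        m = make_matrix(vals, ids=["P0"])
        ca = two_cluster_assignment(5, 5, m.voxels)
        res = wilcoxon_one_vs_rest(m, ca)
        row = res[(res.protein_group_id == "P0") & (res.cluster == 1)].iloc[0]
        assert row.p == pytest.approx(2 / 252)
        assert row.median_diff == 5.0

    def test_identical_groups_p_one(self):
        m = make_matrix([[1.0, 2, 3, 1, 2, 3]], ids=["P0"])
        ca = two_cluster_assignment(3, 3, m.voxels)
        res = wilcoxon_one_vs_rest(m, ca)
        assert (res.p == 1.0).all()

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = list(np.round(rng.normal(size=5), 6))
            y = list(np.round(rng.normal(size=6), 6))
            m = make_matrix([x + y], ids=["P0"])
            ca = two_cluster_assignment(5, 6, m.voxels)
            res = wilcoxon_one_vs_rest(m, ca)
            p_pkg = res[res.cluster == 1].iloc[0].p
            assert p_pkg == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_marker_rule_requires_up_direction(self):
        rng = np.random.default_rng(1)
        up = np.concatenate([rng.normal(3, 0.2, 12), rng.normal(0, 0.2, 12)])
        down = -up
        m = make_matrix([up, down], ids=["UP", "DOWN"])
        ca = two_cluster_assignment(12, 12, m.voxels)
        res = wilcoxon_one_vs_rest(m, ca, marker_fdr=0.01)
        by = res.set_index(["protein_group_id", "cluster"])
        assert by.loc[("UP", 1), "is_marker"]
        assert not by.loc[("DOWN", 1), "is_marker"]  # significant but down
        assert by.loc[("DOWN", 2), "is_marker"]

    def test_sparse_side_skipped(self):
        vals = [
            [1.0, np.nan, np.nan, 2.0, 3.0, 4.0],  # one observed value in cluster 1
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        ]
        m = make_matrix(vals, ids=["SPARSE", "FULL"])
        ca = two_cluster_assignment(3, 3, m.voxels)
        res = wilcoxon_one_vs_rest(m, ca)
        assert "SPARSE" not in set(res.protein_group_id)
        assert set(res[res.protein_group_id == "FULL"].cluster) == {1, 2}

    def test_requires_two_clusters(self):
        m = make_matrix([[1.0, 2.0]])
        ca = ClusterAssignment({v: 1 for v in m.voxels}, "test")
        with pytest.raises(ValueError):
            wilcoxon_one_vs_rest(m, ca)


class TestPairwiseVolcano:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        m = make_matrix([np.concatenate([base, base])], ids=["P0"])
        ca = two_cluster_assignment(10, 10, m.voxels)
        res = pairwise_volcano(m, ca, 1, 2)
        assert res.iloc[0].log2_fc == pytest.approx(0.0)
        assert res.iloc[0].p > 0.9

    def test_planted_two_unit_shift_is_significant(self):
        rng = np.random.default_rng(3)
        shifted = np.concatenate(
            [rng.normal(2.0, 0.3, 20), rng.normal(0.0, 0.3, 20)]
        )
        nulls = rng.normal(0.0, 0.3, (30, 40))
        m = make_matrix(np.vstack([shifted, nulls]), ids=["HIT"] + [f"N{i}" for i in range(30)])
        ca = two_cluster_assignment(20, 20, m.voxels)
        res = pairwise_volcano(m, ca, 1, 2).set_index("protein_group_id")
        assert res.loc["HIT", "significant"]
        assert res.loc["HIT", "log2_fc"] == pytest.approx(2.0, abs=0.3)

    def test_one_sided_observation_excluded(self):
        vals = [[1.0, 2.0, 3.0] + [np.nan] * 3, [1.0] * 6]
        m = make_matrix(vals, ids=["AONLY", "BOTH"])
        ca = two_cluster_assignment(3, 3, m.voxels)
        res = pairwise_volcano(m, ca, 1, 2)
        assert "AONLY" not in set(res.protein_group_id)

    def test_unknown_cluster_rejected(self):
        m = make_matrix(np.ones((1, 4)))
        ca = two_cluster_assignment(2, 2, m.voxels)
        with pytest.raises(ValueError, match="unknown cluster"):
            pairwise_volcano(m, ca, 1, 9)


class TestReadGMT:
    def test_two_sets_with_dedup(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text(
            "SET_A\tdesc\tTP53\tegfr\tTP53\nSET_B\tdesc\tMYC\n"
        )
        coll = read_gmt(p)
        assert len(coll) == 2
        assert coll["SET_A"] == {"TP53", "EGFR"}

    def test_empty_member_list_warns_but_kept(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("EMPTY_SET\tdesc\n")
        with pytest.warns(UserWarning, match="no members"):
            coll = read_gmt(p)
        assert coll["EMPTY_SET"] == frozenset()

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("GOOD\tdesc\tA\nJUSTONE\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)


def hypergeom_tail_oracle(k, N, K, n):
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
        for j in range(k, min(K, n) + 1)
    )


class TestHypergeometricORA:
    def make_collection(self, **sets):
        return markers.GeneSetCollection(
            {k: frozenset(v) for k, v in sets.items()}, {k: "" for k in sets}
        )

    def test_hand_example(self):
        # N=10, K=5, n=4, k=4 -> p = C(5,4)/C(10,4) = 5/210
        bg = [f"G{i}" for i in range(10)]
        coll = self.make_collection(S=bg[:5])
        res = hypergeometric_ora({1: bg[:4]}, coll, bg)
        assert res.iloc[0].p == pytest.approx(5 / 210)
        assert res.iloc[0].k == 4

    def test_zero_overlap_p_one(self):
        bg = [f"G{i}" for i in range(10)]
        coll = self.make_collection(S=bg[5:])
        res = hypergeometric_ora({1: bg[:3]}, coll, bg)
        assert res.iloc[0].p == pytest.approx(1.0)

    def test_tail_matches_brute_force(self):
        bg = [f"G{i}" for i in range(30)]
        coll = self.make_collection(S=bg[:12])
        for k in range(0, 9):
            query = bg[:k] + bg[12 : 12 + (8 - k)]
            res = hypergeometric_ora({1: query}, coll, bg)
            assert res.iloc[0].p == pytest.approx(
                hypergeom_tail_oracle(k, 30, 12, 8), rel=1e-12
            )

    def test_p_monotone_decreasing_in_k(self):
        ps = [hypergeom_tail_oracle(k, 30, 10, 8) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_disjoint_set_skipped_with_warning(self):
        bg = ["A", "B", "C"]
        coll = self.make_collection(S=["X", "Y"])
        with pytest.warns(UserWarning, match="disjoint"):
            res = hypergeometric_ora({1: ["A"]}, coll, bg)
        assert res.empty

    def test_empty_background_rejected(self):
        coll = self.make_collection(S=["A"])
        with pytest.raises(ValueError, match="background"):
            hypergeometric_ora({1: ["A"]}, coll, [])

    def test_planted_overexpressed_set_has_smallest_q(self, default_dataset):
        """The set of planted region-1 markers tops that cluster's enrichment."""
        norm, grid, _, truth = default_dataset
        ca = ClusterAssignment(
            {v: truth.region_labels[v] for v in norm.voxels}, "truth"
        )
        marker_df = wilcoxon_one_vs_rest(norm, ca)
        by_cluster = markers.marker_genes_by_cluster(marker_df)
        region1 = [
            p
            for p, c in truth.protein_classes.items()
            if c["kind"] == "marker" and c["region"] == 1
        ]
        rng = np.random.default_rng(0)
        background = [p.primary_gene() for p in norm.proteins]
        decoy = list(rng.choice(background, size=30, replace=False))
        coll = self.make_collection(REGION1=region1, DECOY=decoy)
        res = hypergeometric_ora(by_cluster, coll, background)
        c1 = res[res.cluster == 1].set_index("set_name")
        assert c1.loc["REGION1", "q"] == c1["q"].min()
        assert c1.loc["REGION1", "significant"]
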