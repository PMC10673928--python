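"""Self-contained validation measurements for the pipeline's statistics.

Each function regenerates its inputs (synthetic data or random instances),
runs the relevant pipeline stages, and returns the measured quantity —
oracle agreement for Moran's I, permutation-null calibration, planted-truth
recovery rates on the default synthetic conditions, eigengap accuracy, and
imputation moments.  Both the test suite and ``scripts/acceptance.py`` call
these, so every reported number is computed at run time.
"""

from __future__ import annotations

import numpy as np

from . import anf, clustering, feature_distance, grid_io, spatial_stats, synthetic
from .clustering import ClusterAssignment
from .grid_io import VoxelGrid, voxel_id
from .markers import wilcoxon_one_vs_rest
from .spatial_stats import (
    build_queen_neighbors,
    morans_i,
    morans_i_permutation_test,
)

__all__ = [
    "full_grid",
    "moran_oracle_max_abs_diff",
    "moran_null_calibration",
    "permutation_mean_offset",
    "eigengap_accuracy",
    "imputation_moment_errors",
    "recovery_suite",
]


def full_grid(n_rows: int, n_cols: int) -> VoxelGrid:
    positions = {voxel_id(r, c): (r, c) for r in range(n_rows) for c in range(n_cols)}
    return VoxelGrid(n_rows, n_cols, 1.0, positions)


def _moran_double_loop(x: np.ndarray, g) -> float:
    """Literal double-sum Moran's I (the independent oracle)."""
    n = len(x)
    xbar = x.mean()
    w = g.adjacency.toarray()
    num = sum(
        w[i, j] * (x[i] - xbar) * (x[j] - xbar) for i in range(n) for j in range(n)
    )
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / w.sum()) * num / den


def moran_oracle_max_abs_diff(n_instances: int = 100, seed: int = 0) -> float:
    """Largest |vectorised - double-loop| Moran's I over random 6x6 fields."""
    g = build_queen_neighbors(full_grid(6, 6))
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        x = rng.standard_normal(g.n)
        worst = max(worst, abs(morans_i(x, g) - _moran_double_loop(x, g)))
    return worst


def moran_null_calibration(
    n_proteins: int = 2000, shape: tuple[int, int] = (10, 10),
    n_perm: int = 199, alpha: float = 0.05, seed: int = 0,
) -> float:
    """Fraction of i.i.d.-Gaussian fields called at p <= alpha (should be ~alpha)."""
    g = build_queen_neighbors(full_grid(*shape))
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_proteins):
        x = rng.standard_normal(g.n)
        res = morans_i_permutation_test(
            x, g, n_perm=n_perm, seed=np.random.default_rng([seed, i])
        )
        hits += res.p_perm <= alpha
    return hits / n_proteins


def permutation_mean_offset(
    n_perm: int = 20000, shape: tuple[int, int] = (6, 6), seed: int = 0
) -> dict:
    """Permutation mean of I versus the null expectation -1/(n-1), in MC SEs."""
    g = build_queen_neighbors(full_grid(*shape))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(g.n)
    z = x - x.mean()
    vals = spatial_stats._permuted_moran(z, g, n_perm, rng)
    expected = -1.0 / (g.n - 1)
    se = float(vals.std(ddof=1) / np.sqrt(n_perm))
    return {
        "mean": float(vals.mean()),
        "expected": expected,
        "se": se,
        "offset_in_se": float(abs(vals.mean() - expected) / se),
    }


def eigengap_accuracy(k_range: range = range(2, 9)) -> float:
    """Fraction of noiseless block-diagonal affinities whose k is recovered."""
    import warnings

    correct = 0
    for k in k_range:
        sizes = [5 + i for i in range(k)]
        n = sum(sizes)
        A = np.zeros((n, n))
        s = 0
        for sz in sizes:
            A[s : s + sz, s : s + sz] = 1.0
            s += sz
        am = anf.AffinityMatrix(tuple(f"v{i}" for i in range(n)), A)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            correct += anf.eigengap_select_k(am) == k
    return correct / len(k_range)


def imputation_moment_errors(n_missing: int = 10_000, seed: int = 0) -> dict:
    """Downshifted-normal imputation moments vs the (mu-1.8s, 0.3s) target."""
    rng = np.random.default_rng(seed)
    observed = rng.normal(0.0, 1.0, 500)
    col = np.concatenate([observed, np.full(n_missing, np.nan)])
    import pandas as pd

    from .grid_io import ProteinMeta, ProteinQuantMatrix

    ids = [f"P{i}" for i in range(col.size)]
    m = ProteinQuantMatrix(
        pd.DataFrame(col[:, None], index=ids, columns=["v0"]),
        [ProteinMeta(i) for i in ids],
        normalized=True,
    )
    out = clustering.impute_downshift(m, seed=seed + 1)
    mu, sigma = observed.mean(), observed.std(ddof=1)
    imputed = out.data.iloc[500:, 0].to_numpy()
    se_mean = 0.3 * sigma / np.sqrt(n_missing)
    se_sd = 0.3 * sigma / np.sqrt(2 * n_missing)
    return {
        "mean": float(imputed.mean()),
        "target_mean": float(mu - 1.8 * sigma),
        "mean_offset_in_se": float(abs(imputed.mean() - (mu - 1.8 * sigma)) / se_mean),
        "sd": float(imputed.std(ddof=1)),
        "target_sd": float(0.3 * sigma),
        "sd_offset_in_se": float(abs(imputed.std(ddof=1) - 0.3 * sigma) / se_sd),
    }


def recovery_suite(seeds=(0, 1, 2, 3, 4), n_perm: int = 999) -> dict:
    """Planted-truth recovery on the default synthetic conditions.

    For each seed: generate the default 16x16 / 300-protein dataset, run the
    Moran screen (q <= 0.05 calls on smooth fields and nulls), ANF clustering
    (ARI vs the planted regions), the one-vs-rest marker screen against the
    true region labels (1% FDR), and the vessel-distance correlation ranking
    (planted gradients vs the 95th percentile of non-gradient |rho|).
    Detection/recovery rates are pooled over seeds; ARI is reported per seed.
    """
    from sklearn.metrics import adjusted_rand_score

    field_calls = []
    null_calls = []
    aris = []
    marker_hits = []
    gradient_hits = []
    for seed in seeds:
        m, grid, features, truth = synthetic.generate(seed=seed)
        norm = grid_io.filter_min_voxels(grid_io.normalize(m))

        results, _ = spatial_stats.batch_moran(norm, grid, n_perm=n_perm, seed=seed)
        frame = spatial_stats.moran_results_to_frame(results).set_index(
            "protein_group_id"
        )
        fields = [p for p in truth.proteins_of_class("field") if p in frame.index]
        nulls = [p for p in truth.proteins_of_class("null") if p in frame.index]
        field_calls += list(frame.loc[fields, "q"] <= 0.05)
        null_calls += list(frame.loc[nulls, "q"] <= 0.05)

        labels, _ = anf.anf_cluster(norm, grid, seed=seed)
        order = norm.voxels
        aris.append(
            adjusted_rand_score(
                [truth.region_labels[v] for v in order], labels.label_array(order)
            )
        )

        truth_assignment = ClusterAssignment(
            {v: truth.region_labels[v] for v in order}, method="planted"
        )
        marker_df = wilcoxon_one_vs_rest(norm, truth_assignment, marker_fdr=0.01)
        called = set(marker_df[marker_df.is_marker].protein_group_id)
        marker_hits += [p in called for p in truth.proteins_of_class("marker")]

        dmap = feature_distance.distance_to_features(grid, truth.features)
        corr = feature_distance.correlate_with_distance(norm, dmap).set_index(
            "protein_group_id"
        )
        grads = [p for p in truth.proteins_of_class("gradient") if p in corr.index]
        others = corr.index.difference(grads)
        threshold = np.percentile(corr.loc[others, "rho"].abs(), 95)
        gradient_hits += list(corr.loc[grads, "rho"].abs() > threshold)

    return {
        "field_detection_rate": float(np.mean(field_calls)),
        "null_false_positive_rate": float(np.mean(null_calls)),
        "anf_ari_per_seed": [float(a) for a in aris],
        "anf_ari_min": float(min(aris)),
        "marker_recovery_rate": float(np.mean(marker_hits)),
        "gradient_top_rank_rate": float(np.mean(gradient_hits)),
        "n_seeds": len(list(seeds)),
    }
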