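"""Spatially-unaware voxel clustering and embedding preprocessing.

Voxels are clustered on their protein profiles alone: pairwise-complete
Euclidean distances between voxel columns, average-linkage (UPGMA)
hierarchical clustering, and a top-down dynamic tree cut (static cut at a
height, small branches absorbed into their nearest sibling).  For 2-D
visualisation the matrix is first restricted to proteins with >= 70% valid
values, remaining gaps are filled by downshifted-normal draws (width 0.3,
downshift 1.8 column-sd units — the usual proteomics convention for
left-censored missingness), and a neighbour embedding (UMAP) or a
deterministic PCA fallback maps voxels to the plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .grid_io import ProteinQuantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "voxel_distance_matrix",
    "hierarchical_average",
    "dynamic_tree_cut",
    "valid_fraction_filter",
    "impute_downshift",
    "embed_2d",
]


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge history over a set of voxels.

    ``linkage`` is a scipy linkage matrix (n-1 rows of
    [left, right, height, size]); ``leaves`` are the voxel ids in input
    order.
    """

    linkage: np.ndarray
    leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.linkage.shape != (len(self.leaves) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2]) if len(self.linkage) else 0.0


@dataclass
class ClusterAssignment:
    """Voxel -> cluster labelling (positive integers; 0 = unassigned)."""

    labels: dict[str, int]
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len({l for l in self.labels.values() if l > 0})

    def members(self, label: int) -> list[str]:
        return [v for v, l in self.labels.items() if l == label]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")

    def label_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[v] for v in order])


def relabel_by_size(raw: Mapping[str, int], order: Sequence[str]) -> dict[str, int]:
    """Relabel clusters 1..K by decreasing size, ties by first member index."""
    first_index = {v: i for i, v in enumerate(order)}
    groups: dict[int, list[str]] = {}
    for v, l in raw.items():
        groups.setdefault(l, []).append(v)
    ranked = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), min(first_index[v] for v in kv[1])),
    )
    mapping = {old: new for new, (old, _) in enumerate(ranked, start=1)}
    return {v: mapping[l] for v, l in raw.items()}


def voxel_distance_matrix(m: ProteinQuantMatrix) -> pd.DataFrame:
    """Pairwise-complete Euclidean distances between voxel profiles.

    For voxels a, b with P proteins in the matrix and P_valid jointly
    observed, d = sqrt(P / P_valid * sum_valid (a_k - b_k)^2) — missing
    entries are skipped and the sum rescaled, the convention of standard
    dist functions on matrices with NAs.
    """
    if not m.normalized:
        raise ValueError("voxel_distance_matrix expects a normalized matrix")
    X = m.values  # proteins x voxels
    P, V = X.shape
    if V < 2:
        raise ValueError("need at least 2 voxels")
    mask = np.isfinite(X).astype(float)
    X0 = np.nan_to_num(X)
    joint = mask.T @ mask
    sq = X0 * X0
    # sum over jointly-observed proteins of a^2, b^2 and a*b
    a2 = sq.T @ mask
    cross = X0.T @ X0
    ss = a2 + a2.T - 2.0 * cross
    if np.any(joint == 0):
        i, j = np.argwhere(joint == 0)[0]
        raise ValueError(
            f"voxels {m.voxels[i]!r} and {m.voxels[j]!r} share no observed protein"
        )
    with np.errstate(invalid="ignore"):
        d = np.sqrt(np.maximum(P / joint * ss, 0.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=m.voxels, columns=m.voxels)


def hierarchical_average(d: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix."""
    if isinstance(d, pd.DataFrame):
        leaves = tuple(str(c) for c in d.columns)
        arr = d.to_numpy(dtype=float)
    else:
        arr = np.asarray(d, dtype=float)
        leaves = tuple(str(i) for i in range(arr.shape[0]))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T) or np.any(arr < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")
    Z = hierarchy.linkage(squareform(arr, checks=False), method="average")
    return Dendrogram(Z, leaves)


def _static_cut(dend: Dendrogram, cut_height: float) -> dict[str, int]:
    flat = hierarchy.fcluster(dend.linkage, t=cut_height, criterion="distance")
    return {v: int(l) for v, l in zip(dend.leaves, flat)}


def dynamic_tree_cut(
    dend: Dendrogram, cut_height: float = 100.0, min_cluster_size: int = 3
) -> ClusterAssignment:
    """Top-down ("tree" variant) dynamic cut of a dendrogram.

    A static cut at ``cut_height`` defines candidate branches; branches with
    fewer than ``min_cluster_size`` leaves are then absorbed into their
    nearest sibling (smallest mean cophenetic distance), repeatedly, until
    all clusters meet the minimum or a single cluster remains.  Labels are
    1..K in decreasing cluster size.
    """
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    if dend.n_leaves < min_cluster_size:
        raise ValueError("dendrogram smaller than min_cluster_size")
    labels = _static_cut(dend, cut_height)
    if min_cluster_size > 1:
        coph = squareform(hierarchy.cophenet(dend.linkage))
        index = {v: i for i, v in enumerate(dend.leaves)}
        while True:
            sizes: dict[int, int] = {}
            for l in labels.values():
                sizes[l] = sizes.get(l, 0) + 1
            small = [l for l, s in sizes.items() if s < min_cluster_size]
            if not small or len(sizes) == 1:
                break
            l_small = min(small, key=lambda l: sizes[l])
            members = [index[v] for v, l in labels.items() if l == l_small]
            best, best_d = None, np.inf
            for other in sizes:
                if other == l_small:
                    continue
                others = [index[v] for v, l in labels.items() if l == other]
                md = float(coph[np.ix_(members, others)].mean())
                if md < best_d:
                    best, best_d = other, md
            for v in list(labels):
                if labels[v] == l_small:
                    labels[v] = best
    labels = relabel_by_size(labels, dend.leaves)
    return ClusterAssignment(
        labels,
        method="dynamic_tree_cut",
        params={"cut_height": cut_height, "min_cluster_size": min_cluster_size},
    )


def valid_fraction_filter(
    m: ProteinQuantMatrix, min_fraction: float = 0.70
) -> ProteinQuantMatrix:
    """Remove proteins observed in fewer than ``min_fraction`` of voxels."""
    if not m.normalized:
        raise ValueError("valid_fraction_filter expects a normalized matrix")
    frac = m.data.notna().mean(axis=1)
    keep = frac.index[frac >= min_fraction].tolist()
    return m.subset_proteins(keep)


def impute_downshift(
    m: ProteinQuantMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> ProteinQuantMatrix:
    """Fill missing entries with draws from a downshifted normal, per voxel.

    For each voxel column with observed mean mu and sd sigma, missing entries
    are drawn i.i.d. from Normal(mu - downshift*sigma, (width*sigma)^2),
    mimicking the left-censored tail of undetected low-abundance proteins.
    Observed entries are untouched; results are reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    out = m.data.copy()
    for col in out.columns:
        colvals = out[col]
        miss = colvals.isna()
        if not miss.any():
            continue
        obs = colvals.dropna()
        if obs.size < 2:
            raise ValueError(
                f"voxel {col!r} has {obs.size} observed value(s); "
                "sd undefined for imputation"
            )
        mu, sigma = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - downshift * sigma, width * sigma, size=int(miss.sum()))
        out.loc[miss, col] = draws
    return ProteinQuantMatrix(out, list(m.proteins), m.normalized)


def embed_2d(
    m: ProteinQuantMatrix,
    method: str = "umap",
    seed: int = 0,
    **params,
) -> pd.DataFrame:
    """2-D voxel embedding of a complete (imputed) matrix.

    ``method="umap"`` uses the UMAP neighbour embedding (default settings)
    if the optional ``umap-learn`` backend is installed; ``method="pca"`` is
    a deterministic fallback (first two principal components).  Coordinates
    are for visualisation only — no downstream statistic depends on them.
    Returns a DataFrame indexed by voxel with columns ``dim1, dim2``.
    """
    if m.data.isna().any().any():
        raise ValueError("embed_2d requires a complete (imputed) matrix")
    X = m.values.T  # voxels x proteins
    if method == "umap":
        try:
            import umap  # noqa: F401  (optional backend)
        except ImportError as exc:
            raise ImportError(
                "umap-learn is not installed; use method='pca' for the "
                "deterministic PCA fallback"
            ) from exc
        reducer = umap.UMAP(n_components=2, random_state=seed, **params)
        coords = reducer.fit_transform(X)
    elif method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed, **params).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=m.voxels, columns=["dim1", "dim2"])
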