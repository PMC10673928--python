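"""Spatially-aware voxel clustering by affinity network fusion (ANF).

Two complementary views of the voxel set are built: a proteomic view
(Spearman rank correlation of the top-variance proteins, distance
D = 1 - rho) and a spatial view (grid-unit Euclidean distance between voxel
centres, adjacent = 1, diagonal = sqrt(2)).  Each distance matrix is turned
into a non-negative affinity with a locally-scaled Gaussian kernel
A_ij = exp(-D_ij^2 / (sigma_i sigma_j)), sigma_i = mean distance from i to
its k nearest neighbours.  The one-step two-view ANF update fuses the views:
each view's affinity is row-normalised to a transition matrix, k-NN
sparsified into a local kernel S_v, and the fused network is
sum_v w_v * S_v @ Pbar_{-v} @ S_v^T (equal weights by default), symmetrised.
Cluster number is chosen by the maximal eigengap of the symmetric-normalised
Laplacian and the final labels come from normalised spectral clustering.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .clustering import ClusterAssignment, relabel_by_size
from .grid_io import ProteinQuantMatrix, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityMatrix",
    "select_variable_proteins",
    "proteomic_affinity",
    "spatial_affinity",
    "fuse_affinities",
    "eigengap_select_k",
    "spectral_cluster",
    "anf_cluster",
    "matrisome_restricted_anf",
]


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric non-negative voxel x voxel affinity matrix."""

    nodes: tuple[str, ...]
    A: np.ndarray
    view: str = "proteomic"

    def __post_init__(self) -> None:
        a = self.A
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("affinity shape does not match node count")
        if not np.allclose(a, a.T):
            raise ValueError("affinity must be symmetric")
        if np.any(a < 0):
            raise ValueError("affinities must be non-negative")

    @property
    def n(self) -> int:
        return len(self.nodes)


def default_k_nn(n: int) -> int:
    """ANF neighbourhood size: max(10, n/10), capped at n - 1."""
    return min(max(10, round(n / 10)), n - 1)


def select_variable_proteins(
    m: ProteinQuantMatrix, fraction: float = 0.25
) -> ProteinQuantMatrix:
    """Keep the ceil(fraction * P) proteins of highest observed-value variance.

    Ties at the cutoff are broken lexicographically by protein id.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if not m.normalized:
        raise ValueError("select_variable_proteins expects a normalized matrix")
    var = m.data.var(axis=1, ddof=1, skipna=True).fillna(-np.inf)
    n_keep = math.ceil(fraction * m.n_proteins)
    order = sorted(var.index, key=lambda pid: (-var[pid], pid))
    return m.subset_proteins(order[:n_keep])


def _local_scale_kernel(D: np.ndarray, k_nn: int) -> np.ndarray:
    """Locally-scaled Gaussian affinity from a distance matrix."""
    n = D.shape[0]
    k = min(k_nn, n - 1)
    # mean distance to the k nearest neighbours, excluding self
    part = np.sort(D + np.diag(np.full(n, np.inf)), axis=1)[:, :k]
    sigma = part.mean(axis=1)
    sigma = np.maximum(sigma, 1e-12)
    A = np.exp(-(D**2) / np.outer(sigma, sigma))
    A = (A + A.T) / 2.0
    return A


def _spearman_distance(m: ProteinQuantMatrix) -> np.ndarray:
    """1 - Spearman rank correlation between voxel profiles (pairwise-complete)."""
    df = m.data  # proteins x voxels
    min_joint = 3
    joint = df.notna().astype(int).T @ df.notna().astype(int)
    if (joint.to_numpy() < min_joint).any():
        bad = np.argwhere(joint.to_numpy() < min_joint)[0]
        raise ValueError(
            f"voxels {df.columns[bad[0]]!r} and {df.columns[bad[1]]!r} share "
            f"fewer than {min_joint} observed proteins"
        )
    rho = df.corr(method="spearman", min_periods=min_joint).to_numpy()
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    return np.maximum((D + D.T) / 2.0, 0.0)


def proteomic_affinity(
    m: ProteinQuantMatrix, k_nn: int | None = None
) -> AffinityMatrix:
    """Affinity view from Spearman correlation of voxel protein profiles."""
    if m.data.shape[1] < 3:
        raise ValueError("need at least 3 voxels")
    D = _spearman_distance(m)
    k = k_nn if k_nn is not None else default_k_nn(D.shape[0])
    return AffinityMatrix(tuple(m.voxels), _local_scale_kernel(D, k), "proteomic")


def spatial_affinity(
    grid: VoxelGrid, nodes: Sequence[str] | None = None, k_nn: int | None = None
) -> AffinityMatrix:
    """Affinity view from grid-unit Euclidean distances between voxel centres.

    Horizontally/vertically adjacent voxels are distance 1, diagonal
    neighbours sqrt(2), and so on.
    """
    if nodes is None:
        nodes = grid.included_voxels()
    if len(nodes) < 2:
        raise ValueError("need at least 2 voxels")
    xy = grid.coords(nodes)
    diff = xy[:, None, :] - xy[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    k = k_nn if k_nn is not None else default_k_nn(len(nodes))
    return AffinityMatrix(tuple(nodes), _local_scale_kernel(D, k), "spatial")


def _row_normalize(A: np.ndarray) -> np.ndarray:
    rs = A.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return A / rs


def _knn_transition(A: np.ndarray, k_nn: int) -> np.ndarray:
    """Row-stochastic local kernel keeping each row's k largest affinities."""
    n = A.shape[0]
    k = min(k_nn, n - 1)
    S = np.zeros_like(A)
    masked = A - np.diag(np.diag(A))
    for i in range(n):
        nn = np.argpartition(masked[i], -k)[-k:]
        S[i, nn] = masked[i, nn]
    return _row_normalize(S)


def fuse_affinities(
    views: Sequence[AffinityMatrix],
    k_nn: int | None = None,
    weights: Sequence[float] | None = None,
) -> AffinityMatrix:
    """One-step affinity network fusion of multiple views.

    Each view is row-normalised into a full transition matrix P_v and
    k-NN-sparsified into a local transition matrix S_v; the fused network is
    sum_v w_v * S_v @ Pbar @ S_v^T with Pbar the unweighted mean of all
    views' full transition matrices, equal view weights by default, and the
    result symmetrised.  Diffusing over the mean network (rather than over
    the other views alone) keeps each view's own structure in its term, so
    an uninformative (all-equal) view degrades the fusion gracefully instead
    of erasing the informative view.  A single view yields its own smoothed
    transition matrix S @ P @ S^T.
    """
    if not views:
        raise ValueError("need at least one view")
    nodes = views[0].nodes
    for v in views[1:]:
        if v.nodes != nodes:
            raise ValueError("views must share an identical node set")
    n = len(nodes)
    k = k_nn if k_nn is not None else default_k_nn(n)
    if weights is None:
        w = np.full(len(views), 1.0 / len(views))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(views):
            raise ValueError("one weight per view required")
        if not np.isclose(w.sum(), 1.0):
            warnings.warn("view weights do not sum to 1; renormalising", stacklevel=2)
            w = w / w.sum()
    P = [_row_normalize(v.A) for v in views]
    S = [_knn_transition(v.A, k) for v in views]
    p_mean = np.mean(P, axis=0)
    fused = np.zeros((n, n))
    for i in range(len(views)):
        fused += w[i] * (S[i] @ p_mean @ S[i].T)
    fused = (fused + fused.T) / 2.0
    return AffinityMatrix(nodes, fused, "fused")


def _sym_laplacian_eigs(A: np.ndarray) -> np.ndarray:
    deg = A.sum(axis=1)
    deg = np.maximum(deg, 1e-300)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(A.shape[0]) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    return linalg.eigvalsh(L)


def eigengap_select_k(A: AffinityMatrix, k_min: int = 2, k_max: int = 15) -> int:
    """Choose the cluster number at the maximal Laplacian eigengap.

    Eigenvalues of the symmetric-normalised Laplacian are taken in ascending
    order; the returned k maximises lambda_{k+1} - lambda_k over
    [k_min, k_max].  A disconnected affinity graph short-circuits to its
    number of connected components (with a warning).
    """
    n_comp, _ = connected_components(A.A > 0, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"affinity graph has {n_comp} connected components", stacklevel=2
        )
        return int(n_comp)
    lam = _sym_laplacian_eigs(A.A)
    hi = min(k_max, A.n - 1)
    if k_min > hi:
        raise ValueError("k_min exceeds usable range")
    gaps = lam[k_min : hi + 1] - lam[k_min - 1 : hi]
    return int(k_min + np.argmax(gaps))


def spectral_cluster(A: AffinityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Normalised spectral clustering of an affinity matrix into k clusters.

    Voxels are embedded in the k eigenvectors of the symmetric-normalised
    Laplacian with smallest eigenvalues, row-normalised to the unit sphere,
    and partitioned by seeded k-means (50 restarts) — deterministic given
    the seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > A.n:
        raise ValueError(f"k={k} exceeds node count {A.n}")
    deg = np.maximum(A.A.sum(axis=1), 1e-300)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(A.n) - d_inv_sqrt[:, None] * A.A * d_inv_sqrt[None, :]
    _, vecs = linalg.eigh(L, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = vecs / norms
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(U)
    raw = {v: int(l) + 1 for v, l in zip(A.nodes, km.labels_)}
    labels = relabel_by_size(raw, A.nodes)
    return ClusterAssignment(labels, method="spectral", params={"k": k, "seed": seed})


def anf_cluster(
    m: ProteinQuantMatrix,
    grid: VoxelGrid,
    fraction: float = 0.25,
    k_nn: int | None = None,
    k: int | None = None,
    k_min: int = 2,
    k_max: int = 15,
    weights: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[ClusterAssignment, dict]:
    """Full spatially-aware ANF pipeline on a normalized matrix.

    Selects the top-variance proteins, builds the proteomic and spatial
    affinity views over the matrix's voxels, fuses them, selects k by the
    eigengap heuristic (unless given) and spectrally clusters.  Returns the
    assignment and a run record (chosen k, k_nn, eigenvalues).
    """
    selected = select_variable_proteins(m, fraction)
    nodes = list(m.voxels)
    knn = k_nn if k_nn is not None else default_k_nn(len(nodes))
    prot = proteomic_affinity(selected, k_nn=knn)
    spat = spatial_affinity(grid, nodes=nodes, k_nn=knn)
    fused = fuse_affinities([prot, spat], k_nn=knn, weights=weights)
    lam = _sym_laplacian_eigs(fused.A)
    chosen = k if k is not None else eigengap_select_k(fused, k_min, k_max)
    assignment = spectral_cluster(fused, chosen, seed=seed)
    record = {
        "n_voxels": len(nodes),
        "n_proteins_used": selected.n_proteins,
        "k_nn": knn,
        "k": chosen,
        "weights": list(weights) if weights is not None else None,
        "laplacian_eigenvalues": lam[: min(20, len(lam))].tolist(),
    }
    return assignment, record


def matrisome_restricted_anf(
    m: ProteinQuantMatrix,
    grid: VoxelGrid,
    matrisome_ids: Sequence[str],
    fraction: float = 1.0,
    **kwargs,
) -> tuple[ClusterAssignment, dict]:
    """ANF clustering with the proteomic view restricted to a protein list.

    ``matrisome_ids`` is a user-supplied annotation list (gene symbols or
    protein-group ids, e.g. a core-matrisome catalogue).  All listed detected
    proteins enter the similarity computation (no variance selection);
    voxels observing none of the listed proteins are dropped and reported in
    the run record.
    """
    wanted = {s.upper() for s in matrisome_ids}
    keep = [
        p.protein_group_id
        for p in m.proteins
        if p.protein_group_id.upper() in wanted or p.primary_gene() in wanted
    ]
    if not keep:
        raise ValueError("annotation list has no overlap with the matrix")
    restricted = m.subset_proteins(keep)
    observed_any = restricted.data.notna().any(axis=0)
    dropped = observed_any.index[~observed_any].tolist()
    if dropped:
        logger.warning(
            "dropping %d voxel(s) with no observed listed protein: %s",
            len(dropped),
            dropped,
        )
        restricted = restricted.subset_voxels(observed_any.index[observed_any].tolist())
    assignment, record = anf_cluster(restricted, grid, fraction=fraction, **kwargs)
    record["restricted_to"] = len(keep)
    record["voxels_dropped_no_listed_protein"] = dropped
    for v in dropped:
        assignment.labels[v] = 0
    return assignment, record
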