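"""Moran's I spatial autocorrelation with permutation pseudo-p-values.

Global Moran's I on a binary Queen's-case contiguity graph is the workhorse
test for spatially variable proteins on an LCM voxel grid:

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with w_ij = 1 iff voxels i and j share an edge or a vertex (Queen's case),
W = sum_ij w_ij.  I is near +1 for spatially clustered values, near -1 for
dispersed (checkerboard) values, and has null expectation -1/(n-1) under
random arrangement.  Significance is assessed by random spatial permutation
(999 permutations by default) with the pseudo-p convention
p = (1 + #exceedances) / (1 + n_perm), upper tail, followed by
Benjamini-Hochberg adjustment across proteins.

Missing values: each protein is tested on the subgraph induced by its
observed voxels; observed voxels left without any observed neighbour are
dropped (``n_used`` reflects the drop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from .grid_io import ProteinQuantMatrix, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "MoranResult",
    "build_queen_neighbors",
    "morans_i",
    "morans_i_permutation_test",
    "bh_adjust",
    "batch_moran",
    "moran_results_to_frame",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric binary spatial weights over a set of voxels.

    ``adjacency`` is a CSR boolean/0-1 matrix aligned with ``nodes``;
    ``W`` is the total weight (twice the undirected edge count).
    """

    nodes: tuple[str, ...]
    adjacency: sparse.csr_matrix

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValueError("adjacency shape does not match node count")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-weights are not allowed (w_ii must be 0)")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def W(self) -> float:
        return float(self.adjacency.sum())

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


def _queen_adjacency(coords: np.ndarray) -> sparse.csr_matrix:
    """0/1 adjacency for Queen's-case contiguity given integer (row, col)."""
    dr = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
    dc = np.abs(coords[:, 1][:, None] - coords[:, 1][None, :])
    adj = np.maximum(dr, dc) == 1  # shares an edge or a vertex
    np.fill_diagonal(adj, False)
    return sparse.csr_matrix(adj.astype(np.int8))


def build_queen_neighbors(
    grid: VoxelGrid,
    observed: Iterable[str] | None = None,
    warn_isolated: bool = True,
) -> NeighborGraph:
    """Build the binary Queen's-case neighbour graph over observed voxels.

    Two voxels are neighbours iff their (row, col) coordinates differ by at
    most 1 in each direction (and are not identical) — i.e. they share an
    edge or a vertex.  Voxels with no observed neighbour are dropped with a
    warning; fewer than 2 observed voxels is an error.
    """
    if observed is None:
        nodes = grid.included_voxels()
    else:
        allowed = set(grid.included_voxels())
        nodes = [v for v in observed if v in allowed]
        stray = set(observed) - allowed
        if stray:
            raise ValueError(f"observed voxels not on grid or excluded: {sorted(stray)}")
    if len(nodes) < 2:
        raise ValueError("need at least 2 observed voxels to build a graph")
    adj = _queen_adjacency(grid.coords(nodes))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if (deg == 0).any():
        isolated = [nodes[i] for i in np.flatnonzero(deg == 0)]
        log = logger.warning if warn_isolated else logger.debug
        log("dropping %d isolated voxel(s): %s", len(isolated), isolated)
        keep = np.flatnonzero(deg > 0)
        nodes = [nodes[i] for i in keep]
        if len(nodes) < 2:
            raise ValueError("fewer than 2 connected voxels remain")
        adj = adj[np.ix_(keep, keep)].tocsr()
    return NeighborGraph(tuple(nodes), adj)


def morans_i(x: Sequence[float] | np.ndarray, g: NeighborGraph) -> float:
    """Global Moran's I of values ``x`` indexed by ``g.nodes``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (g.n,):
        raise ValueError(f"expected {g.n} values, got {x.shape}")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance: Moran's I undefined for constant values")
    cross = float(z @ (g.adjacency @ z))
    return (g.n / g.W) * cross / denom


@dataclass
class MoranResult:
    """Per-protein Moran test outcome."""

    protein_group_id: str
    n_used: int
    I: float
    p_perm: float
    q: float = np.nan
    gene_name: str = ""


def _permuted_moran(
    z: np.ndarray, g: NeighborGraph, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Moran's I for n_perm random rearrangements of centred values z."""
    n = z.size
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = z[rng.permutation(n)]
    cross = np.einsum("ij,ij->i", perms @ g.adjacency.T, perms)
    denom = float(z @ z)
    return (n / g.W) * cross / denom


def morans_i_permutation_test(
    x: Sequence[float] | np.ndarray,
    g: NeighborGraph,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    protein_group_id: str = "",
) -> MoranResult:
    """Upper-tail permutation test for Moran's I.

    The pseudo-p-value is ``(1 + b) / (1 + n_perm)`` where b counts random
    spatial rearrangements whose I meets or exceeds the observed I.  The same
    seed always yields the same result.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    i_obs = morans_i(x, g)
    z = x - x.mean()
    i_perm = _permuted_moran(z, g, n_perm, rng)
    b = int(np.sum(i_perm >= i_obs))
    p = (1 + b) / (1 + n_perm)
    return MoranResult(protein_group_id, g.n, i_obs, p)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def batch_moran(
    m: ProteinQuantMatrix,
    grid: VoxelGrid,
    n_perm: int = 999,
    seed: int = 0,
    min_voxels: int = 9,
) -> tuple[list[MoranResult], pd.DataFrame]:
    """Permutation-test every protein for spatial autocorrelation.

    For each protein the Queen graph is rebuilt on the voxels where that
    protein is observed; proteins failing the preconditions are collected as
    untested with a reason.  q-values are BH over all tested proteins.
    Per-protein RNG streams derive from ``(seed, protein index)`` so results
    do not depend on protein order.

    Returns
    -------
    (results, untested) where ``untested`` is a DataFrame with columns
    ``protein_group_id, reason``.
    """
    if not m.normalized:
        raise ValueError("batch_moran expects a normalized matrix")
    results: list[MoranResult] = []
    untested: list[tuple[str, str]] = []
    obs_mask = m.observed()
    for idx, meta in enumerate(m.proteins):
        pid = meta.protein_group_id
        row = m.data.loc[pid]
        voxels = obs_mask.columns[obs_mask.loc[pid]].tolist()
        if len(voxels) < min_voxels:
            untested.append((pid, "min_voxels"))
            continue
        try:
            g = build_queen_neighbors(grid, voxels, warn_isolated=False)
        except ValueError:
            untested.append((pid, "no_graph"))
            continue
        if g.n < min_voxels:
            untested.append((pid, "min_voxels"))
            continue
        x = row.loc[list(g.nodes)].to_numpy()
        if np.ptp(x) == 0:
            untested.append((pid, "zero_variance"))
            continue
        rng = np.random.default_rng([seed, idx])
        res = morans_i_permutation_test(x, g, n_perm=n_perm, seed=rng, protein_group_id=pid)
        res.gene_name = meta.gene_name
        results.append(res)
    if results:
        q = bh_adjust([r.p_perm for r in results])
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results, pd.DataFrame(untested, columns=["protein_group_id", "reason"])


def moran_results_to_frame(results: list[MoranResult]) -> pd.DataFrame:
    """Tabulate Moran results (protein, gene, n_used, I, p_perm, q)."""
    return pd.DataFrame(
        {
            "protein_group_id": [r.protein_group_id for r in results],
            "gene_name": [r.gene_name for r in results],
            "n_used": [r.n_used for r in results],
            "moran_I": [r.I for r in results],
            "p_perm": [r.p_perm for r in results],
            "q": [r.q for r in results],
        }
    )
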