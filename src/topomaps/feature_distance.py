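"""Distance-to-feature maps and protein gradient statistics.

Given point features on the grid (e.g. blood-vessel centres supplied as a
coordinate table), each voxel gets the Euclidean distance from its centre to
the nearest feature, in grid units and micrometres.  Proteins are screened
for monotone association with that distance (Spearman correlation,
BH-adjusted), a proxy for nutrient/oxygen gradients around vasculature.
Aggregate per-voxel abundance maps of a protein set (e.g. summed or mean
core-matrisome signal) use observed values only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid_io import ProteinQuantMatrix, VoxelGrid
from .spatial_stats import bh_adjust

__all__ = [
    "DistanceMap",
    "distance_to_features",
    "correlate_with_distance",
    "aggregate_set_abundance",
]


@dataclass(frozen=True)
class DistanceMap:
    """Per-voxel distance to the nearest feature point.

    ``grid_units`` maps voxel_id -> distance in voxel-side units; ``um``
    is the same scaled by the grid's voxel side length.
    """

    grid_units: dict[str, float]
    um: dict[str, float]
    features: tuple[tuple[float, float], ...]

    def as_series(self, scale: str = "grid") -> pd.Series:
        d = self.grid_units if scale == "grid" else self.um
        return pd.Series(d, name=f"distance_{scale}")


def distance_to_features(
    grid: VoxelGrid, features: Sequence[tuple[float, float]]
) -> DistanceMap:
    """Minimum Euclidean distance from each voxel centre to any feature.

    Features are (row, col) points in grid coordinates; fractional
    coordinates are allowed.  Excluded voxels are omitted.
    """
    if len(features) == 0:
        raise ValueError("need at least one feature point")
    pts = np.asarray(features, dtype=float).reshape(-1, 2)
    if (
        (pts[:, 0] < -0.5).any()
        or (pts[:, 0] > grid.n_rows - 0.5).any()
        or (pts[:, 1] < -0.5).any()
        or (pts[:, 1] > grid.n_cols - 0.5).any()
    ):
        raise ValueError("feature point outside grid bounds")
    nodes = grid.included_voxels()
    xy = grid.coords(nodes)
    diffs = xy[:, None, :] - pts[None, :, :]
    d = np.sqrt((diffs**2).sum(axis=2)).min(axis=1)
    grid_units = {v: float(di) for v, di in zip(nodes, d)}
    um = {v: float(di) * grid.voxel_side for v, di in zip(nodes, d)}
    return DistanceMap(grid_units, um, tuple(map(tuple, pts)))


def correlate_with_distance(
    m: ProteinQuantMatrix, dmap: DistanceMap, min_voxels: int = 9
) -> pd.DataFrame:
    """Spearman correlation of each protein's abundance with feature distance.

    Proteins with fewer than ``min_voxels`` observed values on mapped voxels
    are skipped; two-sided p-values are BH-adjusted across tested proteins.

    Returns columns protein_group_id, gene_name, n_used, rho, p, q.
    """
    if not m.normalized:
        raise ValueError("correlate_with_distance expects a normalized matrix")
    dist = dmap.as_series("grid")
    common = [v for v in m.voxels if v in dist.index]
    if len(set(dist.loc[common])) < 2:
        raise ValueError("distance vector is constant over the matrix voxels")
    rows = []
    for meta in m.proteins:
        vals = m.data.loc[meta.protein_group_id, common].dropna()
        if vals.size < min_voxels:
            continue
        rho, p = stats.spearmanr(vals.to_numpy(), dist.loc[vals.index].to_numpy())
        rows.append(
            {
                "protein_group_id": meta.protein_group_id,
                "gene_name": meta.gene_name,
                "n_used": int(vals.size),
                "rho": float(rho),
                "p": float(min(max(p, np.nextafter(0, 1)), 1.0)),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    return result


def aggregate_set_abundance(
    m: ProteinQuantMatrix, protein_set: Sequence[str], stat: str = "sum"
) -> pd.Series:
    """Per-voxel summed or mean abundance of a protein set (observed only).

    ``protein_set`` entries match protein-group ids or (first) gene symbols,
    case-insensitively.  Voxels observing none of the set's proteins are
    missing (NaN) in the returned Series.
    """
    if stat not in ("sum", "mean"):
        raise ValueError("stat must be 'sum' or 'mean'")
    wanted = {s.upper() for s in protein_set}
    keep = [
        p.protein_group_id
        for p in m.proteins
        if p.protein_group_id.upper() in wanted or p.primary_gene() in wanted
    ]
    if not keep:
        raise ValueError("protein set has no overlap with the matrix")
    sub = m.data.loc[keep]
    any_obs = sub.notna().any(axis=0)
    agg = sub.sum(axis=0, skipna=True) if stat == "sum" else sub.mean(axis=0, skipna=True)
    agg[~any_obs] = np.nan
    agg.name = f"{stat}_abundance"
    return agg
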