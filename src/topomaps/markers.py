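"""Cluster marker statistics and gene-set overrepresentation.

Markers of a voxel cluster are proteins with higher abundance inside the
cluster than in all remaining voxels: a two-sided Wilcoxon rank-sum test per
(protein, cluster) pair, BH-adjusted jointly, with the marker call requiring
q <= 1% AND a positive cluster-minus-rest median difference.  Marker lists
are then tested for overrepresentation of gene sets (GMT collections, e.g.
MSigDB Hallmark) with a one-sided hypergeometric test against the full set
of detected proteins as background, BH within each cluster's set family.
A pairwise Welch-t volcano between two chosen clusters rounds out the
between-region comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment
from .grid_io import ProteinQuantMatrix
from .spatial_stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "wilcoxon_one_vs_rest",
    "pairwise_volcano",
    "read_gmt",
    "hypergeometric_ora",
    "marker_genes_by_cluster",
]

_EXACT_MAX_N = 25


@dataclass(frozen=True)
class GeneSetCollection:
    """Named sets of uppercase gene symbols parsed from a GMT file."""

    sets: Mapping[str, frozenset]
    descriptions: Mapping[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    tie/continuity-corrected normal approximation otherwise."""
    n = x.size + y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n
    method = "exact" if (n <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    # fully tied data yields an undefined normal approximation: no evidence
    return 1.0 if not np.isfinite(p) else min(max(p, np.nextafter(0, 1)), 1.0)


def wilcoxon_one_vs_rest(
    m: ProteinQuantMatrix,
    labels: ClusterAssignment,
    marker_fdr: float = 0.01,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker screen over all clusters.

    Each protein is tested in each cluster against all other clustered
    voxels (two-sided); tests with fewer than 2 observed values on either
    side are skipped.  BH runs jointly over all protein x cluster tests.
    The ``is_marker`` column applies the marker rule: q <= ``marker_fdr``
    and positive cluster-minus-rest median difference.

    Returns a DataFrame with columns protein_group_id, gene_name, cluster,
    n_in, n_out, median_diff, p, q, is_marker.
    """
    clusters = sorted({l for l in labels.labels.values() if l > 0})
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    voxel_labels = pd.Series(labels.labels)
    voxel_labels = voxel_labels[voxel_labels > 0]
    voxel_labels = voxel_labels[voxel_labels.index.isin(m.voxels)]
    rows = []
    for meta in m.proteins:
        series = m.data.loc[meta.protein_group_id, voxel_labels.index]
        for cl in clusters:
            x = series[voxel_labels == cl].dropna().to_numpy()
            y = series[voxel_labels != cl].dropna().to_numpy()
            if x.size < 2 or y.size < 2:
                logger.debug(
                    "skipping %s / cluster %d: too few observed values",
                    meta.protein_group_id,
                    cl,
                )
                continue
            rows.append(
                {
                    "protein_group_id": meta.protein_group_id,
                    "gene_name": meta.gene_name,
                    "cluster": cl,
                    "n_in": x.size,
                    "n_out": y.size,
                    "median_diff": float(np.median(x) - np.median(y)),
                    "p": _rank_sum_p(x, y),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["is_marker"] = (result["q"] <= marker_fdr) & (result["median_diff"] > 0)
    return result


def marker_genes_by_cluster(markers: pd.DataFrame) -> dict[int, list[str]]:
    """Per-cluster lists of marker gene symbols (first symbol, uppercased)."""
    out: dict[int, list[str]] = {}
    for cl, grp in markers[markers["is_marker"]].groupby("cluster"):
        genes = (
            grp["gene_name"]
            .map(lambda g: g.split(";")[0].strip().upper())
            .replace("", np.nan)
            .dropna()
            .unique()
            .tolist()
        )
        out[int(cl)] = genes
    return out


def pairwise_volcano(
    m: ProteinQuantMatrix,
    labels: ClusterAssignment,
    cluster_a: int,
    cluster_b: int,
    fdr: float = 0.05,
    fc_line: float = 2.0,
) -> pd.DataFrame:
    """Welch-t volcano statistics between two clusters.

    Per protein with >= 3 observed values in each cluster: two-sided Welch
    t-test and log2 fold-change (mean_A - mean_B on the already-log2 data);
    BH across tested proteins; ``significant`` flags q <= fdr and
    |log2FC| >= log2(fc_line).
    """
    present = {l for l in labels.labels.values() if l > 0}
    for cl in (cluster_a, cluster_b):
        if cl not in present:
            raise ValueError(f"unknown cluster label {cl}")
    voxel_labels = pd.Series(labels.labels)
    in_a = voxel_labels.index[voxel_labels == cluster_a]
    in_b = voxel_labels.index[voxel_labels == cluster_b]
    in_a = [v for v in in_a if v in m.voxels]
    in_b = [v for v in in_b if v in m.voxels]
    rows = []
    for meta in m.proteins:
        a = m.data.loc[meta.protein_group_id, in_a].dropna().to_numpy()
        b = m.data.loc[meta.protein_group_id, in_b].dropna().to_numpy()
        if a.size < 3 or b.size < 3:
            logger.debug("excluding %s from volcano", meta.protein_group_id)
            continue
        t = stats.ttest_ind(a, b, equal_var=False)
        p = float(t.pvalue)
        if not np.isfinite(p):  # zero variance on both sides
            p = 1.0
        rows.append(
            {
                "protein_group_id": meta.protein_group_id,
                "gene_name": meta.gene_name,
                "log2_fc": float(a.mean() - b.mean()),
                "t": float(t.statistic) if np.isfinite(t.statistic) else 0.0,
                "p": min(max(p, np.nextafter(0, 1)), 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = (result["q"] <= fdr) & (
        result["log2_fc"].abs() >= np.log2(fc_line)
    )
    return result


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, members per line).

    Member symbols are uppercased and deduplicated; empty member lists are
    retained (K = 0) with a warning; malformed lines raise with the line
    number.
    """
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line {lineno}: need name and description")
            name, desc, *members = parts
            members = [g.strip().upper() for g in members if g.strip()]
            if not members:
                warnings.warn(f"gene set {name!r} has no members", stacklevel=2)
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def hypergeometric_ora(
    markers: Mapping[int, Sequence[str]],
    sets: GeneSetCollection,
    background: Sequence[str],
    fdr: float = 0.05,
    family: str = "per-cluster",
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of gene sets per cluster.

    For each (cluster, set): background N = detected genes, set size
    K = |set ∩ background|, query n = |cluster markers ∩ background|,
    overlap k; p = P[X >= k] for X ~ Hypergeom(N, K, n).  BH is applied
    within each cluster's family of sets (``family="per-cluster"``, the
    default) or globally (``family="global"``).

    Returns columns cluster, set_name, k, K, n, N, p, q, significant.
    """
    bg = {g.upper() for g in background if g}
    if not bg:
        raise ValueError("background is empty")
    N = len(bg)
    rows = []
    for cl, genes in markers.items():
        query = {g.upper() for g in genes} & bg
        n = len(query)
        for name in sets.names():
            members = sets[name] & bg
            K = len(members)
            if K == 0:
                warnings.warn(
                    f"gene set {name!r} is disjoint from the background; skipped",
                    stacklevel=2,
                )
                continue
            k = len(query & members)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append(
                {
                    "cluster": cl,
                    "set_name": name,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": min(p, 1.0),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    if family == "per-cluster":
        result["q"] = np.nan
        for cl in result["cluster"].unique():
            sel = result["cluster"] == cl
            result.loc[sel, "q"] = bh_adjust(result.loc[sel, "p"].to_numpy())
    elif family == "global":
        result["q"] = bh_adjust(result["p"].to_numpy())
    else:
        raise ValueError(f"unknown BH family {family!r}")
    result["significant"] = result["q"] <= fdr
    return result
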