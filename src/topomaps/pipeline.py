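"""End-to-end orchestration: config, stage execution, exports, run record.

``run_full`` executes the analysis graph on a protein table + grid mapping
(or on a freshly generated synthetic dataset): ingest -> normalise/filter ->
Moran screen -> tree-cut clustering -> ANF clustering -> markers -> ORA ->
optional distance analysis -> exports.  Every stage logs protein/voxel
counts into a machine-readable run record so the analysis funnel is
auditable and reproducible from the record alone.

Map orientation for all exports: row 0 at the top, col 0 at the left.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anf as anf_mod
from . import clustering, feature_distance, grid_io, markers, spatial_stats, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full", "export_protein_map"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str
    protein_table: str | None = None
    dialect: str = "maxquant"
    mapping: str | None = None
    n_rows: int = 16
    n_cols: int = 16
    voxel_side: float = 833.0
    exclusions: str | None = None
    gmt: str | None = None
    features: str | None = None
    annotation_list: str | None = None
    synthetic: bool = False
    synthetic_params: dict = field(default_factory=dict)
    seed: int = 0
    min_voxels: int = 9
    n_perm: int = 999
    cut_height: float = 100.0
    min_cluster_size: int = 3
    valid_fraction: float = 0.70
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    embed_method: str = "pca"
    anf_fraction: float = 0.25
    anf_k: int | None = None
    anf_k_min: int = 2
    anf_k_max: int = 15
    marker_fdr: float = 0.01
    ora_fdr: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("protein_table", "mapping"):
                val = getattr(self, name)
                if val is None:
                    raise ValueError(f"config requires {name} unless synthetic: true")
                if not Path(val).exists():
                    raise FileNotFoundError(f"{name}: {val}")
        for name in ("exclusions", "gmt", "features", "annotation_list"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{name}: {val}")


def _load_inputs(config: RunConfig):
    if config.synthetic:
        syn_cfg = synthetic.SyntheticConfig(**config.synthetic_params)
        raw, grid, features, truth = synthetic.generate(syn_cfg, seed=config.seed)
        # synthetic data are already voxel-indexed
        keep = [v for v in raw.voxels if v not in grid.excluded]
        return raw.subset_voxels(keep), grid, features, truth
    raw = grid_io.read_protein_table(config.protein_table, dialect=config.dialect)
    grid = grid_io.load_grid(
        config.mapping,
        config.n_rows,
        config.n_cols,
        config.voxel_side,
        exclusions=config.exclusions,
    )
    raw = grid_io.join_grid(raw, grid)
    features = None
    if config.features is not None:
        features = pd.read_csv(config.features)
    return raw, grid, features, None


def run_full(config: RunConfig) -> Path:
    """Execute all pipeline stages; returns the run directory.

    A stage failure aborts with the stage name in the exception; outputs of
    completed stages are retained.  ``record.json`` in the run directory
    holds parameters, the seed and per-stage row counts.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record: dict = {"config": asdict(config), "seed": config.seed, "stages": {}}
    stage = "ingest"
    try:
        raw, grid, features, truth = _load_inputs(config)
        grid.to_json(out / "grid.json")
        record["stages"][stage] = {
            "proteins": raw.n_proteins,
            "voxels": len(raw.voxels),
        }

        stage = "normalize_filter"
        norm = grid_io.normalize(raw)
        norm = grid_io.filter_min_voxels(norm, config.min_voxels)
        grid_io.write_matrix_tsv(norm, out / "normalized_matrix.tsv")
        record["stages"][stage] = {
            "proteins": norm.n_proteins,
            "voxels": len(norm.voxels),
        }

        stage = "moran"
        results, untested = spatial_stats.batch_moran(
            norm, grid, n_perm=config.n_perm, seed=config.seed,
            min_voxels=config.min_voxels,
        )
        moran_df = spatial_stats.moran_results_to_frame(results)
        moran_df.to_csv(out / "moran.tsv", sep="\t", index=False)
        untested.to_csv(out / "moran_untested.tsv", sep="\t", index=False)
        record["stages"][stage] = {
            "tested": len(results),
            "untested": len(untested),
            "significant_q05": int((moran_df["q"] <= 0.05).sum()) if len(results) else 0,
        }

        stage = "tree_cut_clustering"
        d = clustering.voxel_distance_matrix(norm)
        dend = clustering.hierarchical_average(d)
        tree_labels = clustering.dynamic_tree_cut(
            dend, cut_height=config.cut_height,
            min_cluster_size=config.min_cluster_size,
        )
        _write_assignment(tree_labels, grid, out / "clusters_tree.tsv")
        record["stages"][stage] = {"clusters": tree_labels.n_clusters}

        stage = "embedding"
        filtered = clustering.valid_fraction_filter(norm, config.valid_fraction)
        embedding_info = {"proteins_after_70pct": filtered.n_proteins}
        if filtered.n_proteins >= 2:
            imputed = clustering.impute_downshift(
                filtered, width=config.impute_width,
                downshift=config.impute_downshift, seed=config.seed,
            )
            coords = clustering.embed_2d(
                imputed, method=config.embed_method, seed=config.seed
            )
            coords.to_csv(out / "embedding.tsv", sep="\t", index_label="voxel_id")
            embedding_info["method"] = config.embed_method
        else:
            embedding_info["skipped"] = "too few proteins after 70% filter"
        record["stages"][stage] = embedding_info

        stage = "anf"
        anf_labels, anf_record = anf_mod.anf_cluster(
            norm, grid, fraction=config.anf_fraction, k=config.anf_k,
            k_min=config.anf_k_min, k_max=config.anf_k_max, seed=config.seed,
        )
        _write_assignment(anf_labels, grid, out / "clusters_anf.tsv")
        record["stages"][stage] = anf_record

        stage = "markers"
        if tree_labels.n_clusters < 2:
            marker_df = pd.DataFrame()
            record["stages"][stage] = {"skipped": "fewer than 2 clusters"}
        else:
            marker_df = markers.wilcoxon_one_vs_rest(
                norm, tree_labels, marker_fdr=config.marker_fdr
            )
            marker_df.to_csv(out / "markers.tsv", sep="\t", index=False)
            record["stages"][stage] = {
                "tests": len(marker_df),
                "markers": int(marker_df["is_marker"].sum()) if len(marker_df) else 0,
            }

        stage = "enrichment"
        if marker_df.empty:
            record["stages"][stage] = {"skipped": "no marker tests available"}
        elif config.gmt is not None:
            sets = markers.read_gmt(config.gmt)
            background = [
                p.primary_gene() for p in norm.proteins if p.primary_gene()
            ]
            by_cluster = markers.marker_genes_by_cluster(marker_df)
            enr = markers.hypergeometric_ora(
                by_cluster, sets, background, fdr=config.ora_fdr
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            record["stages"][stage] = {
                "tests": len(enr),
                "significant": int(enr["significant"].sum()) if len(enr) else 0,
            }
        else:
            record["stages"][stage] = {"skipped": "no GMT collection supplied"}

        stage = "distance"
        if features is not None and len(features):
            pts = list(zip(features["row"], features["col"]))
            dmap = feature_distance.distance_to_features(grid, pts)
            dmap.as_series("grid").to_csv(
                out / "distance_map.tsv", sep="\t", header=True,
                index_label="voxel_id",
            )
            corr = feature_distance.correlate_with_distance(
                norm, dmap, min_voxels=config.min_voxels
            )
            corr.to_csv(out / "distance_correlation.tsv", sep="\t", index=False)
            record["stages"][stage] = {"proteins_tested": len(corr)}
        else:
            record["stages"][stage] = {"skipped": "no feature table supplied"}
    except Exception as exc:
        record["failed_stage"] = stage
        (out / "record.json").write_text(json.dumps(record, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "record.json").write_text(json.dumps(record, indent=1, default=str))
    return out


def _write_assignment(
    assignment: clustering.ClusterAssignment, grid: grid_io.VoxelGrid, path: Path
) -> None:
    rows = [
        {
            "voxel_id": v,
            "row": grid.positions[v][0],
            "col": grid.positions[v][1],
            "cluster": l,
        }
        for v, l in assignment.labels.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_protein_map(
    m: grid_io.ProteinQuantMatrix,
    grid: grid_io.VoxelGrid,
    protein_id: str,
    path: str | Path,
    fmt: str = "tsv",
) -> Path:
    """Export one protein's spatial map (row 0 top, col 0 left).

    ``tsv``: an n_rows x n_cols matrix of values with missing cells empty.
    ``png``: per-protein min-max rescaled intensities, not-detected voxels in
    grey.
    """
    if protein_id not in m.data.index:
        raise KeyError(f"unknown protein {protein_id!r}")
    arr = np.full((grid.n_rows, grid.n_cols), np.nan)
    series = m.data.loc[protein_id]
    for v in m.voxels:
        r, c = grid.positions[v]
        arr[r, c] = series[v]
    path = Path(path)
    if np.all(np.isnan(arr)):
        logger.warning("protein %s has no observed values", protein_id)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# protein map {protein_id}; row 0 = top, col 0 = left\n")
            pd.DataFrame(arr).to_csv(fh, sep="\t", header=False, index=False, na_rep="")
    elif fmt == "png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        finite = arr[np.isfinite(arr)]
        if finite.size and np.ptp(finite) > 0:
            scaled = (arr - finite.min()) / np.ptp(finite)
        else:
            scaled = arr * 0.0
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("lightgrey")
        fig, ax = plt.subplots(figsize=(grid.n_cols / 3, grid.n_rows / 3))
        ax.imshow(np.ma.masked_invalid(scaled), cmap=cmap, origin="upper",
                  vmin=0, vmax=1)
        ax.set_title(protein_id)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
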