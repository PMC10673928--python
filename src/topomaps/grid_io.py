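"""Reading, filtering and normalisation of voxel-grid protein quantification data.

Laser-capture microdissection (LCM) proteomics samples a tissue slice as a
rectangular grid of square "voxels"; each voxel is one LC-MS sample.  This
module parses protein-group quantification tables (MaxQuant ``proteinGroups``
dialect, DIA-NN protein-matrix dialect, or a generic TSV), applies the
standard protein-level filters (reverse hits, contaminants, site-only
identifications), log2-transforms and median-centres per voxel, and joins the
resulting proteins x voxels matrix onto the grid geometry described by a
sample -> (row, col) mapping table.

Conventions
-----------
* A raw LFQ intensity of 0 (MaxQuant's code for "not quantified") and an
  absent cell are both recorded as missing, never as the number 0.
* Grid coordinates are 0-based ``(row, col)``, row-major; row 0 is the top of
  every exported map and col 0 the left.
* Median subtraction uses observed values only, independently per voxel.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ProteinMeta",
    "VoxelGrid",
    "ProteinQuantMatrix",
    "read_protein_table",
    "normalize",
    "filter_min_voxels",
    "load_grid",
    "join_grid",
    "write_matrix_tsv",
]


class FormatError(ValueError):
    """An input table does not conform to the declared dialect."""


@dataclass(frozen=True)
class ProteinMeta:
    """Per-protein-group metadata carried alongside the quantification matrix."""

    protein_group_id: str
    gene_name: str = ""
    is_reverse: bool = False
    is_contaminant: bool = False
    is_site_only: bool = False

    @property
    def flagged(self) -> bool:
        return self.is_reverse or self.is_contaminant or self.is_site_only

    def primary_gene(self) -> str:
        """First gene symbol of a possibly semicolon-separated list, uppercased."""
        return self.gene_name.split(";")[0].strip().upper()


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a rectangular LCM voxel grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; the study's large field of view is 24 x 16 voxels.
    voxel_side : float
        Side length of a (square) voxel in micrometres (833, 350 or 40 in the
        study's three resolutions).
    positions : mapping voxel_id -> (row, col)
        0-based coordinates; injective.
    excluded : frozenset of voxel_id
        Voxels removed from all analyses (empty voxels, annotated
        haemorrhage); must be a subset of ``positions``.
    sample_map : mapping sample_name -> voxel_id
        Which mass-spectrometry sample measured which voxel; injective.
    """

    n_rows: int
    n_cols: int
    voxel_side: float
    positions: Mapping[str, tuple[int, int]]
    excluded: frozenset = frozenset()
    sample_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], str] = {}
        for vid, (r, c) in self.positions.items():
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(
                    f"voxel {vid!r} at ({r}, {c}) outside "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
            if (r, c) in seen:
                raise ValueError(
                    f"voxels {seen[r, c]!r} and {vid!r} share position ({r}, {c})"
                )
            seen[r, c] = vid
        unknown = set(self.excluded) - set(self.positions)
        if unknown:
            raise ValueError(f"excluded voxels not on grid: {sorted(unknown)}")
        if len(set(self.sample_map.values())) != len(self.sample_map):
            raise ValueError("sample_map is not injective")

    @property
    def voxel_ids(self) -> list[str]:
        return list(self.positions)

    def included_voxels(self) -> list[str]:
        return [v for v in self.positions if v not in self.excluded]

    def coords(self, voxel_ids: Iterable[str]) -> np.ndarray:
        """(n, 2) array of (row, col) for the given voxels, in order."""
        return np.array([self.positions[v] for v in voxel_ids], dtype=float)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "voxel_side_um": self.voxel_side,
            "positions": {v: list(rc) for v, rc in self.positions.items()},
            "excluded": sorted(self.excluded),
            "sample_map": dict(self.sample_map),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "VoxelGrid":
        d = json.loads(Path(path).read_text())
        return cls(
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            voxel_side=d["voxel_side_um"],
            positions={v: tuple(rc) for v, rc in d["positions"].items()},
            excluded=frozenset(d["excluded"]),
            sample_map=d["sample_map"],
        )


@dataclass
class ProteinQuantMatrix:
    """Proteins x voxels quantification matrix with explicit missing entries.

    ``data`` is a DataFrame indexed by protein_group_id with one column per
    voxel (or per raw sample before :func:`join_grid`); missing entries are
    NaN, which is distinct from any real intensity.  Before
    :func:`normalize` the entries are raw LFQ intensities; afterwards they are
    log2 intensities with the per-voxel observed median subtracted.
    """

    data: pd.DataFrame
    proteins: list[ProteinMeta]
    normalized: bool = False

    def __post_init__(self) -> None:
        ids = [p.protein_group_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein_group_id")
        if list(self.data.index) != ids:
            raise ValueError("data index does not match protein metadata order")

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def voxels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def observed(self) -> pd.DataFrame:
        """Boolean mask of observed (non-missing) entries."""
        return self.data.notna()

    def n_observed_per_protein(self) -> pd.Series:
        return self.data.notna().sum(axis=1)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_group_id": [p.protein_group_id for p in self.proteins],
                "gene_name": [p.gene_name for p in self.proteins],
            }
        ).set_index("protein_group_id")

    def subset_proteins(self, keep: Sequence[str]) -> "ProteinQuantMatrix":
        keep_set = set(keep)
        metas = [p for p in self.proteins if p.protein_group_id in keep_set]
        ids = [p.protein_group_id for p in metas]
        return ProteinQuantMatrix(self.data.loc[ids].copy(), metas, self.normalized)

    def subset_voxels(self, keep: Sequence[str]) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(
            self.data[list(keep)].copy(), list(self.proteins), self.normalized
        )

    def meta_by_id(self) -> dict[str, ProteinMeta]:
        return {p.protein_group_id: p for p in self.proteins}


# ---------------------------------------------------------------------------
# protein table readers

_MAXQUANT_ID = "Protein IDs"
_MAXQUANT_GENE = "Gene names"
_MAXQUANT_FLAGS = {
    "Reverse": "is_reverse",
    "Potential contaminant": "is_contaminant",
    "Only identified by site": "is_site_only",
}
_LFQ_PREFIX = "LFQ intensity "

_DIANN_ID = "Protein.Group"
_DIANN_GENE = "Genes"
_DIANN_META_COLS = {
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
}


def _parse_quant(df: pd.DataFrame) -> pd.DataFrame:
    """Exact (correctly-rounded) float parsing; blanks/non-numeric -> NaN."""

    def conv(x):
        if x is None or x == "":
            return np.nan
        try:
            return float(x)
        except ValueError:
            return np.nan

    return df.map(conv)


def _check_duplicate_columns(path: str | Path, sep: str = "\t") -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise FormatError(f"duplicate column(s) in {path}: {sorted(dupes)}")


def read_protein_table(
    path: str | Path, dialect: str = "maxquant"
) -> ProteinQuantMatrix:
    """Parse a protein-level quantification table into a ProteinQuantMatrix.

    Rows flagged reverse / contaminant / only-identified-by-site are removed;
    intensities of 0 or blank become missing.  The returned matrix is
    unnormalized (raw intensity scale) and its columns are named by sample.

    Parameters
    ----------
    dialect : {"maxquant", "diann", "generic-tsv"}
        ``maxquant`` expects ``Protein IDs`` plus ``LFQ intensity <sample>``
        columns and "+"-coded flag columns; ``diann`` expects the DIA-NN
        protein-group matrix layout (``Protein.Group``, ``Genes``, one column
        per run); ``generic-tsv`` expects ``protein_group_id``, optional
        ``gene_name``, and one numeric column per sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_duplicate_columns(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    if dialect == "maxquant":
        if _MAXQUANT_ID not in df.columns:
            raise FormatError(f"missing required column {_MAXQUANT_ID!r}")
        sample_cols = [c for c in df.columns if c.startswith(_LFQ_PREFIX)]
        if not sample_cols:
            raise FormatError(f"no {_LFQ_PREFIX.strip()!r} columns found")
        metas = []
        for _, row in df.iterrows():
            flags = {
                attr: row.get(col, "").strip() == "+"
                for col, attr in _MAXQUANT_FLAGS.items()
            }
            metas.append(
                ProteinMeta(
                    protein_group_id=row[_MAXQUANT_ID],
                    gene_name=row.get(_MAXQUANT_GENE, ""),
                    **flags,
                )
            )
        sample_names = [c[len(_LFQ_PREFIX) :] for c in sample_cols]
        quant = _parse_quant(df[sample_cols])
        quant.columns = sample_names
    elif dialect == "diann":
        if _DIANN_ID not in df.columns:
            raise FormatError(f"missing required column {_DIANN_ID!r}")
        sample_cols = [c for c in df.columns if c not in _DIANN_META_COLS]
        if not sample_cols:
            raise FormatError("no run columns found in DIA-NN matrix")
        metas = [
            ProteinMeta(protein_group_id=row[_DIANN_ID], gene_name=row.get(_DIANN_GENE, ""))
            for _, row in df.iterrows()
        ]
        quant = _parse_quant(df[sample_cols])
    elif dialect == "generic-tsv":
        if "protein_group_id" not in df.columns:
            raise FormatError("missing required column 'protein_group_id'")
        meta_cols = {"protein_group_id", "gene_name"}
        sample_cols = [c for c in df.columns if c not in meta_cols]
        metas = [
            ProteinMeta(
                protein_group_id=row["protein_group_id"],
                gene_name=row.get("gene_name", ""),
            )
            for _, row in df.iterrows()
        ]
        quant = _parse_quant(df[sample_cols])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    # MaxQuant writes 0 for unquantified proteins; treat 0 and blank as missing
    quant = quant.mask(quant == 0)
    keep = [i for i, m in enumerate(metas) if not m.flagged]
    metas = [metas[i] for i in keep]
    quant = quant.iloc[keep]
    quant.index = pd.Index([m.protein_group_id for m in metas])
    if quant.index.has_duplicates:
        raise FormatError("duplicate protein group ids after filtering")
    return ProteinQuantMatrix(quant.astype(float), metas, normalized=False)


def normalize(m: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """log2-transform and median-centre each voxel column on observed values.

    Each observed raw intensity x becomes ``log2(x) - median_col`` where
    ``median_col`` is the median of the log2 observed intensities in that
    column.  All-missing columns are left all-missing with a warning.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    raw = m.data
    observed = raw.notna()
    if (raw[observed] <= 0).any().any():
        bad = raw.columns[(raw[observed] <= 0).any()].tolist()
        raise ValueError(f"non-positive observed intensities in column(s) {bad}")
    logged = np.log2(raw)
    medians = logged.median(axis=0, skipna=True)
    empty_cols = medians.index[medians.isna()].tolist()
    if empty_cols:
        warnings.warn(f"all-missing voxel column(s): {empty_cols}", stacklevel=2)
        medians = medians.fillna(0.0)
    out = logged - medians
    return ProteinQuantMatrix(out, list(m.proteins), normalized=True)


def filter_min_voxels(m: ProteinQuantMatrix, min_voxels: int = 9) -> ProteinQuantMatrix:
    """Drop proteins observed in fewer than ``min_voxels`` voxels (default 9)."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if not m.normalized:
        raise ValueError("filter_min_voxels expects a normalized matrix")
    counts = m.n_observed_per_protein()
    keep = counts.index[counts >= min_voxels].tolist()
    return m.subset_proteins(keep)


def load_grid(
    mapping_path: str | Path,
    n_rows: int,
    n_cols: int,
    voxel_side: float,
    exclusions: str | Path | None = None,
) -> VoxelGrid:
    """Build a VoxelGrid from a sample -> (row, col) mapping table.

    The mapping table (CSV or TSV, sniffed) must have columns
    ``sample_name, row, col``.  ``exclusions`` is an optional file with one
    voxel_id per line (empty voxels, haemorrhage annotations).  Voxel ids are
    derived from positions as ``"r<row>c<col>"``.
    """
    mapping = pd.read_csv(mapping_path, sep=None, engine="python")
    required = {"sample_name", "row", "col"}
    missing = required - set(mapping.columns)
    if missing:
        raise FormatError(f"mapping table missing column(s) {sorted(missing)}")
    positions: dict[str, tuple[int, int]] = {}
    sample_map: dict[str, str] = {}
    for _, rec in mapping.iterrows():
        r, c = int(rec["row"]), int(rec["col"])
        vid = voxel_id(r, c)
        positions[vid] = (r, c)
        sample_map[str(rec["sample_name"])] = vid
    excluded: frozenset = frozenset()
    if exclusions is not None:
        lines = Path(exclusions).read_text().split()
        excluded = frozenset(lines)
    return VoxelGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        voxel_side=voxel_side,
        positions=positions,
        excluded=excluded,
        sample_map=sample_map,
    )


def voxel_id(row: int, col: int) -> str:
    return f"r{row}c{col}"


def join_grid(m: ProteinQuantMatrix, grid: VoxelGrid) -> ProteinQuantMatrix:
    """Rename sample columns to voxel ids and drop excluded voxels.

    Every sample column of ``m`` must appear in ``grid.sample_map``.
    """
    unmapped = [s for s in m.data.columns if s not in grid.sample_map]
    if unmapped:
        raise KeyError(f"sample(s) not present in grid mapping: {unmapped}")
    renamed = m.data.rename(columns=dict(grid.sample_map))
    keep = [v for v in renamed.columns if v not in grid.excluded]
    dropped = renamed.shape[1] - len(keep)
    if dropped:
        logger.info("dropped %d excluded voxel column(s)", dropped)
    return ProteinQuantMatrix(renamed[keep], list(m.proteins), m.normalized)


def write_matrix_tsv(m: ProteinQuantMatrix, path: str | Path) -> None:
    """Write the proteins x voxels matrix as TSV (missing cells empty)."""
    out = m.data.copy()
    out.insert(0, "gene_name", [p.gene_name for p in m.proteins])
    out.to_csv(path, sep="\t", index_label="protein_group_id", na_rep="")
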