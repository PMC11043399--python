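"""Readers, writers, containers and configuration for the LOY pipeline.

All external formats the pipeline touches live here: 10x-style
market-matrix triplets (coordinate MatrixMarket file plus one-per-line
feature and barcode lists), tab-separated cell metadata, comma-separated
ddPCR well sheets, and YAML/JSON dataset profiles.

Count matrices are oriented genes x cells (the 10x convention).  Gene
identity is by symbol, upper-cased; duplicate symbols are disambiguated
deterministically by suffixing ``-1``, ``-2``, ... in file order.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("mosaicloy")

TISSUES = ("tumor", "UM", "blood")
CELL_TYPES = ("Treg", "Th", "CTL", "other", "unassigned")
LOY_CALLS = ("LOY", "nonLOY", "unassigned")

#: Columns a cell-metadata table must carry.
REQUIRED_CELL_COLUMNS = ("cell_id", "donor_id", "tissue")
#: Optional columns filled with "unassigned" when absent.
OPTIONAL_CELL_COLUMNS = ("cell_type", "loy_call")


class FormatError(ValueError):
    """Malformed input file (wrong dialect, bad dimensions, bad values)."""


class ValidationError(ValueError):
    """Structurally readable input violating a domain constraint."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of raw UMI counts.

    Attributes
    ----------
    values
        Sparse non-negative integer matrix, one row per gene, one column
        per cell barcode.
    gene_ids
        Upper-cased, unique gene symbols (row labels).
    cell_ids
        Unique cell barcodes (column labels).
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("count matrix has negative entries")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene symbols not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell barcodes not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbols) -> np.ndarray:
        """Row indices of ``symbols`` (upper-cased); absent symbols dropped."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[s.upper()] for s in symbols if s.upper() in lookup], dtype=int)

    def to_cells_by_genes(self) -> pd.DataFrame:
        """Dense cells x genes DataFrame (barcodes as index, symbols as columns)."""
        return pd.DataFrame(
            self.values.T.toarray(), index=self.cell_ids, columns=self.gene_ids
        )

    def to_anndata(self):
        """AnnData view (cells x genes) for interoperability with scanpy."""
        import anndata as ad

        return ad.AnnData(
            X=sp.csr_matrix(self.values.T),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


@dataclass
class DatasetProfile:
    """Filtering thresholds and gene panels for one dataset flavour.

    ``min_group_cells`` mirrors the two published regimes: 15 for a small
    multi-tissue patient cohort, 50 for a large pan-cancer atlas.
    """

    min_group_cells: int = 15
    min_patients_per_cancer: int = 4
    msy_panel: tuple = ("RPS4Y1", "ZFY", "USP9Y", "DDX3Y", "KDM5D", "EIF1AY")
    treg_markers: tuple = ("CTLA4", "IL23R")
    detection_threshold_pct: float = 5.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.min_group_cells <= 0:
            raise ValidationError("min_group_cells must be positive")
        if self.min_patients_per_cancer < 0 or self.detection_threshold_pct < 0:
            raise ValidationError("thresholds must be non-negative")
        self.msy_panel = tuple(g.upper() for g in self.msy_panel)
        self.treg_markers = tuple(g.upper() for g in self.treg_markers)


#: Shipped presets for the two supported filtering regimes.
PROFILES = {
    "zhang-like": DatasetProfile(min_group_cells=15, name="zhang-like"),
    "atlas-like": DatasetProfile(min_group_cells=50, name="atlas-like"),
}


def load_profile(source: str | Path | None = None, **overrides) -> DatasetProfile:
    """Resolve a profile from a preset name, a YAML/JSON file, or defaults.

    ``source`` may be one of the preset names (``"zhang-like"``,
    ``"atlas-like"``), a path to a YAML or JSON mapping of DatasetProfile
    fields, or None for the zhang-like default.  Keyword overrides win.
    """
    if source is None:
        profile = PROFILES["zhang-like"]
    elif str(source) in PROFILES:
        profile = PROFILES[str(source)]
    else:
        path = Path(source)
        if not path.exists():
            raise FormatError(f"profile {source!r}: not a preset name and file does not exist")
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise FormatError(f"{path}: profile file must be a mapping")
        profile = DatasetProfile(**data)
    return replace(profile, **overrides) if overrides else profile


# ---------------------------------------------------------------------------
# matrix triplet


def _read_lines(path: str | Path, what: str) -> list[str]:
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty {what} file")
    return lines


def _dedupe_symbols(symbols: list[str]) -> list[str]:
    """Upper-case and make unique by suffixing -1, -2, ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        s = s.upper()
        if s in seen:
            seen[s] += 1
            out.append(f"{s}-{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_matrix_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a 10x-style triplet (MatrixMarket counts + features + barcodes).

    The matrix file must be a coordinate-format integer MatrixMarket file
    oriented genes x cells; feature and barcode files carry one record per
    line (only the first tab-separated field of each feature line is used,
    so 10x ``features.tsv`` with id/name/type columns also parses).
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"{matrix_path}: not a valid MatrixMarket file ({exc})") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{matrix_path}: non-integer entries in count matrix")
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative entries in count matrix")

    feature_rows = [ln.split("\t") for ln in _read_lines(features_path, "features")]
    # 10x features.tsv is (id, symbol, type); one-column files are symbols
    features = [row[1] if len(row) >= 2 else row[0] for row in feature_rows]
    barcodes = _read_lines(barcodes_path, "barcodes")
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{matrix_path}: header declares {mat.shape[0]} genes but "
            f"{features_path} lists {len(features)}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{matrix_path}: header declares {mat.shape[1]} cells but "
            f"{barcodes_path} lists {len(barcodes)}"
        )
    cm = CountMatrix(mat.astype(np.int64), _dedupe_symbols(features), barcodes)
    logger.info("read matrix triplet: %d genes x %d cells, %d nonzeros",
                cm.n_genes, cm.n_cells, cm.values.nnz)
    return cm


def write_matrix_triplet(
    matrix: CountMatrix,
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a CountMatrix as the triplet ``read_matrix_triplet`` accepts."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(matrix.values), field="integer")
    Path(features_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in matrix.cell_ids))


# ---------------------------------------------------------------------------
# cell metadata


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated cell-metadata table.

    Requires ``cell_id``, ``donor_id`` and ``tissue`` columns; fills the
    optional ``cell_type``/``loy_call`` columns with ``"unassigned"``.
    Tissue must be one of tumor / UM / blood; cell barcodes must be unique.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_cell_table(table, source=str(path))


def validate_cell_table(table: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    table = table.copy()
    for col in REQUIRED_CELL_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"{source}: missing required column {col!r}")
    for col in OPTIONAL_CELL_COLUMNS:
        if col not in table.columns:
            table[col] = "unassigned"
        else:
            table[col] = table[col].fillna("unassigned")
    dup = table["cell_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{source}: duplicate cell_id {table['cell_id'].iloc[row]!r} at row {row + 1}"
        )
    bad = ~table["tissue"].isin(TISSUES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{source}: unknown tissue {table['tissue'].iloc[row]!r} at row {row + 1} "
            f"(expected one of {TISSUES})"
        )
    for col, allowed in (("cell_type", CELL_TYPES), ("loy_call", LOY_CALLS)):
        bad = ~table[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{source}: invalid {col} {table[col].iloc[row]!r} at row {row + 1}"
            )
    return table


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ddPCR well sheets


@dataclass
class DropletWell:
    """One two-channel droplet well: total droplets and per-channel positives.

    ``n_pos_x`` counts droplets positive for the X-chromosome reference
    target (AMELX, FAM channel); ``n_pos_y`` for the Y target (AMELY, VIC).
    """

    sample_id: str
    n_total: int
    n_pos_x: int
    n_pos_y: int
    droplet_volume_ul: float = 0.00085  # QX200 nominal droplet volume

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError(f"well {self.sample_id!r}: n_total must be positive")
        for name in ("n_pos_x", "n_pos_y"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_total:
                raise ValidationError(
                    f"well {self.sample_id!r}: {name}={v} outside [0, n_total={self.n_total}]"
                )
        if self.droplet_volume_ul <= 0:
            raise ValidationError(f"well {self.sample_id!r}: droplet volume must be positive")


def read_ddpcr_sheet(path: str | Path) -> list[DropletWell]:
    """Read a comma-separated well sheet with columns
    sample_id, n_total, n_pos_x, n_pos_y (extra columns ignored)."""
    table = pd.read_csv(path)
    needed = ("sample_id", "n_total", "n_pos_x", "n_pos_y")
    for col in needed:
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    wells = []
    for i, row in table.iterrows():
        try:
            wells.append(
                DropletWell(
                    sample_id=str(row["sample_id"]),
                    n_total=int(row["n_total"]),
                    n_pos_x=int(row["n_pos_x"]),
                    n_pos_y=int(row["n_pos_y"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    logger.info("read ddPCR sheet %s: %d wells", path, len(wells))
    return wells


def write_ddpcr_sheet(wells: list[DropletWell], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": w.sample_id, "n_total": w.n_total,
             "n_pos_x": w.n_pos_x, "n_pos_y": w.n_pos_y}
            for w in wells
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bundled reference table


def load_patient_loy_table() -> pd.DataFrame:
    """Bundled per-patient ddPCR %LOY table for the 20-patient surgical cohort.

    Ten primary colorectal cancer (CRC) and ten CRC liver-metastasis
    (LM_CRC) patients with %LOY measured by the AMELX/AMELY droplet assay
    in whole blood, tumor-infiltrating CD45+ cells and uninvolved-margin
    (UM) CD45+ cells.  Values below the 5% detection threshold are
    recorded as 0, matching the assay's reporting convention.
    """
    path = Path(__file__).parent / "data" / "table1_crc_lm.tsv"
    return pd.read_csv(path, sep="\t")
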