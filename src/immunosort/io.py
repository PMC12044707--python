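"""Reading, writing and normalization of expression matrices.

Bulk matrices arrive as CSV/TSV with gene symbols in the first column and
sample names in the header, in linear units (TPM or FPKM).  Single-cell
data arrive either as a dense CSV/TSV or as a MatrixMarket triplet with
separate gene- and cell-id files, plus a per-cell annotation table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

Unit = Literal["TPM", "FPKM", "LOG2"]
LINEAR_UNITS = ("TPM", "FPKM")


class ExpressionIOError(ValueError):
    """Raised for malformed expression inputs (non-numeric cells, negatives, ...)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit.

    ``data`` is indexed by unique, uppercased gene symbols; columns are
    sample names.  Values must be non-negative for linear units.
    """

    data: pd.DataFrame
    unit: Unit = "TPM"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene ids after ingest: {dupes}")
        if self.data.columns.has_duplicates:
            raise ExpressionIOError("duplicate sample names")
        if self.unit in LINEAR_UNITS and (self.data.to_numpy() < 0).any():
            raise ExpressionIOError(f"negative values not allowed for unit {self.unit}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SingleCellDataset:
    """Cells x genes expression with per-cell annotations.

    ``matrix`` is indexed by cell id (rows) with uppercased gene symbols as
    columns.  ``obs`` is indexed identically and carries at least a
    ``patient`` column, optionally ``cell_type`` and ``umi_total``.
    """

    matrix: pd.DataFrame
    obs: pd.DataFrame
    unit: Unit = "TPM"
    true_composition: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.matrix.index.equals(self.obs.index):
            raise ExpressionIOError("matrix and annotation cell ids differ or are reordered")
        if "patient" not in self.obs.columns:
            raise ExpressionIOError("annotation lacks the required 'patient' column")
        if self.obs["patient"].isna().any():
            bad = self.obs.index[self.obs["patient"].isna()].tolist()
            raise ExpressionIOError(f"cells without a patient label: {bad}")
        if self.matrix.columns.has_duplicates:
            raise ExpressionIOError("duplicate gene ids in single-cell matrix")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def subset_cells(self, cell_ids) -> "SingleCellDataset":
        return SingleCellDataset(
            matrix=self.matrix.loc[cell_ids],
            obs=self.obs.loc[cell_ids],
            unit=self.unit,
            true_composition=self.true_composition,
        )


def _sniff_delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def _coerce_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any() and not df.isna().any().any():
        col = out.columns[out.isna().any()][0]
        row = out.index[out[col].isna()][0]
        raise ExpressionIOError(
            f"{path}: non-numeric value at gene {row!r}, sample {col!r}: {df.loc[row, col]!r}"
        )
    if out.isna().any().any():
        col = out.columns[out.isna().any()][0]
        row = out.index[out[col].isna()][0]
        raise ExpressionIOError(f"{path}: missing value at gene {row!r}, sample {col!r}")
    return out


def read_expression_matrix(
    path,
    delimiter: Optional[str] = None,
    unit: Unit = "TPM",
    duplicate_policy: Literal["mean", "max", "error"] = "mean",
) -> ExpressionMatrix:
    """Read a genes-x-samples matrix from CSV/TSV.

    The first column holds gene symbols (uppercased at ingest); the header
    row holds sample names.  Duplicate symbols are collapsed per
    ``duplicate_policy``; the number of collapsed rows is logged.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ExpressionIOError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str).str.strip().str.upper()
    df = _coerce_numeric(df, path)
    if (df.to_numpy() < 0).any():
        raise ExpressionIOError(f"{path}: negative expression value found")
    n_dupes = int(df.index.duplicated().sum())
    if n_dupes:
        if duplicate_policy == "error":
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"{path}: duplicate gene symbols: {dupes}")
        agg = {"mean": "mean", "max": "max"}[duplicate_policy]
        df = df.groupby(level=0, sort=False).agg(agg)
        logger.info("collapsed %d duplicate gene rows in %s by %s", n_dupes, path, agg)
    return ExpressionMatrix(data=df, unit=unit)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    m.data.to_csv(path, sep=sep, float_format="%.17g")


def normalize_expression(m: ExpressionMatrix, already_normalized: bool = False) -> ExpressionMatrix:
    """Apply the log2(x+1) transform used before diversity/display steps.

    With ``already_normalized=True`` the input is returned unchanged.
    Transforming a LOG2 matrix again is refused (double-transform guard).
    """
    if already_normalized:
        return m
    if m.unit == "LOG2":
        raise ExpressionIOError("matrix is already log2-transformed; pass already_normalized=True")
    return ExpressionMatrix(data=np.log2(m.data + 1.0), unit="LOG2")


def read_single_cell(
    matrix_path,
    annotation_path,
    gene_ids_path=None,
    cell_ids_path=None,
    cells_as: Literal["rows", "columns"] = "columns",
    unit: Unit = "TPM",
    delimiter: Optional[str] = None,
) -> SingleCellDataset:
    """Read a single-cell matrix (dense CSV/TSV or MTX triplet) plus annotations.

    For MTX input, rows are genes and columns are cells; ``gene_ids_path``
    and ``cell_ids_path`` are one-id-per-line text files.  The annotation
    table is TSV/CSV keyed by ``cell_id`` with ``patient`` and optional
    ``cell_type`` / ``umi_total`` columns.  Every matrix cell must have an
    annotation row (and vice versa).
    """
    matrix_path = Path(matrix_path)
    annotation_path = Path(annotation_path)
    if matrix_path.suffix.lower() == ".mtx":
        if gene_ids_path is None or cell_ids_path is None:
            raise ExpressionIOError("MTX input needs gene_ids_path and cell_ids_path")
        mat = scipy.io.mmread(matrix_path)
        genes = [g.strip().upper() for g in Path(gene_ids_path).read_text().splitlines() if g.strip()]
        cells = [c.strip() for c in Path(cell_ids_path).read_text().splitlines() if c.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise ExpressionIOError(
                f"MTX shape {dense.shape} does not match {len(genes)} genes x {len(cells)} cells"
            )
        mdf = pd.DataFrame(dense.T, index=cells, columns=genes)
    else:
        sep = _sniff_delimiter(matrix_path, delimiter)
        raw = pd.read_csv(matrix_path, sep=sep, index_col=0)
        raw = _coerce_numeric(raw, matrix_path)
        if cells_as == "columns":
            raw = raw.T
            raw.columns = [str(g).strip().upper() for g in raw.columns]
        else:
            raw.columns = [str(g).strip().upper() for g in raw.columns]
        mdf = raw
        mdf.index = mdf.index.astype(str)
    if (mdf.to_numpy() < 0).any():
        raise ExpressionIOError(f"{matrix_path}: negative expression value found")

    ann_sep = _sniff_delimiter(annotation_path, None)
    obs = pd.read_csv(annotation_path, sep=ann_sep)
    if "cell_id" not in obs.columns:
        raise ExpressionIOError(f"{annotation_path}: annotation lacks a 'cell_id' column")
    if "patient" not in obs.columns:
        raise ExpressionIOError(f"{annotation_path}: annotation lacks a 'patient' column")
    obs = obs.set_index(obs["cell_id"].astype(str)).drop(columns=["cell_id"])

    missing_ann = [c for c in mdf.index if c not in obs.index]
    missing_mat = [c for c in obs.index if c not in mdf.index]
    if missing_ann or missing_mat:
        raise ExpressionIOError(
            f"cell id mismatch: {len(missing_ann)} matrix cells without annotation "
            f"{missing_ann[:5]}; {len(missing_mat)} annotated cells without expression "
            f"{missing_mat[:5]}"
        )
    obs = obs.loc[mdf.index]
    return SingleCellDataset(matrix=mdf, obs=obs, unit=unit)


def write_composition(composition, path) -> None:
    """Write a composition table (samples as rows, cell types as columns) to CSV."""
    df = composition.data if hasattr(composition, "data") else composition
    if df.shape[0] == 0:
        raise ExpressionIOError("composition table has no samples")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.17g", index_label="sample")


def read_composition(path):
    from .deconvolution import CompositionTable

    df = pd.read_csv(path, index_col=0)
    return CompositionTable(data=df)
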