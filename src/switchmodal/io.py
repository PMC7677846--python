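"""Expression-matrix containers, readers/writers and TPM normalization.

The pipeline works on a genes x cells matrix carried through three named
layers: raw ``counts``, length-normalized ``tpm`` (columns scaled to sum to
1e6 per cell) and ``logtpm`` = ln(TPM + 1).  Matrices are stored as pandas
DataFrames (genes as rows) inside a small :class:`ExpressionMatrix` holder;
cell group labels (cell types or ordered timepoints) live in a
:class:`CellAnnotation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "read_expression",
    "write_expression",
    "read_gene_lengths",
    "read_annotation",
    "compute_tpm",
    "log_transform",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values under named layers."""

    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, df in self.layers.items():
            _validate_layer(df, name)

    @property
    def gene_ids(self) -> pd.Index:
        return next(iter(self.layers.values())).index

    @property
    def cell_ids(self) -> pd.Index:
        return next(iter(self.layers.values())).columns

    def __getitem__(self, layer: str) -> pd.DataFrame:
        return self.layers[layer]

    def add_layer(self, name: str, df: pd.DataFrame) -> None:
        _validate_layer(df, name)
        if self.layers:
            ref = next(iter(self.layers.values()))
            if not (df.index.equals(ref.index) and df.columns.equals(ref.columns)):
                raise ValueError(f"layer {name!r} does not match existing gene/cell ids")
        self.layers[name] = df


def _validate_layer(df: pd.DataFrame, name: str) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in layer {name!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate cell id {dup!r} in layer {name!r}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression value in layer {name!r}")


@dataclass
class CellAnnotation:
    """One group label per cell; ``group_order`` orders timepoint groups."""

    groups: pd.Series  # index: cell_id, values: group label
    group_order: list[str] | None = None

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            raise ValueError("duplicate cell id in annotation")
        if self.groups.isna().any():
            raise ValueError("every cell needs a group label")
        if self.group_order is not None:
            present = set(self.groups.unique())
            listed = set(self.group_order)
            if len(self.group_order) != len(listed):
                raise ValueError("group_order contains duplicates")
            if listed != present:
                raise ValueError(
                    f"group_order {sorted(listed)} does not cover groups {sorted(present)}"
                )

    def cells_in(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


def read_expression(path: str | Path, format: str = "tsv", layer: str = "counts") -> ExpressionMatrix:
    """Read a genes x cells matrix from TSV/CSV (genes as rows, header of
    cell ids) or MatrixMarket triplets with ``.genes``/``.cells`` sidecars."""
    path = Path(path)
    if format in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx-triplet":
        mat = scipy.io.mmread(path)
        genes = Path(str(path) + ".genes").read_text().split()
        cells = Path(str(path) + ".cells").read_text().split()
        df = pd.DataFrame(
            scipy.sparse.coo_matrix(mat).toarray(), index=genes, columns=cells
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix({layer: df})


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, layer: str = "counts", format: str = "tsv"
) -> None:
    path = Path(path)
    df = matrix[layer]
    if format in ("tsv", "csv"):
        df.to_csv(path, sep="\t" if format == "tsv" else ",")
    elif format == "mtx-triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(df.to_numpy()))
        if not path.exists() and Path(str(path) + ".mtx").exists():
            Path(str(path) + ".mtx").rename(path)  # scipy appends .mtx itself
        Path(str(path) + ".genes").write_text("\n".join(df.index) + "\n")
        Path(str(path) + ".cells").write_text("\n".join(df.columns) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, length in bp) -> Series of positive ints."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"])
    lengths = pd.Series(df["length"].to_numpy(), index=df["gene_id"].astype(str))
    if lengths.index.has_duplicates:
        raise ValueError("duplicate gene id in lengths table")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return lengths


def read_annotation(path: str | Path, group_order: list[str] | None = None) -> CellAnnotation:
    """Two-column TSV (cell_id, group)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "group"],
                     usecols=[0, 1])
    groups = pd.Series(df["group"].astype(str).to_numpy(), index=df["cell_id"].astype(str))
    return CellAnnotation(groups, group_order=group_order)


def compute_tpm(
    matrix: ExpressionMatrix,
    lengths: pd.Series,
    counts_layer: str = "counts",
    on_zero_cell: str = "drop",
) -> ExpressionMatrix:
    """Add a ``tpm`` layer: per cell, 1e6 * (count/length) / sum(count/length).

    Every gene must have a length.  Cells with zero total counts are dropped
    with a warning (``on_zero_cell="drop"``), kept as all-zero columns
    (``"keep"``) or rejected (``"error"``).
    """
    counts = matrix[counts_layer]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no length for gene(s): {list(missing[:5])}")
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    colsum = rate.sum(axis=0)
    zero_cells = colsum[colsum == 0].index
    if len(zero_cells):
        if on_zero_cell == "error":
            raise ValueError(f"all-zero cell(s): {list(zero_cells[:5])}")
        if on_zero_cell == "drop":
            logger.warning("dropping %d all-zero cell(s)", len(zero_cells))
            keep = counts.columns.difference(zero_cells, sort=False)
            matrix.layers = {k: v[keep] for k, v in matrix.layers.items()}
            rate, colsum = rate[keep], colsum[keep]
        elif on_zero_cell != "keep":
            raise ValueError(f"unknown on_zero_cell={on_zero_cell!r}")
    with np.errstate(invalid="ignore"):
        tpm = rate.div(colsum, axis=1).fillna(0.0) * 1e6
    matrix.add_layer("tpm", tpm)
    return matrix


def log_transform(matrix: ExpressionMatrix, tpm_layer: str = "tpm") -> ExpressionMatrix:
    """Add a ``logtpm`` layer: elementwise natural log of (TPM + 1)."""
    tpm = matrix[tpm_layer]
    if (tpm.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    matrix.add_layer("logtpm", np.log1p(tpm))
    return matrix
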