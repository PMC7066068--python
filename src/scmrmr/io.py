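"""Reading and writing labelled expression matrices and biomarker outputs.

The on-disk dialects are the plain-text formats GEO supplementary matrices
commonly use: dense TSV/CSV with gene identifiers in the first column and
cell identifiers in the header row, or a Matrix Market triplet with
one-identifier-per-line gene and cell sidecar files.  Labels travel as a
two-column TSV (cell_id, label).  All outputs are tab-separated with a
commented header recording version, seed and configuration, so any result
file names the run that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from . import __version__

DENSE_TSV = "dense_tsv"
DENSE_CSV = "dense_csv"
MTX_TRIPLET = "mtx_triplet"


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """A genes x cells real-valued matrix with unique identifiers.

    Values are non-negative counts as generated or loaded; after a log1p
    transform they may be any non-negative real.  Zeros are meaningful
    (dropout or true absence), NaNs are rejected at construction.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        for kind, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {kind} ids: {', '.join(dups)}")
        bad = np.argwhere(np.isnan(self.values))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"NaN entry at gene {self.gene_ids[r]!r} (row {r}), "
                f"cell {self.cell_ids[c]!r} (column {c})"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing)}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(self.values[idx], list(gene_ids), list(self.cell_ids))

    def log1p(self) -> "ExpressionMatrix":
        if (self.values < 0).any():
            raise ValueError("log1p transform requires non-negative values")
        return ExpressionMatrix(np.log1p(self.values), list(self.gene_ids), list(self.cell_ids))


@dataclass
class LabelVector:
    """Per-cell binary tissue label; ``labels`` is True for the positive class.

    Display names default to the tumor-core vs periphery contrast.
    """

    labels: np.ndarray
    positive_name: str = "tumor"
    negative_name: str = "periphery"
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.cell_ids is not None and len(self.cell_ids) != self.labels.size:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.labels.size} labels"
            )

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())

    def both_classes_present(self) -> bool:
        return 0 < self.n_positive < self.n_cells

    def require_both_classes(self) -> None:
        if not self.both_classes_present():
            raise ValueError(
                "both classes must be present; got "
                f"{self.n_positive} {self.positive_name} and "
                f"{self.n_negative} {self.negative_name} cells"
            )

    def names(self) -> np.ndarray:
        return np.where(self.labels, self.positive_name, self.negative_name)


def read_expression_matrix(
    path: str | Path,
    format: str = DENSE_TSV,
    genes_in_rows: bool = True,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix, normalising orientation to genes x cells.

    ``dense_tsv``/``dense_csv``: first column holds row identifiers, header
    row holds column identifiers.  ``mtx_triplet``: a Matrix Market file plus
    gene and cell sidecars (defaulting to ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` next to the matrix).  ``genes_in_rows`` states the
    on-disk layout; the returned matrix is always genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in (DENSE_TSV, DENSE_CSV):
        sep = "\t" if format == DENSE_TSV else ","
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    elif format == MTX_TRIPLET:
        genes_path = Path(genes_path) if genes_path else path.with_suffix(".genes.txt")
        cells_path = Path(cells_path) if cells_path else path.with_suffix(".cells.txt")
        for side in (genes_path, cells_path):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar file {side}")
        mm = mmread(str(path))
        values = np.asarray(mm.todense() if hasattr(mm, "todense") else mm, dtype=float)
        gene_ids = [l.strip() for l in genes_path.read_text().splitlines() if l.strip()]
        cell_ids = [l.strip() for l in cells_path.read_text().splitlines() if l.strip()]
        mat = values if genes_in_rows else values.T
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        return ExpressionMatrix(mat, gene_ids, cell_ids)
    else:
        raise ValueError(f"unknown format {format!r}")

    if genes_in_rows:
        return ExpressionMatrix(values, row_ids, col_ids)
    return ExpressionMatrix(values.T, col_ids, row_ids)


def read_labels(
    path: str | Path,
    positive_name: str = "tumor",
    negative_name: str = "periphery",
    cell_ids: Sequence[str] | None = None,
) -> LabelVector:
    """Read a two-column TSV (cell_id, label) into a LabelVector.

    If ``cell_ids`` is given the labels are reordered to match it; every
    cell must be labelled exactly once.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell_id, label")
    df.columns = ["cell_id", "label", *df.columns[2:]]
    known = {positive_name, negative_name}
    bad = sorted(set(df["label"]) - known)
    if bad:
        raise ValueError(f"unknown labels {bad}; expected {sorted(known)}")
    if cell_ids is not None:
        table = dict(zip(df["cell_id"], df["label"]))
        missing = [c for c in cell_ids if c not in table]
        if missing:
            raise ValueError(f"cells without labels: {', '.join(missing[:5])}")
        ordered = [table[c] for c in cell_ids]
        return LabelVector(
            np.array([l == positive_name for l in ordered]),
            positive_name,
            negative_name,
            list(cell_ids),
        )
    return LabelVector(
        (df["label"] == positive_name).to_numpy(),
        positive_name,
        negative_name,
        df["cell_id"].tolist(),
    )


def count_expressed_genes(
    matrix: ExpressionMatrix, threshold: float = 0.0
) -> tuple[np.ndarray, float]:
    """Per-cell count of genes expressed strictly above ``threshold``.

    Returns the integer vector (one entry per cell) and its mean.  With the
    default threshold of 0 this is the number of genes with any mapped
    reads in each cell.
    """
    counts = (matrix.values > threshold).sum(axis=0).astype(int)
    return counts, float(counts.mean())


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# scmrmr {__version__}"]
    for key, val in (meta or {}).items():
        lines.append(f"# {key}: {val}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a DataFrame as TSV with a commented provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_ranked_list(ranked, path: str | Path, meta: dict | None = None) -> None:
    """Write a RankedGeneList as TSV (rank, gene_id, relevance, redundancy, mrmr_score)."""
    if len(ranked.table) == 0:
        raise ValueError("refusing to write an empty ranked list")
    write_table(ranked.table, path, meta)


def read_ranked_list(path: str | Path):
    from .mrmr import RankedGeneList

    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["rank", "gene_id", "relevance", "redundancy", "mrmr_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ranked-list file lacks columns: {missing}")
    df["gene_id"] = df["gene_id"].astype(str)
    return RankedGeneList(table=df[required], n_total_genes=int(len(df)))


def write_panel(panel, path: str | Path, meta: dict | None = None) -> None:
    """Write a BiomarkerPanel as TSV (rank, gene_id) with provenance."""
    if not panel.gene_ids:
        raise ValueError("refusing to write an empty panel")
    df = pd.DataFrame(
        {"rank": np.arange(1, len(panel.gene_ids) + 1), "gene_id": panel.gene_ids}
    )
    merged = {"k": panel.k, "peak_mcc": panel.peak_mcc, **(meta or {}), **panel.provenance}
    write_table(df, path, merged)


def write_labels(labels: LabelVector, path: str | Path, meta: dict | None = None) -> None:
    if labels.cell_ids is None:
        raise ValueError("labels carry no cell ids to write")
    df = pd.DataFrame({"cell_id": labels.cell_ids, "label": labels.names()})
    write_table(df, path, meta)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a dense TSV (genes in rows, header row of cell ids)."""
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
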