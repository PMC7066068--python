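"""Greedy minimum-redundancy maximum-relevance (mRMR) gene ranking.

Genes are ranked against a binary tissue label by the difference ("MID")
criterion: at each step the candidate gene g maximizing

    D(g) - (1/m) * sum_{g_i in selected} I(g, g_i)

moves onto the ranked list, where D(g) = I(g, label) is the relevance and
the subtracted term is the mean mutual information with the m genes already
selected (defined as 0 for the first pick, where the list is empty).  A
gene that merely duplicates an already-selected gene is penalized by their
shared information and falls behind weaker but independent markers, which
is the property that makes the ranking useful on redundant gene families.

Ties at any step are broken by higher relevance, then lexicographically
smaller gene id, so rankings are deterministic across runs and platforms.
Pairwise mutual information is evaluated lazily against selected genes only
(O(n_select * n_genes) evaluations), never as a full gene x gene table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .information import (
    MEAN_SIGMA,
    DiscretizedVector,
    discretize_matrix,
    mi_against_vector,
    mutual_information,
)
from .io import ExpressionMatrix, LabelVector


@dataclass
class RankedGeneList:
    """Ordered mRMR ranking with per-gene relevance, redundancy and score.

    ``table`` columns: rank (1-based), gene_id, relevance, redundancy,
    mrmr_score; mrmr_score = relevance - redundancy, with redundancy the
    mean-MI term at the moment the gene was selected.
    """

    table: pd.DataFrame
    n_total_genes: int

    def __post_init__(self) -> None:
        if self.table["gene_id"].duplicated().any():
            dups = self.table["gene_id"][self.table["gene_id"].duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in ranking: {dups}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.table):
            raise ValueError(f"k={k} outside [1, {len(self.table)}]")
        return self.gene_ids[:k]


def _label_bins(labels: LabelVector) -> np.ndarray:
    # labels are already categorical with two levels; no discretization
    return labels.labels.astype(np.int64)


def relevance_scores(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    scheme: str = MEAN_SIGMA,
    alpha: float = 0.5,
    n_bins: int = 3,
) -> np.ndarray:
    """Per-gene relevance D(g) = I(discretized g, label), in gene order."""
    labels.require_both_classes()
    if labels.n_cells != matrix.n_cells:
        raise ValueError(
            f"{labels.n_cells} labels for {matrix.n_cells} cells"
        )
    bins = discretize_matrix(matrix.values, scheme, alpha, n_bins)
    return mi_against_vector(bins, n_bins, _label_bins(labels), 2)


def pairwise_mi_cache(
    matrix: ExpressionMatrix,
    gene_ids: list[str] | None = None,
    scheme: str = MEAN_SIGMA,
    alpha: float = 0.5,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Symmetric gene x gene mutual-information table for a gene subset.

    The diagonal holds per-gene plug-in entropies (I(x, x) = H(x)).
    """
    gene_ids = gene_ids if gene_ids is not None else list(matrix.gene_ids)
    if not gene_ids:
        raise ValueError("gene subset must be non-empty")
    sub = matrix.subset_genes(gene_ids)
    bins = discretize_matrix(sub.values, scheme, alpha, n_bins)
    k = len(gene_ids)
    out = np.zeros((k, k))
    for i in range(k):
        out[i, i:] = mi_against_vector(bins[i:], n_bins, bins[i], n_bins)
        out[i:, i] = out[i, i:]
    return pd.DataFrame(out, index=gene_ids, columns=gene_ids)


def mrmr_rank(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    n_select: int = 100,
    scheme: str = MEAN_SIGMA,
    alpha: float = 0.5,
    n_bins: int = 3,
    min_cells_expressed: int = 0,
) -> RankedGeneList:
    """Rank genes by greedy mRMR (difference criterion) against the label.

    Parameters
    ----------
    n_select : how many genes to rank (the rest are left unranked).
    min_cells_expressed : optional pre-filter dropping genes expressed
        (value > 0) in fewer than this many cells before ranking.
    """
    labels.require_both_classes()
    if matrix.n_cells != labels.n_cells:
        raise ValueError(f"{labels.n_cells} labels for {matrix.n_cells} cells")

    work = matrix
    if min_cells_expressed > 0:
        keep = (matrix.values > 0).sum(axis=1) >= min_cells_expressed
        work = ExpressionMatrix(
            matrix.values[keep],
            [g for g, k in zip(matrix.gene_ids, keep) if k],
            list(matrix.cell_ids),
        )
    n_genes = work.n_genes
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if n_select > n_genes:
        raise ValueError(
            f"n_select={n_select} exceeds the {n_genes} genes available"
        )

    bins = discretize_matrix(work.values, scheme, alpha, n_bins)
    relevance = mi_against_vector(bins, n_bins, _label_bins(labels), 2)
    gene_ids = np.array(work.gene_ids)

    candidate = np.ones(n_genes, dtype=bool)
    redundancy_sum = np.zeros(n_genes)
    rows = []
    for step in range(n_select):
        m = step
        red = redundancy_sum / m if m else np.zeros(n_genes)
        score = relevance - red
        # deterministic argmax: score, then relevance, then lexicographic id.
        # Scores are compared after rounding to 12 decimals so that values
        # equal up to float summation order fall through to the tie rule
        # identically on every platform.
        idx_c = np.flatnonzero(candidate)
        order = sorted(
            idx_c,
            key=lambda i: (-round(score[i], 12), -round(relevance[i], 12), gene_ids[i]),
        )
        best = order[0]
        rows.append(
            {
                "rank": step + 1,
                "gene_id": str(gene_ids[best]),
                "relevance": float(relevance[best]),
                "redundancy": float(red[best]),
                "mrmr_score": float(score[best]),
            }
        )
        candidate[best] = False
        if step + 1 < n_select:
            idx_c = np.flatnonzero(candidate)
            redundancy_sum[idx_c] += mi_against_vector(
                bins[idx_c], n_bins, bins[best], n_bins
            )
    return RankedGeneList(table=pd.DataFrame(rows), n_total_genes=n_genes)
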