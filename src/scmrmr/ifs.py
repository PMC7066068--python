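"""Incremental feature selection (IFS) over nested top-k gene prefixes.

Given an mRMR ranking, the IFS curve evaluates the top-k prefix S_k for
k = 1..K with a cross-validated classifier and records the confusion
matrix and MCC at each k.  The biomarker panel is the prefix at the curve's
peak; ties are broken toward the smallest k (parsimony).  Prefixes are
nested by construction — point k uses exactly point k-1's genes plus the
rank-k gene — and each point's evaluation is an independent CV pass, so no
information leaks between prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    ClassifierSpec,
    ConfusionMatrix,
    CVScheme,
    confusion,
    cross_validated_predictions,
    mcc,
)
from .io import ExpressionMatrix, LabelVector
from .mrmr import RankedGeneList


@dataclass
class IFSCurve:
    """Per-k cross-validated MCC over nested top-k gene sets.

    ``table`` columns: k (consecutive from 1), mcc, tp, fp, tn, fn.
    """

    table: pd.DataFrame
    cv: CVScheme
    classifier: ClassifierSpec
    gene_ids: list[str]  # ranked prefix order, length >= max k

    def __post_init__(self) -> None:
        ks = self.table["k"].to_numpy()
        if len(ks) and not np.array_equal(ks, np.arange(1, len(ks) + 1)):
            raise ValueError("curve k values must be consecutive from 1")

    def __len__(self) -> int:
        return len(self.table)

    def point(self, k: int) -> ConfusionMatrix:
        row = self.table.loc[self.table["k"] == k]
        if row.empty:
            raise KeyError(f"no curve point at k={k}")
        r = row.iloc[0]
        return ConfusionMatrix(tp=int(r.tp), fp=int(r.fp), tn=int(r.tn), fn=int(r.fn))


@dataclass
class BiomarkerPanel:
    """The top-k* genes at the IFS peak, with provenance for reproduction."""

    gene_ids: list[str]
    k: int
    peak_mcc: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k != len(self.gene_ids):
            raise ValueError(
                f"panel size k={self.k} does not match {len(self.gene_ids)} genes"
            )


def ifs_curve(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    ranked: RankedGeneList,
    K: int = 100,
    spec: ClassifierSpec = ClassifierSpec(),
    cv: CVScheme = CVScheme(),
) -> IFSCurve:
    """Evaluate the top-k prefixes of a ranking for k = 1..K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(ranked):
        raise ValueError(f"K={K} exceeds ranked-list length {len(ranked)}")
    genes = ranked.gene_ids
    rows = []
    for k in range(1, K + 1):
        pred = cross_validated_predictions(matrix, labels, genes[:k], spec, cv)
        cm = confusion(pred, labels.labels)
        rows.append(
            {"k": k, "mcc": mcc(cm), "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
        )
    return IFSCurve(table=pd.DataFrame(rows), cv=cv, classifier=spec, gene_ids=genes[:K])


def select_peak(curve: IFSCurve) -> tuple[int, float]:
    """Smallest k attaining the maximum MCC on the curve."""
    if len(curve) == 0:
        raise ValueError("cannot select a peak from an empty curve")
    mccs = curve.table["mcc"].to_numpy()
    best = int(np.argmax(mccs))  # argmax returns the first maximum
    return int(curve.table["k"].iloc[best]), float(mccs[best])


def build_panel(
    ranked: RankedGeneList, k: int, peak_mcc: float, provenance: dict | None = None
) -> BiomarkerPanel:
    """The top-k prefix of the ranking as a biomarker panel."""
    if k <= 0:
        raise ValueError("panel size k must be positive")
    return BiomarkerPanel(
        gene_ids=ranked.top(k), k=k, peak_mcc=peak_mcc, provenance=provenance or {}
    )


def plot_curve(curve: IFSCurve, path: str | Path) -> bool:
    """Plot k vs MCC to an image file; returns False (never raises) on failure."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k_star, peak = select_peak(curve)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve.table["k"], curve.table["mcc"], lw=1.2)
        ax.axvline(k_star, color="crimson", ls="--", lw=0.8)
        ax.annotate(f"peak MCC {peak:.3f} at k={k_star}", (k_star, peak),
                    textcoords="offset points", xytext=(6, -12), fontsize=8)
        ax.set_xlabel("number of top-ranked genes")
        ax.set_ylabel("cross-validated MCC")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return True
    except Exception:
        return False
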