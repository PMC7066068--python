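"""Hypergeometric overlap testing between a biomarker panel and reference sets.

The question answered: drawing |panel| genes at random from a universe of
``universe_size`` genes containing the |reference| signature genes, how
likely is an overlap at least as large as the one observed?  The upper-tail
probability P(X >= k) is computed by exact integer summation of binomial
coefficients — no normal or saddlepoint approximation — so p-values agree
with exhaustive enumeration to floating-point round-off at any size.

The universe size is deliberately an explicit parameter: overlap p-values
are meaningless without it, and published analyses frequently omit theirs.
Gene identifiers are upper-cased before matching; no alias resolution is
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(
            self, "gene_ids", frozenset(g.upper() for g in self.gene_ids)
        )

    def __len__(self) -> int:
        return len(self.gene_ids)


def gene_set(name: str, gene_ids) -> GeneSet:
    """Build a GeneSet from any iterable of identifiers (upper-cased)."""
    ids = [str(g).upper() for g in gene_ids]
    dups = {g for g in ids if ids.count(g) > 1}
    if dups:
        warnings.warn(f"duplicate genes collapsed in set {name!r}: {sorted(dups)}")
    return GeneSet(name=name, gene_ids=frozenset(ids))


def hypergeometric_tail(k: int, universe: int, n_reference: int, n_panel: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, n_reference, n_panel).

    Exact: integer binomial-coefficient summation, divided once at the end.
    """
    if k <= 0:
        return 1.0
    hi = min(n_reference, n_panel)
    if k > hi:
        return 0.0
    num = sum(
        comb(n_reference, i) * comb(universe - n_reference, n_panel - i)
        for i in range(k, hi + 1)
    )
    return num / comb(universe, n_panel)


def hypergeometric_overlap_test(
    panel: GeneSet, reference: GeneSet, universe_size: int
) -> tuple[int, float]:
    """Observed overlap and its upper-tail hypergeometric p-value."""
    union = panel.gene_ids | reference.gene_ids
    if universe_size < len(union):
        raise ValueError(
            f"universe_size={universe_size} smaller than the union of the two "
            f"sets ({len(union)} genes)"
        )
    overlap = len(panel.gene_ids & reference.gene_ids)
    if overlap == 0:
        warnings.warn(
            f"no shared identifiers between {panel.name!r} and {reference.name!r};"
            " check the identifier namespace"
        )
    p = hypergeometric_tail(overlap, universe_size, len(reference), len(panel))
    return overlap, p


def read_gene_set(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, fields name, description, genes...."""
    sets: list[GeneSet] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{ln}: GMT line needs >= 3 tab-separated fields "
                f"(name, description, genes...), got {len(fields)}"
            )
        name, _desc, *genes = fields
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise ValueError(f"{path}:{ln}: gene set {name!r} has no genes")
        sets.append(gene_set(name, genes))
    return sets


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni adjustment over the sets tested from one file."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
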