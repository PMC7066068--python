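"""Independent brute-force oracles the fast implementations are checked against.

Everything here is written for clarity, not speed: explicit loops over bin
pairs, greedy re-scans of every candidate at every step, and exhaustive
combinatorial enumeration.  None of it imports the code paths it verifies.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_mi(x, y) -> float:
    """Plug-in MI in nats by an explicit triple loop over bin pairs."""
    x = list(x)
    y = list(y)
    n = len(x)
    assert len(y) == n and n > 0
    total = 0.0
    for a in sorted(set(x)):
        for b in sorted(set(y)):
            nab = sum(1 for xi, yi in zip(x, y) if xi == a and yi == b)
            if nab == 0:
                continue
            na = x.count(a)
            nb = y.count(b)
            pab = nab / n
            total += pab * math.log(pab * n * n / (na * nb))
    return total


def brute_force_entropy(x) -> float:
    x = list(x)
    n = len(x)
    return -sum(
        (x.count(a) / n) * math.log(x.count(a) / n) for a in sorted(set(x))
    )


def brute_force_mrmr(bin_rows: np.ndarray, label_bins, gene_ids, n_select: int):
    """Greedy difference-criterion mRMR, re-scanning every candidate per step.

    Tie rule: highest score, then highest relevance, then lexicographically
    smallest gene id; scores and relevances are rounded to 12 decimals
    before comparison so float summation order cannot flip a tie.
    Returns the ordered list of gene ids.
    """
    n_genes = len(bin_rows)
    relevance = {g: brute_force_mi(bin_rows[i], label_bins) for i, g in enumerate(gene_ids)}
    row_of = {g: bin_rows[i] for i, g in enumerate(gene_ids)}
    selected: list[str] = []
    candidates = list(gene_ids)
    for _ in range(n_select):
        best = None
        best_key = None
        for g in candidates:
            if selected:
                red = sum(brute_force_mi(row_of[g], row_of[s]) for s in selected) / len(selected)
            else:
                red = 0.0
            key = (-round(relevance[g] - red, 12), -round(relevance[g], 12), g)
            if best is None or key < best_key:
                best, best_key = g, key
        selected.append(best)
        candidates.remove(best)
    return selected


def brute_force_hypergeom_tail(k: int, universe: int, n_reference: int, n_panel: int) -> float:
    """P(overlap >= k) by enumerating every panel draw from the universe."""
    population = list(range(universe))
    reference = set(range(n_reference))
    hits = 0
    total = 0
    for draw in combinations(population, n_panel):
        total += 1
        if len(reference.intersection(draw)) >= k:
            hits += 1
    return hits / total
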