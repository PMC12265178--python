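"""Independent brute-force oracles used to pin down the running-sum statistics.

These deliberately use plain Python loops and their own tie-breaking so
they share no code path with the package implementations they check.
"""

from __future__ import annotations

import math


def brute_ssgsea_score(expression: dict[str, float], set_genes: set[str], weight: float) -> float:
    """Single-sample running-sum score by explicit enumeration.

    Genes ranked by expression descending, ties by gene id ascending;
    rank values N..1; increments rank^w normalized over the set,
    decrement 1/(N-m); score is the sum of the running-sum curve.
    """
    ordered = sorted(expression, key=lambda g: (-expression[g], g))
    n = len(ordered)
    m = sum(1 for g in ordered if g in set_genes)
    rank_value = {g: n - i for i, g in enumerate(ordered)}
    denom = sum(abs(rank_value[g]) ** weight for g in ordered if g in set_genes)
    running = 0.0
    total = 0.0
    for g in ordered:
        if g in set_genes:
            running += abs(rank_value[g]) ** weight / denom
        elif n > m:
            running -= 1.0 / (n - m)
        total += running
    return total


def brute_preranked_es(
    gene_ids: list[str], statistics: list[float], set_genes: set[str], weight: float
) -> tuple[float, list[str]]:
    """Weighted KS enrichment score and leading edge by explicit enumeration."""
    n = len(gene_ids)
    m = sum(1 for g in gene_ids if g in set_genes)
    denom = sum(
        abs(s) ** weight for g, s in zip(gene_ids, statistics) if g in set_genes
    )
    running = 0.0
    curve = []
    for g, s in zip(gene_ids, statistics):
        if g in set_genes:
            running += (abs(s) ** weight / denom) if denom > 0 else 0.0
        elif n > m:
            running -= 1.0 / (n - m)
        curve.append(running)
    peak = max(abs(v) for v in curve)
    ext = min(i for i in range(n) if abs(curve[i]) >= peak - 1e-12)
    es = curve[ext]
    if es >= 0:
        leading = [g for i, g in enumerate(gene_ids) if g in set_genes and i <= ext]
    else:
        leading = [g for i, g in enumerate(gene_ids) if g in set_genes and i > ext]
    return es, leading


def brute_auc(labels: list[int], scores: list[float]) -> float:
    """Pairwise-concordance AUC; ties count one half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_shannon(counts: list[float]) -> float:
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)
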