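"""Independent reference implementations used only by the test suite.

Each oracle is written directly from the defining formula or by brute
force, deliberately sharing no code path with the package.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import pandas as pd


@lru_cache(maxsize=None)
def _tail_counts(N: int, K: int, n: int) -> tuple[int, ...]:
    """counts[i] = number of n-subsets of an N-universe hitting exactly i
    of the first K elements, by exhaustive enumeration over bitmasks."""
    annotated = (1 << K) - 1
    counts = [0] * (min(K, n) + 1)
    for combo in combinations(range(N), n):
        mask = 0
        for item in combo:
            mask |= 1 << item
        counts[(mask & annotated).bit_count()] += 1
    return tuple(counts)


def hypergeom_tail_enumerated(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by counting every one of the C(N, n) possible draws."""
    counts = _tail_counts(N, K, n)
    total = sum(counts)
    return sum(counts[k:]) / total


def bh_stepup_literal(pvals) -> list[float]:
    """BH step-up transcribed literally: sort, q_(i) = min_{j>=i} p_(j)*m/j
    capped at 1, undo the sort. Quadratic on purpose."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = []
    for rank_i in range(m):
        candidates = [
            pvals[order[rank_j]] * m / (rank_j + 1) for rank_j in range(rank_i, m)
        ]
        q_sorted.append(min(1.0, min(candidates)))
    q = [0.0] * m
    for rank_i, original in enumerate(order):
        q[original] = q_sorted[rank_i]
    return q


def classify_one_gene_at_a_time(de: pd.DataFrame, path_conditions) -> dict:
    """Label genes one by one with nested loops; returns label -> gene set."""
    result: dict[tuple[str, ...], set[str]] = {}
    for gene in sorted(set(de["gene"])):
        label = []
        for cond in path_conditions:
            row = de[(de["gene"] == gene) & (de["contrast"] == cond)]
            label.append(row["call"].iloc[0])
        result.setdefault(tuple(label), set()).add(gene)
    return result
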