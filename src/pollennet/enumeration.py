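"""Exhaustive reference minimizers for the entropy normalization bounds.

These enumerate every feasible integer matrix (or allocation) and are used
to validate the greedy/local-search heuristics in :mod:`pollennet.network`
on small problems.  Both H2min and d_min depend on a matrix only through
its marginal totals, and joint entropy is invariant to row/column
permutation, so the family "all integer matrices with marginals <= R and
total <= T" is covered by enumerating unordered marginal partitions.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from math import log
from typing import Iterator, Sequence

import numpy as np

from .network import _kl_d, greedy_min_entropy_allocation, min_kl_allocation

__all__ = [
    "partitions",
    "iter_marginal_pairs",
    "min_entropy_exhaustive",
    "d_min_exhaustive",
    "compositions",
]


def partitions(total: int, max_part: int) -> Iterator[tuple[int, ...]]:
    """Unordered partitions of ``total`` with parts in 1..max_part, descending."""

    def rec(remaining: int, cap: int, prefix: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
        if remaining == 0:
            yield prefix
            return
        for part in range(min(cap, remaining), 0, -1):
            yield from rec(remaining - part, part, prefix + (part,))

    yield from rec(total, max_part, ())


def iter_marginal_pairs(
    max_total: int, max_marginal: int
) -> Iterator[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (row partition, column partition) pairs with equal total <= max_total."""
    for total in range(1, max_total + 1):
        parts = list(partitions(total, max_marginal))
        for r, c in product(parts, parts):
            yield r, c


def compositions(total: int, k: int) -> Iterator[tuple[int, ...]]:
    """All ordered non-negative integer k-tuples summing to ``total``."""
    if k == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, k - 1):
            yield (first,) + rest


def _cell_costs(grand_total: int) -> tuple[float, ...]:
    """-(a/m) ln(a/m) for a = 0..m; entropy is the sum of cell costs."""
    m = grand_total
    return tuple(0.0 if a == 0 else -(a / m) * log(a / m) for a in range(m + 1))


def min_entropy_exhaustive(
    row_totals: Sequence[int], col_totals: Sequence[int]
) -> float:
    """Minimum joint Shannon entropy over all non-negative integer matrices
    with the given marginals, by column-wise dynamic programming.

    State: multiset of remaining row totals (rows with equal remaining
    capacity are exchangeable).  Columns are filled one at a time; each
    column's total is distributed over rows in every feasible way.
    """
    rows = tuple(sorted((int(r) for r in row_totals), reverse=True))
    cols = tuple(sorted((int(c) for c in col_totals), reverse=True))
    if sum(rows) != sum(cols):
        raise ValueError("marginal totals must agree")
    cost = _cell_costs(sum(rows))

    @lru_cache(maxsize=None)
    def best(remaining_rows: tuple[int, ...], col_idx: int) -> float:
        if col_idx == len(cols):
            return 0.0
        c = cols[col_idx]
        k = len(remaining_rows)
        best_val = float("inf")
        # enumerate allocations of c over rows, respecting capacities
        def rec(i: int, left: int, alloc: list[int], acc: float) -> None:
            nonlocal best_val
            if acc >= best_val:
                return
            if i == k:
                if left == 0:
                    new_rows = tuple(
                        sorted(
                            (remaining_rows[j] - alloc[j] for j in range(k)),
                            reverse=True,
                        )
                    )
                    val = acc + best(new_rows, col_idx + 1)
                    if val < best_val:
                        best_val = val
                return
            # skip duplicate states: rows with identical remaining capacity are
            # exchangeable, so force non-increasing allocation among equals
            hi = min(left, remaining_rows[i])
            if i > 0 and remaining_rows[i] == remaining_rows[i - 1]:
                hi = min(hi, alloc[i - 1])
            for a in range(hi, -1, -1):
                alloc.append(a)
                rec(i + 1, left - a, alloc, acc + cost[a])
                alloc.pop()

        rec(0, c, [], 0.0)
        return best_val

    return best(rows, 0)


def d_min_exhaustive(total: int, q: Sequence[float]) -> float:
    """Minimum of d = sum p ln(p/q) over integer allocations of ``total``
    grains across len(q) partners, by full enumeration."""
    q = np.asarray(q, dtype=float)
    best = float("inf")
    for alloc in compositions(total, len(q)):
        val = _kl_d(np.asarray(alloc), q)
        if val < best:
            best = val
    return best


def greedy_min_entropy(row_totals: Sequence[int], col_totals: Sequence[int]) -> float:
    """Entropy of the greedy concentration allocation (heuristic under test)."""
    mat = greedy_min_entropy_allocation(row_totals, col_totals)
    m = mat.sum()
    p = mat[mat > 0] / m
    return float(-(p * np.log(p)).sum())


def d_min_heuristic(total: int, q: Sequence[float]) -> float:
    """d of the proportional + single-grain-repair allocation (heuristic under test)."""
    q = np.asarray(q, dtype=float)
    return _kl_d(min_kl_allocation(total, q), q)
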