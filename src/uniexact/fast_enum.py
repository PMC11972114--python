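"""Fast exact UEFT computation: branch-and-bound with dynamic programming.

Full enumeration of the fixed-margins null population B is exponential.
Two structural facts make a much faster exact scheme possible:

* the statistic decomposes additively over rows once the column-adjustment
  term is fixed: with row sums fixed at R0, each filled row contributes
  (sum_j n_ij^2)/R_i to a running total Q, and
  chi_f^2 = s * (Q - sum_j C_j^2 / N) where the subtracted term is a
  constant over B (column sums are fixed at C0);
* completions of a partial table depend on the residual column capacities
  only through their *multiset* — the uniform margins make residual
  multisets collapse heavily — so per-state tail distributions can be
  memoized.

The engine therefore fills rows in deterministic (lexicographic) order,
memoizes the distribution of the remaining rows' Q-contribution keyed by
(rows remaining, sorted residual capacities), and assembles the exact null
distribution without materializing the population.  All weights are
integer multinomial coefficients and all statistic values are rationals,
so results are bit-identical to brute-force enumeration.

A classical pruned traversal is also provided (:func:`tail_weight_pruned`)
with certified statistic bounds per partial state: subtrees whose bounds
lie entirely above the threshold contribute their whole conditional mass
to the tail without expansion, and subtrees entirely below are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from .core import ContingencyTable, TestResult, funchisq_exact
from .null_models import NullDistribution, UniformSquareNull, uniform_square_null
from .ueftc import NeighborTriple, find_neighbors


@dataclass(frozen=True)
class EnumerationState:
    """A partial table: rows [0, row_index) filled, residual column room."""

    row_index: int
    remaining_col_capacity: tuple[int, ...]
    partial_stat: Fraction  # accumulated row contribution Q of filled rows
    partial_weight: int = 1  # product of per-row multinomial coefficients

    def __post_init__(self) -> None:
        if self.partial_stat < 0:
            raise ValueError("partial statistic contribution must be >= 0")


def _row_multinomial(row: tuple[int, ...]) -> int:
    """Multinomial coefficient R!/prod(n_j!) for one row."""
    w, total = 1, 0
    for n in row:
        total += n
        w *= math.comb(total, n)
    return w


def _bounded_rows(total: int, bounds: tuple[int, ...]):
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    for first in range(min(total, bounds[0]) + 1):
        for rest in _bounded_rows(total - first, bounds[1:]):
            yield (first,) + rest


class _Engine:
    """DP over collapsed residual states for one (k, margins) problem."""

    def __init__(self, row_sums: tuple[int, ...]):
        self.row_sums = row_sums
        self._memo: dict[tuple[int, tuple[int, ...]], dict[Fraction, int]] = {}

    def distribution(self, residual: tuple[int, ...]) -> dict[Fraction, int]:
        """Map from remaining-rows Q-contribution to total integer weight."""
        return self._rec(0, tuple(sorted(residual)))

    def _rec(self, i: int, residual: tuple[int, ...]) -> dict[Fraction, int]:
        if i == len(self.row_sums):
            return {Fraction(0): 1} if all(v == 0 for v in residual) else {}
        key = (i, residual)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        R = self.row_sums[i]
        out: dict[Fraction, int] = {}
        for row in _bounded_rows(R, residual):
            q = Fraction(sum(n * n for n in row), R) if R else Fraction(0)
            w = _row_multinomial(row)
            nxt = tuple(sorted(c - v for c, v in zip(residual, row)))
            for q_rest, w_rest in self._rec(i + 1, nxt).items():
                v = q + q_rest
                out[v] = out.get(v, 0) + w * w_rest
        self._memo[key] = out
        return out


@lru_cache(maxsize=256)
def ueft_distribution_fast(r: int, s: int, N: int) -> NullDistribution:
    """Exact fixed-margins null distribution via the DP engine.

    Identical, value-for-value and weight-for-weight, to the brute-force
    distribution; scales to sample sizes far beyond full enumeration.
    """
    null = uniform_square_null(r, s, N)
    k = null.k
    R = null.row_sums_null[:k]
    C = null.col_sums_null[:k]
    eng = _Engine(R)
    q_dist = eng.distribution(C)
    # global weight N!/prod(n_ij!) = [N!/prod(R_i!)] * prod_i row coefficients
    scale = _row_multinomial(R)
    col_const = Fraction(sum(c * c for c in C), N)
    weight_by_value = {
        s * (q - col_const): w * scale for q, w in q_dist.items()
    }
    return NullDistribution.from_weights(weight_by_value)


def fast_ueft(table: ContingencyTable, want_neighbors: bool = False) -> TestResult:
    """UEFT p-value (and, when flagged, the neighbor triple) via the fast engine."""
    stat = funchisq_exact(table)
    dist = ueft_distribution_fast(table.r, table.s, table.N)
    diagnostics: NeighborTriple | None = None
    if want_neighbors:
        diagnostics = find_neighbors(stat, dist)
    return TestResult("UEFT", float(stat), dist.pvalue(stat), diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Certified bounds and the pruned traversal


def stat_bounds(state: EnumerationState, null: UniformSquareNull) -> tuple[float, float]:
    """Certified bounds on chi_f^2 over all completions of a partial table.

    Each unfilled row of sum R contributes (sum_j n_j^2)/R to the running
    total Q.  Lower bound: at least R/m by Cauchy-Schwarz over the m
    currently positive residual columns (future states have no more
    positive columns, so using today's m only loosens the bound downward —
    still valid).  Upper bound: at most min(R, max residual capacity),
    and capacities only shrink.  The column-adjustment constant is shared
    by every completion.
    """
    lo, hi = _exact_bounds(state, null)
    return float(lo), float(hi)


def _exact_bounds(
    state: EnumerationState, null: UniformSquareNull
) -> tuple[Fraction, Fraction]:
    """Rational version of :func:`stat_bounds` used by the exact traversal."""
    k = null.k
    residual = state.remaining_col_capacity
    m = max(sum(1 for c in residual if c > 0), 1)
    maxcap = max(residual) if residual else 0
    lo = state.partial_stat
    hi = state.partial_stat
    for R in null.row_sums_null[: k][state.row_index:]:
        if R == 0:
            continue
        # row contribution is (sum_j n_j^2)/R: at least R/m (even spread
        # over the m positive columns), at most min(R, max capacity)
        lo += Fraction(R, m)
        hi += min(R, maxcap)
    col_const = Fraction(
        sum(c * c for c in null.col_sums_null[:k]), null.N
    )
    return null.s * (lo - col_const), null.s * (hi - col_const)


@lru_cache(maxsize=100_000)
def _subtree_weight(row_sums: tuple[int, ...], residual: tuple[int, ...]) -> int:
    """Total integer weight of all completions from a residual state."""
    if not row_sums:
        return 1 if all(v == 0 for v in residual) else 0
    total = 0
    for row in _bounded_rows(row_sums[0], residual):
        w = _row_multinomial(row)
        nxt = tuple(sorted(c - v for c, v in zip(residual, row)))
        if w:
            total += w * _subtree_weight(row_sums[1:], nxt)
    return total


def tail_weight_pruned(
    r: int, s: int, N: int, threshold: Fraction, prune: bool = True
) -> tuple[int, int, int]:
    """Upper-tail integer weight Pr-numerator at a statistic threshold.

    Returns ``(tail_weight, total_weight, nodes_visited)``.  With
    ``prune=False`` the traversal degenerates to brute-force leaf
    enumeration (bounds forced open), which must give the identical tail.
    """
    null = uniform_square_null(r, s, N)
    k = null.k
    R = null.row_sums_null[:k]
    C = null.col_sums_null[:k]
    scale = _row_multinomial(R)
    counters = {"nodes": 0, "tail": 0, "total": 0}

    def rec(state: EnumerationState) -> None:
        counters["nodes"] += 1
        i, residual = state.row_index, state.remaining_col_capacity
        if i == k:
            if all(v == 0 for v in residual):
                counters["total"] += state.partial_weight
                null_stat = null.s * (
                    state.partial_stat - Fraction(sum(c * c for c in C), N)
                )
                if null_stat >= threshold:
                    counters["tail"] += state.partial_weight
            return
        if prune:
            lo_stat, hi_stat = _exact_bounds(state, null)
            if lo_stat >= threshold or hi_stat < threshold:
                sub = state.partial_weight * _subtree_weight(
                    R[i:], tuple(sorted(residual))
                )
                counters["total"] += sub
                if lo_stat >= threshold:
                    counters["tail"] += sub
                return
        for row in _bounded_rows(R[i], residual):
            q = Fraction(sum(n * n for n in row), R[i]) if R[i] else Fraction(0)
            rec(
                EnumerationState(
                    row_index=i + 1,
                    remaining_col_capacity=tuple(
                        c - v for c, v in zip(residual, row)
                    ),
                    partial_stat=state.partial_stat + q,
                    partial_weight=state.partial_weight * _row_multinomial(row),
                )
            )

    rec(EnumerationState(0, C, Fraction(0), 1))
    return counters["tail"] * scale, counters["total"] * scale, counters["nodes"]
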