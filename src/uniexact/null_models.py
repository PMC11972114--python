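"""Embedded-uniform-square null populations and exact p-values.

Classical exact tests (Fisher, EFT) condition on the *observed* marginal
counts, which makes p-values from different tables incomparable and breeds
direction bias.  The tests here instead draw their null populations from an
*embedded uniform square*: with k = min(r, s), probability mass (UMFT) or
marginal counts (UEFT) are spread uniformly over a k x k subtable, so the
null is equivalent under transposition of the table.

Two null populations are defined for a table shape (r, s) and sample size N:

* population A (UMFT): every r x s table with total N, weighted by the
  multinomial law with cell probabilities p_i. * p_.j, where the marginals
  put mass 1/k on the first k levels and 0 beyond;
* population B (UEFT): every table whose row and column sums equal the
  near-uniform vectors R0, C0 (counts N/k rounded up for the first
  N mod k levels, down for the rest, zero beyond k), weighted by the
  fixed-margins hypergeometric law.

All probabilities in this module reduce to ratios of integer weights
(multinomial coefficients), so enumeration sums are exact: floats appear
only when a distribution or p-value is handed back to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .core import ContingencyTable, TestResult, funchisq_exact

DEFAULT_ENUMERATION_CAP = 5_000_000

#: shared relative tolerance for grouping/comparing float statistic values
STAT_RTOL = 1e-9


class EnumerationCapExceeded(RuntimeError):
    """Raised when a brute-force enumeration would exceed the table cap."""


@dataclass(frozen=True)
class UniformSquareNull:
    """The embedded-uniform-square null specification for shape (r, s, N)."""

    r: int
    s: int
    N: int
    k: int
    row_probs: tuple[Fraction, ...]
    col_probs: tuple[Fraction, ...]
    row_sums_null: tuple[int, ...]  # R0
    col_sums_null: tuple[int, ...]  # C0


def uniform_square_null(r: int, s: int, N: int) -> UniformSquareNull:
    """Build the embedded-uniform-square null for an r x s table of total N.

    The k = min(r, s) active levels get probability 1/k each; the null
    margins R0, C0 give ceil(N/k) to the first N mod k active levels and
    floor(N/k) to the rest, zero beyond level k.
    """
    if r < 1 or s < 1 or N < 1:
        raise ValueError("require r, s, N >= 1")
    k = min(r, s)
    q, rem = divmod(N, k)

    def margins(m: int) -> tuple[int, ...]:
        return tuple(
            (q + 1 if i < rem else q) if i < k else 0 for i in range(m)
        )

    def probs(m: int) -> tuple[Fraction, ...]:
        return tuple(Fraction(1, k) if i < k else Fraction(0) for i in range(m))

    return UniformSquareNull(
        r=r, s=s, N=N, k=k,
        row_probs=probs(r), col_probs=probs(s),
        row_sums_null=margins(r), col_sums_null=margins(s),
    )


# ---------------------------------------------------------------------------
# Enumeration


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """All ordered ways to write ``total`` as a sum of ``parts`` >= 0 ints."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _bounded_compositions(total: int, bounds: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """Ordered compositions of ``total`` with part j <= bounds[j]."""
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    for first in range(min(total, bounds[0]) + 1):
        for rest in _bounded_compositions(total - first, bounds[1:]):
            yield (first,) + rest


def count_fixed_total(r: int, s: int, N: int) -> int:
    """Number of r x s tables with total N (stars and bars)."""
    return math.comb(N + r * s - 1, r * s - 1)


def enumerate_fixed_total(
    r: int, s: int, N: int, cap: int = DEFAULT_ENUMERATION_CAP
) -> Iterator[ContingencyTable]:
    """Yield every r x s table of non-negative integers summing to N."""
    if N < 1:
        raise ValueError("require N >= 1")
    n_tables = count_fixed_total(r, s, N)
    if n_tables > cap:
        raise EnumerationCapExceeded(
            f"{n_tables} tables exceed cap {cap}; use the UEFT fast engine"
        )
    for flat in _compositions(N, r * s):
        yield ContingencyTable(np.array(flat, dtype=np.int64).reshape(r, s))


def enumerate_fixed_margins(
    row_sums: Sequence[int], col_sums: Sequence[int]
) -> Iterator[ContingencyTable]:
    """Yield every non-negative integer table with the given margins."""
    row_sums = [int(v) for v in row_sums]
    col_sums = [int(v) for v in col_sums]
    if sum(row_sums) != sum(col_sums):
        raise ValueError("row and column sums must have equal totals")
    r, s = len(row_sums), len(col_sums)

    def rec(i: int, residual: tuple[int, ...], rows: list[tuple[int, ...]]):
        if i == r:
            if all(v == 0 for v in residual):
                yield ContingencyTable(np.array(rows, dtype=np.int64))
            return
        for row in _bounded_compositions(row_sums[i], residual):
            nxt = tuple(c - v for c, v in zip(residual, row))
            yield from rec(i + 1, nxt, rows + [row])

    yield from rec(0, tuple(col_sums), [])


# ---------------------------------------------------------------------------
# Probabilities (standalone, log-space)


def multinomial_prob(table: ContingencyTable, null: UniformSquareNull) -> float:
    """Multinomial probability of a table under the uniform-square null.

    Pr(A) = N!/prod(n_ij!) * prod_ij (p_i. p_.j)^n_ij, zero whenever a
    count sits in a zero-probability cell (row or column beyond k).
    """
    if table.r != null.r or table.s != null.s:
        raise ValueError("table shape does not match null")
    counts = table.counts
    N = table.N
    k = null.k
    if counts[k:, :].sum() + counts[:, k:].sum() > 0:
        return 0.0
    logp = gammaln(N + 1) - gammaln(counts + 1).sum()
    logp += float(counts.sum()) * (-2.0 * math.log(k))
    return float(math.exp(logp))


def hypergeometric_prob(table: ContingencyTable, null: UniformSquareNull) -> float:
    """Fixed-margins hypergeometric probability of a table with margins (R0, C0).

    Pr(B) = (prod_i R_i!)(prod_j C_j!) / (N! prod_ij n_ij!).
    """
    if table.r != null.r or table.s != null.s:
        raise ValueError("table shape does not match null")
    if tuple(int(v) for v in table.row_sums) != null.row_sums_null or tuple(
        int(v) for v in table.col_sums
    ) != null.col_sums_null:
        raise ValueError("table margins do not equal the uniform null margins")
    R = np.array(null.row_sums_null)
    C = np.array(null.col_sums_null)
    logp = (
        gammaln(R + 1).sum()
        + gammaln(C + 1).sum()
        - gammaln(null.N + 1)
        - gammaln(table.counts + 1).sum()
    )
    return float(math.exp(logp))


# ---------------------------------------------------------------------------
# Null distributions


@dataclass
class NullDistribution:
    """Distinct achievable null statistic values with probabilities and tails.

    ``values`` are ascending; ``tail[i]`` = Pr(chi_f^2 >= values[i]), so
    ``tail[0] == 1``.  The exact rational values and integer weights that
    generated the floats are kept for exact p-value lookups.
    """

    values: np.ndarray
    probs: np.ndarray
    tail: np.ndarray
    exact_values: list[Fraction]
    weights: list[int]
    total_weight: int

    @classmethod
    def from_weights(cls, weight_by_value: dict[Fraction, int]) -> "NullDistribution":
        if not weight_by_value:
            raise ValueError("empty null population")
        items = sorted(weight_by_value.items())
        exact_values = [v for v, _ in items]
        weights = [w for _, w in items]
        total = sum(weights)
        tail_w = list(np.cumsum(weights[::-1])[::-1])
        return cls(
            values=np.array([float(v) for v in exact_values]),
            probs=np.array([w / total for w in weights]),
            tail=np.array([int(w) / total for w in tail_w]),
            exact_values=exact_values,
            weights=weights,
            total_weight=total,
        )

    def __len__(self) -> int:
        return len(self.exact_values)

    @property
    def max_value(self) -> Fraction:
        return self.exact_values[-1]

    def _tail_weight_at_index(self, idx: int) -> int:
        return sum(self.weights[idx:])

    def index_at_or_above(self, stat: Fraction | float) -> int:
        """Index of the smallest achievable value >= ``stat``.

        Exact comparison for Fractions; floats use the shared relative
        tolerance.  Returns ``len(self)`` when ``stat`` exceeds the maximum.
        """
        if isinstance(stat, Fraction):
            import bisect

            return bisect.bisect_left(self.exact_values, stat)
        threshold = stat - STAT_RTOL * max(1.0, abs(stat))
        return int(np.searchsorted(self.values, threshold, side="left"))

    def pvalue(self, stat: Fraction | float) -> float:
        """Upper-tail probability Pr(chi_f^2 >= stat) under this null."""
        idx = self.index_at_or_above(stat)
        if idx >= len(self):
            return 0.0
        return self._tail_weight_at_index(idx) / self.total_weight

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"value": self.values, "prob": self.probs, "tail": self.tail})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _square_stat(square: np.ndarray, s: int) -> Fraction:
    """chi_f^2 of a table supported on a k x k square inside an r x s shape.

    Only the column count s of the enclosing shape enters the statistic
    beyond the square's counts.
    """
    N = int(square.sum())
    row_part = Fraction(0)
    for row in square:
        ni = int(row.sum())
        if ni:
            row_part += Fraction(int(np.dot(row, row)), ni)
    col = square.sum(axis=0)
    return s * (row_part - Fraction(int(np.dot(col, col)), N))


def _multinomial_weight(flat: Sequence[int]) -> int:
    """Integer multinomial coefficient N!/prod(n!), the UMFT table weight."""
    w = 1
    total = 0
    for n in flat:
        total += n
        w *= math.comb(total, n)
    return w


def null_distribution(
    null: UniformSquareNull,
    population: Literal["fixed_total", "fixed_margins"] = "fixed_margins",
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> NullDistribution:
    """Brute-force null distribution of chi_f^2 under population A or B.

    Only tables with positive null probability carry weight; both
    populations concentrate on the embedded k x k square, so enumeration
    runs over the square and the statistic is evaluated in the full shape.
    """
    k, s, N = null.k, null.s, null.N
    weight_by_value: dict[Fraction, int] = {}
    if population == "fixed_total":
        n_tables = count_fixed_total(k, k, N)
        if n_tables > cap:
            raise EnumerationCapExceeded(
                f"{n_tables} tables exceed cap {cap}; use the UEFT fast engine"
            )
        for flat in _compositions(N, k * k):
            square = np.array(flat, dtype=np.int64).reshape(k, k)
            v = _square_stat(square, s)
            weight_by_value[v] = weight_by_value.get(v, 0) + _multinomial_weight(flat)
    elif population == "fixed_margins":
        R = null.row_sums_null[:k]
        C = null.col_sums_null[:k]
        for tab in enumerate_fixed_margins(R, C):
            v = _square_stat(tab.counts, s)
            w = _multinomial_weight(tab.counts.ravel())
            weight_by_value[v] = weight_by_value.get(v, 0) + w
    else:
        raise ValueError(f"unknown population {population!r}")
    return NullDistribution.from_weights(weight_by_value)


@lru_cache(maxsize=256)
def umft_distribution(r: int, s: int, N: int, cap: int = DEFAULT_ENUMERATION_CAP) -> NullDistribution:
    return null_distribution(uniform_square_null(r, s, N), "fixed_total", cap=cap)


@lru_cache(maxsize=256)
def ueft_distribution_brute(r: int, s: int, N: int) -> NullDistribution:
    return null_distribution(uniform_square_null(r, s, N), "fixed_margins")


# ---------------------------------------------------------------------------
# p-values


def umft_pvalue(table: ContingencyTable, cap: int = DEFAULT_ENUMERATION_CAP) -> TestResult:
    """Exact UMFT p-value: the multinomial upper-tail mass at chi_f^2(O).

    Gold standard for small tables; enumeration cost grows as (k^2)^N.
    """
    stat = funchisq_exact(table)
    dist = umft_distribution(table.r, table.s, table.N, cap)
    return TestResult("UMFT", float(stat), dist.pvalue(stat))


def ueft_pvalue_bruteforce(table: ContingencyTable) -> TestResult:
    """Exact UEFT p-value by full enumeration of the fixed-margins null.

    The observed table's own margins need not equal (R0, C0); only the
    null tables' margins are constrained.
    """
    stat = funchisq_exact(table)
    dist = ueft_distribution_brute(table.r, table.s, table.N)
    return TestResult("UEFT", float(stat), dist.pvalue(stat))
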