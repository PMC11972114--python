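"""Continuity correction of UEFT p-values (the UEFTC test).

The fixed-margins null population B is small for small tables, so UEFT
p-values form a coarse step function of the observed statistic: many
distinct observed tables share a p-value.  UEFTC smooths the step function.
Around the observed statistic it locates three *neighbor* statistics
achievable in B — the lower neighbor (largest null value at or below the
observed), the upper neighbor (smallest at or above; it always exists
because the fixed-margins and fixed-total populations share the same
maximum statistic), and the super neighbor (smallest strictly above the
upper) — averages adjacent exact tail p-values at the two bracketing
values, and linearly interpolates between the averaged points at the
observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .core import ContingencyTable, TestResult, funchisq_exact
from .null_models import (
    NullDistribution,
    STAT_RTOL,
    ueft_distribution_brute,
)


@dataclass
class NeighborTriple:
    """The three null statistics bracketing an observed statistic.

    ``stat_l <= observed <= stat_v < stat_w`` when all are defined;
    ``p_l >= p_v >= p_w`` are the exact UEFT tails at those values.
    ``below_min`` marks an observed statistic under the smallest null value
    (then stat_l = 0 and p_l = 1 by convention); ``at_max`` marks an upper
    neighbor at the maximum null value (then p_w = 0 and stat_w is None).
    """

    stat_l: float
    stat_v: float
    stat_w: float | None
    p_l: float
    p_v: float
    p_w: float
    below_min: bool = False
    at_max: bool = False


def find_neighbors(observed_stat: Fraction | float, dist: NullDistribution) -> NeighborTriple:
    """Locate the lower/upper/super neighbor statistics and their tails.

    Exact (rational) observed statistics are compared exactly; floats use
    the shared relative tolerance, under which an observed value within
    tolerance of an achievable null value counts as equal to it.
    """
    if len(dist) == 0:
        raise ValueError("empty null distribution")
    idx_v = dist.index_at_or_above(observed_stat)
    if idx_v >= len(dist):
        raise AssertionError(
            "observed statistic exceeds the null maximum; this contradicts "
            "the shared-maximum theorem and signals a statistic or "
            "enumeration bug"
        )
    stat_v = float(dist.values[idx_v])
    p_v = dist._tail_weight_at_index(idx_v) / dist.total_weight
    equal_v = _stat_equal(observed_stat, dist, idx_v)

    if equal_v:
        idx_l, below_min = idx_v, False
    elif idx_v == 0:
        idx_l, below_min = None, True
    else:
        idx_l, below_min = idx_v - 1, False

    if below_min:
        stat_l, p_l = 0.0, 1.0
    else:
        stat_l = float(dist.values[idx_l])
        p_l = dist._tail_weight_at_index(idx_l) / dist.total_weight

    idx_w = idx_v + 1
    if idx_w >= len(dist):
        stat_w, p_w, at_max = None, 0.0, True
    else:
        stat_w = float(dist.values[idx_w])
        p_w = dist._tail_weight_at_index(idx_w) / dist.total_weight
        at_max = False

    return NeighborTriple(
        stat_l=stat_l, stat_v=stat_v, stat_w=stat_w,
        p_l=p_l, p_v=p_v, p_w=p_w,
        below_min=below_min, at_max=at_max,
    )


def _stat_equal(observed: Fraction | float, dist: NullDistribution, idx: int) -> bool:
    if isinstance(observed, Fraction):
        return observed == dist.exact_values[idx]
    v = float(dist.values[idx])
    return abs(float(observed) - v) <= STAT_RTOL * max(1.0, abs(v))


def corrected_pvalue(observed_stat: Fraction | float, dist: NullDistribution) -> tuple[float, NeighborTriple]:
    """Continuity-corrected p-value at an observed statistic.

    With exact tails P(Bl), P(Bv), P(Bw) at the neighbor statistics, the
    averaged boundary p-values are Pl = (P(Bl) + P(Bv))/2 and
    Pv = (P(Bv) + P(Bw))/2; the corrected value Pc is 1 when the observed
    statistic is 0, Pv when the observed statistic equals an achievable
    null value, and otherwise the linear interpolation between
    (stat_l, Pl) and (stat_v, Pv) at the observed statistic.
    """
    nb = find_neighbors(observed_stat, dist)
    obs = float(observed_stat)
    p_l_corr = (nb.p_l + nb.p_v) / 2.0
    p_v_corr = (nb.p_v + nb.p_w) / 2.0
    if (isinstance(observed_stat, Fraction) and observed_stat == 0) or (
        not isinstance(observed_stat, Fraction) and abs(obs) <= STAT_RTOL
    ):
        return 1.0, nb
    if not nb.below_min and _bracket_degenerate(nb):
        return p_v_corr, nb
    # linear interpolation between (stat_l, Pl) and (stat_v, Pv)
    span = nb.stat_v - nb.stat_l
    if span <= 0:  # within-tolerance coincidence; fall back to the midpoint rule
        return p_v_corr, nb
    frac = (obs - nb.stat_l) / span
    return p_l_corr + frac * (p_v_corr - p_l_corr), nb


def _bracket_degenerate(nb: NeighborTriple) -> bool:
    return nb.stat_l == nb.stat_v


def ueftc_pvalue(table: ContingencyTable, engine: str = "fast") -> TestResult:
    """UEFTC test of Y = f(X) on a contingency table.

    ``engine`` selects how the fixed-margins null distribution is computed:
    ``"fast"`` (branch-and-bound with dynamic programming) or ``"brute"``
    (full enumeration).  Both give identical results where both run.
    Diagnostics carry the neighbor triple so the correction is auditable.
    """
    stat = funchisq_exact(table)
    dist = _ueft_distribution(table.r, table.s, table.N, engine)
    pc, nb = corrected_pvalue(stat, dist)
    return TestResult("UEFTC", float(stat), pc, diagnostics=nb)


def ueft_pvalue(table: ContingencyTable, engine: str = "fast") -> TestResult:
    """UEFT test of Y = f(X): the uncorrected exact upper-tail p-value."""
    stat = funchisq_exact(table)
    dist = _ueft_distribution(table.r, table.s, table.N, engine)
    return TestResult("UEFT", float(stat), dist.pvalue(stat))


def _ueft_distribution(r: int, s: int, N: int, engine: str) -> NullDistribution:
    if engine == "brute":
        return ueft_distribution_brute(r, s, N)
    if engine == "fast":
        from .fast_enum import ueft_distribution_fast

        return ueft_distribution_fast(r, s, N)
    raise ValueError(f"unknown engine {engine!r}")
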