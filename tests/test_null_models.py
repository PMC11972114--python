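from fractions import Fraction

import numpy as np
import pytest

from uniexact import (
    ContingencyTable,
    enumerate_fixed_margins,
    enumerate_fixed_total,
    hypergeometric_prob,
    multinomial_prob,
    null_distribution,
    ueft_pvalue_bruteforce,
    umft_pvalue,
    uniform_square_null,
)
from uniexact.core import funchisq_exact
from uniexact.null_models import EnumerationCapExceeded

from conftest import all_tables


class TestUniformSquareNull:
    @pytest.mark.parametrize(
        "r,s,N,R0,C0",
        [
            (3, 2, 7, (4, 3, 0), (4, 3)),
            (3, 3, 9, (3, 3, 3), (3, 3, 3)),
            (2, 4, 9, (5, 4), (5, 4, 0, 0)),
        ],
    )
    def test_margin_vectors(self, r, s, N, R0, C0):
        null = uniform_square_null(r, s, N)
        assert null.row_sums_null == R0
        assert null.col_sums_null == C0
        assert sum(null.row_sums_null) == sum(null.col_sums_null) == N

    def test_probability_vectors(self):
        null = uniform_square_null(2, 4, 9)
        assert null.col_probs == (Fraction(1, 2), Fraction(1, 2), Fraction(0), Fraction(0))
        assert sum(null.row_probs) == sum(null.col_probs) == 1

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            uniform_square_null(0, 2, 5)


class TestEnumeration:
    def test_fixed_total_count_stars_and_bars(self):
        assert sum(1 for _ in enumerate_fixed_total(2, 2, 2)) == 10

    def test_single_cell(self):
        tables = list(enumerate_fixed_total(1, 1, 5))
        assert len(tables) == 1 and tables[0].counts.tolist() == [[5]]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            next(enumerate_fixed_total(2, 2, 0))

    def test_cap_enforced(self):
        with pytest.raises(EnumerationCapExceeded):
            next(enumerate_fixed_total(4, 4, 50, cap=1000))

    def test_fixed_margins_permutations(self):
        tables = list(enumerate_fixed_margins([1, 1], [1, 1]))
        assert len(tables) == 2
        assert {t.counts.tobytes() for t in tables} == {
            np.array([[1, 0], [0, 1]], dtype=np.int64).tobytes(),
            np.array([[0, 1], [1, 0]], dtype=np.int64).tobytes(),
        }

    def test_fixed_margins_forced_by_zeros(self):
        tables = list(enumerate_fixed_margins([2, 0], [2, 0]))
        assert len(tables) == 1
        assert tables[0].counts.tolist() == [[2, 0], [0, 0]]

    def test_fixed_margins_count_matches_recursive_oracle(self):
        def count_oracle(rows, cols):
            # independent recursive counter over bounded row fillings
            if not rows:
                return 1 if all(c == 0 for c in cols) else 0
            total = 0

            def fill(j, left, cols):
                nonlocal total
                if j == len(cols) - 1:
                    if left <= cols[j]:
                        total += count_oracle(
                            rows[1:], cols[:j] + (cols[j] - left,)
                        )
                    return
                for v in range(min(left, cols[j]) + 1):
                    fill(j + 1, left - v, cols[:j] + (cols[j] - v,) + cols[j + 1:])

            fill(0, rows[0], tuple(cols))
            return total

        got = sum(1 for _ in enumerate_fixed_margins([3, 3, 3], [3, 3, 3]))
        assert got == count_oracle((3, 3, 3), (3, 3, 3)) == 55

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            next(enumerate_fixed_margins([2, 1], [1, 1]))

    def test_fixed_margin_population_is_subset_of_fixed_total(self):
        null = uniform_square_null(2, 2, 4)
        everything = {t.counts.tobytes() for t in enumerate_fixed_total(2, 2, 4)}
        for t in enumerate_fixed_margins(null.row_sums_null, null.col_sums_null):
            assert t.counts.tobytes() in everything


class TestProbabilities:
    def test_multinomial_single_draw(self):
        null = uniform_square_null(2, 2, 1)
        t = ContingencyTable(np.array([[1, 0], [0, 0]]))
        assert multinomial_prob(t, null) == pytest.approx(0.25)

    def test_multinomial_zero_probability_cell(self):
        null = uniform_square_null(3, 2, 2)  # k = 2: row 3 has zero probability
        t = ContingencyTable(np.array([[1, 0], [0, 0], [1, 0]]))
        assert multinomial_prob(t, null) == 0.0

    @pytest.mark.parametrize("r,s,N", [(2, 2, 3), (2, 3, 4)])
    def test_multinomial_normalizes(self, r, s, N):
        null = uniform_square_null(r, s, N)
        total = sum(multinomial_prob(t, null) for t in enumerate_fixed_total(r, s, N))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_hypergeometric_two_table_population(self):
        null = uniform_square_null(2, 2, 2)
        for t in enumerate_fixed_margins([1, 1], [1, 1]):
            assert hypergeometric_prob(t, null) == pytest.approx(0.5)

    @pytest.mark.parametrize("r,s,N", [(2, 2, 4), (3, 3, 6), (2, 3, 5)])
    def test_hypergeometric_normalizes(self, r, s, N):
        null = uniform_square_null(r, s, N)
        total = sum(
            hypergeometric_prob(t, null)
            for t in enumerate_fixed_margins(null.row_sums_null, null.col_sums_null)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_hypergeometric_forced_table_is_certain(self):
        # shape (1, 2): margins force the single table [[3, 0]]
        null = uniform_square_null(1, 2, 3)
        (only,) = list(
            enumerate_fixed_margins(null.row_sums_null, null.col_sums_null)
        )
        assert hypergeometric_prob(only, null) == pytest.approx(1.0)

    def test_hypergeometric_margin_mismatch_rejected(self):
        null = uniform_square_null(2, 2, 4)
        t = ContingencyTable(np.array([[4, 0], [0, 0]]))
        with pytest.raises(ValueError):
            hypergeometric_prob(t, null)


class TestPValues:
    def test_single_cell_table_has_p_one(self):
        assert umft_pvalue(ContingencyTable(np.array([[5]]))).p_value == 1.0

    def test_zero_statistic_has_p_one(self, table_all_ones_3x3):
        assert umft_pvalue(table_all_ones_3x3).p_value == 1.0
        assert ueft_pvalue_bruteforce(table_all_ones_3x3).p_value == 1.0

    def test_umft_against_independent_summation_oracle(self):
        t = ContingencyTable(np.array([[2, 0], [0, 2]]))
        null = uniform_square_null(2, 2, 4)
        threshold = funchisq_exact(t)
        oracle = sum(
            multinomial_prob(a, null)
            for a in enumerate_fixed_total(2, 2, 4)
            if funchisq_exact(a) >= threshold
        )
        assert umft_pvalue(t).p_value == pytest.approx(oracle, abs=1e-12)
        assert umft_pvalue(t).p_value == pytest.approx(3 / 64)

    @pytest.mark.parametrize(
        "counts",
        [
            [[3, 0, 0], [0, 3, 0], [0, 0, 3]],
            [[2, 1, 0], [0, 2, 1], [1, 0, 2]],
            [[1, 1, 1], [3, 0, 0], [0, 0, 3]],
        ],
    )
    def test_ueft_against_independent_summation_oracle(self, counts):
        t = ContingencyTable(np.array(counts))
        null = uniform_square_null(3, 3, 9)
        threshold = funchisq_exact(t)
        oracle = sum(
            hypergeometric_prob(b, null)
            for b in enumerate_fixed_margins(null.row_sums_null, null.col_sums_null)
            if funchisq_exact(b) >= threshold
        )
        assert ueft_pvalue_bruteforce(t).p_value == pytest.approx(oracle, abs=1e-9)

    def test_pvalues_non_increasing_in_statistic(self):
        seen = []
        for counts in all_tables(2, 3, 6):
            t = ContingencyTable(counts)
            seen.append(
                (
                    funchisq_exact(t),
                    umft_pvalue(t).p_value,
                    ueft_pvalue_bruteforce(t).p_value,
                )
            )
        seen.sort()
        for (s1, u1, e1), (s2, u2, e2) in zip(seen, seen[1:]):
            assert u1 >= u2 - 1e-12
            assert e1 >= e2 - 1e-12


class TestNullDistribution:
    def test_two_permutation_population_single_value(self):
        dist = null_distribution(uniform_square_null(2, 2, 2), "fixed_margins")
        assert len(dist) == 1
        assert dist.tail[0] == 1.0

    @pytest.mark.parametrize("population", ["fixed_total", "fixed_margins"])
    def test_probs_sum_to_one(self, population):
        dist = null_distribution(uniform_square_null(3, 3, 6), population)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert dist.tail[0] == pytest.approx(1.0)
        assert np.all(np.diff(dist.tail) <= 1e-15)

    def test_fixed_total_minimum_is_zero(self):
        dist = null_distribution(uniform_square_null(3, 3, 9), "fixed_total")
        assert dist.values[0] == 0.0

    def test_theorem1_shared_maximum_small(self):
        for (r, s), N in [((2, 3), 5), ((3, 2), 5), ((2, 2), 6)]:
            max_a = max(funchisq_exact(t) for t in enumerate_fixed_total(r, s, N))
            null = uniform_square_null(r, s, N)
            max_b = max(
                funchisq_exact(t)
                for t in enumerate_fixed_margins(null.row_sums_null, null.col_sums_null)
            )
            assert max_a == max_b

    @pytest.mark.parametrize("population", ["fixed_total", "fixed_margins"])
    def test_transpose_equivalence_small(self, population):
        d1 = null_distribution(uniform_square_null(2, 3, 5), population)
        d2 = null_distribution(uniform_square_null(3, 2, 5), population)
        assert d1.weights == d2.weights
        assert d1.total_weight == d2.total_weight
        # statistic values agree after exact rescaling by s/r
        assert [v * Fraction(2, 3) for v in d1.exact_values] == d2.exact_values

    def test_remainder_placement_permutation_invariant(self):
        """Permuting which uniform margins get the +1 remainder leaves the
        null distribution unchanged."""
        from uniexact.null_models import NullDistribution, _multinomial_weight, _square_stat

        null = uniform_square_null(3, 3, 7)  # R0 = C0 = (3, 2, 2)
        ref = null_distribution(null, "fixed_margins")
        for R in [(2, 3, 2), (2, 2, 3)]:
            for C in [(3, 2, 2), (2, 3, 2)]:
                weights: dict = {}
                for t in enumerate_fixed_margins(R, C):
                    v = _square_stat(t.counts, null.s)
                    weights[v] = weights.get(v, 0) + _multinomial_weight(t.counts.ravel())
                alt = NullDistribution.from_weights(weights)
                assert alt.exact_values == ref.exact_values
                assert alt.weights == ref.weights

    def test_tsv_export(self, tmp_path):
        import pandas as pd

        dist = null_distribution(uniform_square_null(2, 2, 4), "fixed_margins")
        p = tmp_path / "dist.tsv"
        dist.to_tsv(p)
        df = pd.read_csv(p, sep="\t")
        assert list(df.columns) == ["value", "prob", "tail"]
        assert df["prob"].sum() == pytest.approx(1.0)
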