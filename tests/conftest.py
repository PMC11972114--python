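import numpy as np
import pytest

from uniexact import ContingencyTable


def naive_funchisq(counts) -> float:
    """Independent brute-force evaluation of the functional chi-squared.

    Literal double sum over cells with the zero-row convention; kept free
    of any code shared with the package's implementation.
    """
    counts = np.asarray(counts, dtype=float)
    r, s = counts.shape
    N = counts.sum()
    total = 0.0
    for i in range(r):
        ni = counts[i].sum()
        if ni == 0:
            continue
        e = ni / s
        for j in range(s):
            total += (counts[i, j] - e) ** 2 / e
    ec = N / s
    for j in range(s):
        total -= (counts[:, j].sum() - ec) ** 2 / ec
    return total


def all_tables(r, s, N):
    """Every r x s non-negative integer table with total N (stars and bars)."""
    def comps(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in comps(total - first, parts - 1):
                yield (first,) + rest

    for flat in comps(N, r * s):
        yield np.array(flat, dtype=np.int64).reshape(r, s)


@pytest.fixture
def table_2x2_diag():
    return ContingencyTable(np.array([[3, 0], [0, 3]]))


@pytest.fixture
def table_all_ones_3x3():
    return ContingencyTable(np.ones((3, 3), dtype=np.int64))
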