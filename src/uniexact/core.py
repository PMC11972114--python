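"""Contingency tables and the functional chi-squared statistic.

A contingency table tallies joint observations of two discrete random
variables: X indexes rows, Y indexes columns.  The functional chi-squared
statistic rewards tables in which Y looks like a (possibly noisy,
many-to-one) function of X: it is zero when the empirical joint
distribution factorizes (empirical independence) and, for fixed column
sums, is maximized exactly by tables whose every row has at most one
nonzero entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ContingencyTable:
    """An r x s grid of non-negative integer counts with cached marginals.

    Rows are levels of X (1-based in all user-facing I/O), columns are
    levels of Y.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("counts must be a non-empty 2-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", np.ascontiguousarray(arr, dtype=np.int64))

    @property
    def r(self) -> int:
        return self.counts.shape[0]

    @property
    def s(self) -> int:
        return self.counts.shape[1]

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        """Swap the roles of X and Y (test X = f(Y) instead of Y = f(X))."""
        return ContingencyTable(self.counts.T.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        return self.counts.shape == other.counts.shape and bool(
            np.array_equal(self.counts, other.counts)
        )

    def __hash__(self) -> int:
        return hash((self.counts.shape, self.counts.tobytes()))


@dataclass
class TestResult:
    """Outcome of one directional function test on one table."""

    method: str  # "UMFT" | "UEFT" | "UEFTC"
    statistic: float
    p_value: float
    diagnostics: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.statistic < 0:
            raise ValueError(f"statistic {self.statistic} negative")


def build_table(
    observations: Sequence[tuple], r: int | None = None, s: int | None = None
) -> ContingencyTable:
    """Tally paired discrete observations into an r x s table.

    Levels may be integers in [1..r] x [1..s] (when ``r``/``s`` are given)
    or arbitrary hashable labels, which are mapped to levels in order of
    first appearance.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("empty observation list")
    xs, ys = zip(*observations)
    if r is not None and s is not None:
        xi, yi = [], []
        for x, y in observations:
            if not (1 <= int(x) <= r) or not (1 <= int(y) <= s):
                raise ValueError(f"observation ({x}, {y}) outside [1..{r}] x [1..{s}]")
            xi.append(int(x) - 1)
            yi.append(int(y) - 1)
    else:
        xmap: dict = {}
        ymap: dict = {}
        for x in xs:
            xmap.setdefault(x, len(xmap))
        for y in ys:
            ymap.setdefault(y, len(ymap))
        r, s = len(xmap), len(ymap)
        xi = [xmap[x] for x in xs]
        yi = [ymap[y] for y in ys]
    counts = np.zeros((r, s), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return ContingencyTable(counts)


def funchisq_statistic(table: ContingencyTable | np.ndarray) -> float:
    """The functional chi-squared statistic of a contingency table.

    chi_f^2 = sum_i sum_j (n_ij - n_i./s)^2 / (n_i./s)
              - sum_j (n.j - N/s)^2 / (N/s)

    Rows with zero sum contribute 0 to the first term (the 0/0 limit).
    Equivalently (expanding the squares),

        chi_f^2 = s * [ sum_i (sum_j n_ij^2) / n_i.  -  (sum_j n.j^2) / N ]

    which is the form computed here.  Raises on an all-zero table.
    """
    return float(funchisq_exact(table))


def funchisq_exact(table: ContingencyTable | np.ndarray) -> Fraction:
    """Exact rational value of the functional chi-squared statistic."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    N = int(counts.sum())
    if N == 0:
        raise ValueError("all-zero table has no defined statistic")
    s = counts.shape[1]
    row_part = Fraction(0)
    for row in counts:
        ni = int(row.sum())
        if ni == 0:
            continue
        row_part += Fraction(int(np.dot(row, row)), ni)
    col = counts.sum(axis=0)
    col_part = Fraction(int(np.dot(col, col)), N)
    return s * (row_part - col_part)


def transpose(table: ContingencyTable) -> ContingencyTable:
    """Functional alias of :meth:`ContingencyTable.transpose`."""
    return table.transpose()


# ---------------------------------------------------------------------------
# File I/O: plain-text tables and long-format observation files.

def read_table(path, *, header: bool | None = None, delimiter: str | None = None) -> ContingencyTable:
    """Read an integer count matrix from a TSV/CSV file.

    ``header=None`` auto-detects a header/rowname line (a first line that
    does not parse as integers); ``header=True``/``False`` force it.
    """
    import pandas as pd

    sep = delimiter if delimiter is not None else None
    raw = pd.read_csv(path, sep=sep, header=None, engine="python", dtype=str)
    has_header = (
        header
        if header is not None
        else not all(_is_int(v) for v in raw.iloc[0])
    )
    if has_header:
        raw = raw.iloc[1:]
    # a leading rowname column is one whose entries do not parse as ints
    if raw.shape[1] > 1 and not all(_is_int(v) for v in raw.iloc[:, 0]):
        raw = raw.iloc[:, 1:]
    return ContingencyTable(raw.to_numpy().astype(np.int64))


def read_observations(path, *, delimiter: str | None = None) -> ContingencyTable:
    """Read a two-column (x, y) observation file and tally it.

    Labels are mapped to levels by first-appearance order.  Rows with
    missing entries are rejected.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=delimiter, header=None, engine="python", comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 columns, found {df.shape[1]}")
    if df.isna().any().any():
        raise ValueError("observation file contains missing entries")
    return build_table(list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_table(table: ContingencyTable, path, *, delimiter: str = "\t") -> None:
    np.savetxt(path, table.counts, fmt="%d", delimiter=delimiter)


def _is_int(v) -> bool:
    try:
        int(str(v))
        return True
    except (TypeError, ValueError):
        return False
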