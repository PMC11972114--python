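"""Synthetic contingency tables: noisy functional and independent patterns.

The generator mirrors the benchmark conditions used to validate the tests:
tables of configurable shape and sample size, X margins either uniform or
sharply nonuniform (Pr(i) proportional to i^8, so mass piles on the last
levels), and a noise channel that displaces the function's output to
nearby levels with probability equal to the noise level.  For functional
tables only X's marginal is configurable — Y = f(X), so Y's marginal is
determined by X's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import ContingencyTable

#: benchmark grids at the study's conditions (replicate counts are scaled
#: by the caller)
NOISE_GRID = (0.01, 0.15, 0.3, 0.45, 0.6, 0.75, 0.9)
SAMPLE_SIZE_GRID = (8, 12, 16, 20, 24, 28, 32, 36, 40, 44)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated-table condition."""

    r: int
    s: int
    N: int
    kind: Literal["functional", "independent"]
    x_marginal: Literal["uniform", "power8"] = "uniform"
    y_marginal: Literal["uniform", "power8"] = "uniform"  # independent only
    noise_level: float = 0.0
    seed: int = 0
    #: "any_nonconstant" admits injective maps; "many_to_one" additionally
    #: requires a collision (some output shared by two inputs), the class of
    #: patterns whose X -> Y direction is identifiable.  An injective f puts
    #: X and Y in bijection on the support, so neither direction is "truer".
    function_kind: Literal["any_nonconstant", "many_to_one"] = "any_nonconstant"

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_level <= 1.0):
            raise ValueError("noise_level must be in [0, 1]")
        if self.kind not in ("functional", "independent"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "functional" and self.r < 2:
            raise ValueError("functional tables need r >= 2 (non-constant map)")
        if self.function_kind == "many_to_one" and self.r < 3:
            raise ValueError("many-to-one non-constant maps need r >= 3")


def marginal_probs(M: int, mode: str) -> np.ndarray:
    """Marginal law over M levels: uniform, or Pr(i) = i^8 / sum_m m^8."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if mode == "uniform":
        return np.full(M, 1.0 / M)
    if mode == "power8":
        w = np.arange(1, M + 1, dtype=float) ** 8
        return w / w.sum()
    raise ValueError(f"unknown marginal mode {mode!r}")


def noise_channel_probs(y: int, s: int, noise_level: float) -> np.ndarray:
    """Transition law of the noise channel from level y (1-based).

    Geometric distance-decaying kernel: Pr(j | y) proportional to
    noise_level^|j - y|.  At noise 0 the channel is the identity; spread
    grows monotonically with the noise level; at noise 1 the output is
    uniform over all s levels, independent of y, so the functional signal
    vanishes entirely.  Displacement to nearby levels is always more
    likely than to distant ones, emulating level-displacement noise on an
    ordered discrete scale.
    """
    if not (1 <= y <= s):
        raise ValueError(f"level {y} outside [1..{s}]")
    if noise_level == 0.0 or s == 1:
        p = np.zeros(s)
        p[y - 1] = 1.0
        return p
    d = np.abs(np.arange(1, s + 1) - y).astype(float)
    w = noise_level ** d
    return w / w.sum()


def noise_channel(y: int, s: int, noise_level: float, rng: np.random.Generator) -> int:
    """Draw one (possibly displaced) output level from the noise channel."""
    return int(rng.choice(s, p=noise_channel_probs(y, s, noise_level)) + 1)


def _sample_function(
    r: int, s: int, rng: np.random.Generator, function_kind: str = "any_nonconstant"
) -> np.ndarray:
    """A uniform non-constant map f: [1..r] -> [1..s] (constant maps carry
    no directional signal and are excluded).  ``many_to_one`` rejects
    injective maps as well, keeping only direction-identifiable patterns."""
    if s == 1:
        raise ValueError("s = 1 admits only constant functions")
    while True:
        f = rng.integers(1, s + 1, size=r)
        n_used = len(set(f.tolist()))
        if n_used < 2:
            continue
        if function_kind == "many_to_one" and n_used >= r:
            continue
        return f


def simulate_independent(config: SimulationConfig) -> ContingencyTable:
    """N iid draws of (X, Y) from the product of the configured marginals."""
    if config.kind != "independent":
        raise ValueError("config.kind must be 'independent'")
    rng = np.random.default_rng(config.seed)
    px = marginal_probs(config.r, config.x_marginal)
    py = marginal_probs(config.s, config.y_marginal)
    xs = rng.choice(config.r, size=config.N, p=px)
    ys = rng.choice(config.s, size=config.N, p=py)
    counts = np.zeros((config.r, config.s), dtype=np.int64)
    np.add.at(counts, (xs, ys), 1)
    return ContingencyTable(counts)


def simulate_functional(config: SimulationConfig) -> tuple[ContingencyTable, np.ndarray]:
    """A noisy functional table Y = f(X) plus the ground-truth map f.

    X is drawn N times from the configured marginal, Y = f(X) is passed
    through the noise channel independently per sample, and the pairs are
    tallied.  Returns (table, f) with f 1-based of length r.
    """
    if config.kind != "functional":
        raise ValueError("config.kind must be 'functional'")
    rng = np.random.default_rng(config.seed)
    f = _sample_function(config.r, config.s, rng, config.function_kind)
    px = marginal_probs(config.r, config.x_marginal)
    xs = rng.choice(config.r, size=config.N, p=px) + 1
    counts = np.zeros((config.r, config.s), dtype=np.int64)
    # vectorized channel: per-sample transition row of the channel matrix
    channel = np.stack(
        [noise_channel_probs(y, config.s, config.noise_level) for y in range(1, config.s + 1)]
    )
    for x in xs:
        y = f[x - 1]
        yy = rng.choice(config.s, p=channel[y - 1]) + 1
        counts[x - 1, yy - 1] += 1
    return ContingencyTable(counts), f


def simulate(config: SimulationConfig):
    """Dispatch on ``config.kind``; independent tables return (table, None)."""
    if config.kind == "independent":
        return simulate_independent(config), None
    return simulate_functional(config)
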