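"""Direction scoring, reference statistics, and the benchmark harness.

``direction_contrast`` turns a pair of per-direction test results into a
signed score whose sign names the inferred function direction.  The
reference statistics (conditional entropy, fraction of information,
Goodman-Kruskal tau) are the classical model-free association measures the
exact tests are compared against; Fisher's exact test (2x2) and the G-test
come from scipy rather than being reimplemented.  ``run_benchmark`` drives
power / type-I-error / AUROC / AUPR studies on simulated tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import ContingencyTable
from .simulate import SimulationConfig, simulate_functional, simulate_independent

#: contrast saturation value reached when the direction ratio hits zero
CONTRAST_MAX = -math.log(0.01) + math.log(1.01)  # = log(101)

_TIE_TOL = 1e-12


@dataclass
class DirectionVerdict:
    """Outcome of comparing the two test directions on one table."""

    contrast: float
    direction: Literal["row_to_col", "col_to_row", "tie"]
    score_xy: float
    score_yx: float


def direction_contrast(
    score_xy: float, score_yx: float, larger_is_stronger: bool = False
) -> DirectionVerdict:
    """Signed log-ratio contrast between the X->Y and Y->X test results.

    contrast = -log(ratio + 0.01) + log(1.01), with ratio the X->Y score
    over the Y->X score for p-value-like inputs (smaller = stronger).  The
    contrast is 0 iff the two scores are equal, positive iff the row->col
    direction is stronger, and saturates at log(101) when the ratio is 0.
    For statistic-valued methods where larger means stronger, pass
    ``larger_is_stronger=True``: the ratio is inverted so the sign
    convention is preserved.
    """
    if score_xy < 0 or score_yx < 0:
        raise ValueError("scores must be non-negative")
    a, b = (score_yx, score_xy) if larger_is_stronger else (score_xy, score_yx)
    if a == b:
        contrast = 0.0
    elif b == 0.0:  # ratio -> infinity: unbounded below
        contrast = -math.inf
    else:
        contrast = -math.log(a / b + 0.01) + math.log(1.01)
    if abs(contrast) < _TIE_TOL:
        direction = "tie"
    elif contrast > 0:
        direction = "row_to_col"
    else:
        direction = "col_to_row"
    return DirectionVerdict(contrast, direction, score_xy, score_yx)


# ---------------------------------------------------------------------------
# Reference statistics


def conditional_entropy(table: ContingencyTable) -> float:
    """H(Y | X) in bits: zero iff Y is (empirically) a function of X."""
    counts = table.counts.astype(float)
    N = counts.sum()
    ce = 0.0
    for row in counts:
        ni = row.sum()
        if ni == 0:
            continue
        p = row[row > 0] / ni
        ce += (ni / N) * float(-(p * np.log2(p)).sum())
    return ce


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def fraction_of_information(table: ContingencyTable) -> float:
    """(H(Y) - H(Y|X)) / H(Y); defined as 0 when H(Y) = 0."""
    hy = _entropy(table.col_sums / table.N)
    if hy == 0.0:
        return 0.0
    return (hy - conditional_entropy(table)) / hy


def goodman_kruskal_tau(table: ContingencyTable) -> float:
    """Goodman-Kruskal tau(Y|X): proportional reduction in Y's variability.

    tau = [sum_ij n_ij^2/(N n_i.) - sum_j (n_.j/N)^2] / [1 - sum_j (n_.j/N)^2],
    0 when Y is constant (no variability to explain).
    """
    counts = table.counts.astype(float)
    N = counts.sum()
    vy = float(((table.col_sums / N) ** 2).sum())
    if 1.0 - vy == 0.0:
        return 0.0
    num = 0.0
    for row in counts:
        ni = row.sum()
        if ni:
            num += float((row ** 2).sum()) / (N * ni)
    return (num - vy) / (1.0 - vy)


def reference_statistics(table: ContingencyTable) -> dict[str, float]:
    """CE, FOI and GKT scores of a table (all computed from frequencies)."""
    return {
        "CE": conditional_entropy(table),
        "FOI": fraction_of_information(table),
        "GKT": goodman_kruskal_tau(table),
    }


def gtest_pvalue(table: ContingencyTable) -> float:
    """G-test (log-likelihood-ratio chi-squared) p-value via scipy."""
    from scipy.stats import chi2_contingency

    counts = table.counts
    keep_r = table.row_sums > 0
    keep_c = table.col_sums > 0
    counts = counts[np.ix_(keep_r, keep_c)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0
    return float(chi2_contingency(counts, lambda_="log-likelihood")[1])


def fisher_pvalue(table: ContingencyTable) -> float:
    """Fisher's exact test p-value (2x2 tables only, via scipy)."""
    from scipy.stats import fisher_exact

    if table.counts.shape != (2, 2):
        raise ValueError("Fisher baseline is available for 2x2 tables only")
    return float(fisher_exact(table.counts)[1])


# ---------------------------------------------------------------------------
# Benchmark harness


@dataclass
class EvaluationRecord:
    """One method applied to one simulated table."""

    config: SimulationConfig
    replicate: int
    method: str
    metric: Literal["p_value", "statistic"]
    value: float
    truth: Literal["functional", "independent"]


def _method_registry() -> dict[str, tuple[str, Callable[[ContingencyTable], float]]]:
    from .null_models import umft_pvalue
    from .ueftc import ueft_pvalue, ueftc_pvalue

    return {
        "umft": ("p_value", lambda t: umft_pvalue(t).p_value),
        "ueft": ("p_value", lambda t: ueft_pvalue(t).p_value),
        "ueftc": ("p_value", lambda t: ueftc_pvalue(t).p_value),
        "gtest": ("p_value", gtest_pvalue),
        "fisher": ("p_value", fisher_pvalue),
        "ce": ("statistic", conditional_entropy),
        "foi": ("statistic", fraction_of_information),
        "gkt": ("statistic", goodman_kruskal_tau),
    }


def run_benchmark(
    grid: Sequence[SimulationConfig],
    methods: Sequence[str],
    metrics: Sequence[str] = ("power", "type1", "auroc", "aupr"),
    n_replicates: int = 100,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate methods on simulated tables with known ground truth.

    power = fraction of functional tables with p <= alpha; type-I error =
    fraction of independent tables with p <= alpha; AUROC/AUPR rank pooled
    functional-vs-independent tables by each method's score (p-values
    negated so larger = more functional; CE negated likewise; FOI/GKT used
    as-is).  Requesting power or type-I from a statistic-only method is a
    configuration error, mirroring their exclusion from significance-based
    comparisons.
    """
    registry = _method_registry()
    for m in methods:
        if m not in registry:
            raise ValueError(f"unknown method {m!r}")
        if (
            registry[m][0] == "statistic"
            and ({"power", "type1"} & set(metrics))
            and not ({"auroc", "aupr"} & set(metrics))
        ):
            raise ValueError(
                f"method {m!r} provides no p-values; power/type-I are undefined"
            )
    records: list[EvaluationRecord] = []
    ss = np.random.SeedSequence(base_seed)
    for cfg_i, cfg in enumerate(grid):
        child = ss.spawn(1)[0]
        seeds = child.generate_state(n_replicates) % (2**31)
        for rep in range(n_replicates):
            cfg_rep = SimulationConfig(
                r=cfg.r, s=cfg.s, N=cfg.N, kind=cfg.kind,
                x_marginal=cfg.x_marginal, y_marginal=cfg.y_marginal,
                noise_level=cfg.noise_level, seed=int(seeds[rep]),
            )
            if cfg.kind == "functional":
                table, _ = simulate_functional(cfg_rep)
            else:
                table = simulate_independent(cfg_rep)
            for m in methods:
                metric_kind, fn = registry[m]
                records.append(
                    EvaluationRecord(
                        config=cfg_rep, replicate=rep, method=m,
                        metric=metric_kind, value=float(fn(table)),
                        truth=cfg.kind,
                    )
                )
    df = pd.DataFrame(
        {
            "r": rec.config.r, "s": rec.config.s, "N": rec.config.N,
            "kind": rec.truth, "noise": rec.config.noise_level,
            "x_marginal": rec.config.x_marginal, "seed": rec.config.seed,
            "replicate": rec.replicate, "method": rec.method,
            "metric": rec.metric, "value": rec.value,
        }
        for rec in records
    )
    summary: dict = {"alpha": alpha, "methods": {}}
    for m in methods:
        sub = df[df.method == m]
        entry: dict = {}
        if registry[m][0] == "p_value":
            func = sub[sub.kind == "functional"]
            indep = sub[sub.kind == "independent"]
            if "power" in metrics and len(func):
                entry["power"] = float((func.value <= alpha).mean())
            if "type1" in metrics and len(indep):
                entry["type1"] = float((indep.value <= alpha).mean())
        if {"auroc", "aupr"} & set(metrics):
            labels = (sub.kind == "functional").to_numpy().astype(int)
            if labels.min() == 0 and labels.max() == 1:
                scores = _ranking_scores(m, sub)
                from sklearn.metrics import average_precision_score, roc_auc_score

                if "auroc" in metrics:
                    entry["auroc"] = float(roc_auc_score(labels, scores))
                if "aupr" in metrics:
                    entry["aupr"] = float(average_precision_score(labels, scores))
        summary["methods"][m] = entry
    return df, summary


def _ranking_scores(method: str, sub: pd.DataFrame) -> np.ndarray:
    """Scores oriented so that larger = more functional."""
    v = sub.value.to_numpy()
    if sub.metric.iloc[0] == "p_value" or method == "ce":
        return -v
    return v
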