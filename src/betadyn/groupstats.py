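"""Normality-gated group comparisons and correlations.

Shapiro-Wilk (alpha = 0.05) decides the branch: normally distributed groups go
to one-way ANOVA with Tukey's post hoc, otherwise Kruskal-Wallis with Dunn's
post hoc (Bonferroni-adjusted over pairs). Correlations use Pearson when both
variables pass Shapiro-Wilk, Spearman otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "CorrelationResult",
    "normality_gate",
    "compare_groups",
    "correlate",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: tuple[int, ...]
    posthoc: tuple[tuple[str, str, float], ...] = ()

    def statistic_label(self) -> str:
        """Report-style statistic string: F(df1,df2)=... or X2=..."""
        if self.test_name.startswith("one-way ANOVA"):
            return f"F({self.df[0]},{self.df[1]}) = {self.statistic:.4g}"
        return f"X2 = {self.statistic:.4g}"


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p_value: float
    n: int


def normality_gate(groups: Sequence[np.ndarray], alpha: float = 0.05) -> bool:
    """True iff every group passes Shapiro-Wilk at alpha."""
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise ValueError("Shapiro-Wilk needs n >= 3 per group")
        if stats.shapiro(g).pvalue <= alpha:
            return False
    return True


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str],
) -> tuple[tuple[str, str, float], ...]:
    """Dunn's rank-based pairwise z tests with tie correction.

    Two-sided p-values Bonferroni-adjusted over the number of pairs.
    """
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(list(combinations(range(len(groups)), 2)))
    out = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = min(2.0 * stats.norm.sf(z) * m, 1.0)
        out.append((labels[i], labels[j], float(p)))
    return tuple(out)


def compare_groups(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Omnibus comparison with the Shapiro-Wilk gate and matching post hoc."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs n >= 3")
    labels = list(labels) if labels is not None else [f"g{i + 1}" for i in range(len(groups))]

    if normality_gate(groups, alpha):
        stat, p = stats.f_oneway(*groups)
        df1 = len(groups) - 1
        df2 = sum(g.size for g in groups) - len(groups)
        tk = stats.tukey_hsd(*groups)
        posthoc = tuple(
            (labels[i], labels[j], float(tk.pvalue[i, j]))
            for i, j in combinations(range(len(groups)), 2)
        )
        return TestResult("one-way ANOVA + Tukey", float(stat), float(p), (df1, df2), posthoc)

    stat, p = stats.kruskal(*groups)
    posthoc = dunn_posthoc(groups, labels)
    return TestResult("Kruskal-Wallis + Dunn", float(stat), float(p),
                      (len(groups) - 1,), posthoc)


def correlate(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> CorrelationResult:
    """Pearson if both variables pass Shapiro-Wilk, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    if x.size < 4:
        raise ValueError("correlation needs n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant variable")
    # perfect linear dependence has degenerate residuals that upset the
    # normality gate; the coefficient is +-1 on either branch, report Pearson
    r0 = float(np.corrcoef(x, y)[0, 1])
    if abs(r0) >= 1.0 - 1e-14:
        return CorrelationResult("pearson", float(np.sign(r0)), 0.0, x.size)
    if stats.shapiro(x).pvalue > alpha and stats.shapiro(y).pvalue > alpha:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method, float(r), float(p), x.size)
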