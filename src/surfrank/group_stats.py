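"""Normality-gated two-group and multi-group comparisons.

Expression contrasts (case vs control, cluster vs cluster) are routed
through a Shapiro-Wilk gate: when every group looks normal at the chosen
alpha the parametric path is taken (unpaired t-test, or one-way ANOVA with
Holm-Sidak-adjusted pairwise t-tests), otherwise the rank-based path
(Mann-Whitney, or Kruskal-Wallis with Dunn's tie-corrected pairwise
z-tests, Holm-Sidak adjusted). The gate uses the same alpha as the main
test. The module's contribution is the gating logic and its audit trail;
the individual tests are standard scipy/statsmodels routines, except
Dunn's pairwise z-test which is implemented here from the usual
rank-sum formula with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "compare_many_groups", "compare_two_groups"]


@dataclass
class TestResult:
    """Outcome of one gated comparison.

    ``test_name`` records which branch the gate selected; ``shapiro_p``
    the per-group gate p-values; ``adjusted_p`` (multi-group only) the
    per-pair adjusted p-values keyed ``"i-j"`` by group position.
    """

    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    shapiro_p: list[float] = field(default_factory=list)
    adjusted_p: dict[str, float] | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_groups(groups: Sequence[Sequence[float]], min_n: int) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(out):
        if g.size < min_n:
            raise ValueError(
                f"group {i} has {g.size} observations; at least {min_n} required "
                "for the normality gate"
            )
    return out


def _gate(groups: list[np.ndarray], alpha: float) -> tuple[bool, list[float]]:
    """True iff every group passes Shapiro-Wilk at alpha."""
    pvals = []
    for g in groups:
        if np.ptp(g) == 0:
            # constant data: Shapiro is undefined; clearly non-normal
            pvals.append(0.0)
        else:
            pvals.append(float(stats.shapiro(g).pvalue))
    return all(p >= alpha for p in pvals), pvals


def compare_two_groups(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Two-sided two-group comparison behind the Shapiro-Wilk gate.

    Both groups normal at ``alpha`` -> unpaired t-test; otherwise
    Mann-Whitney U. Groups need at least 3 observations each.
    """
    gx, gy = _as_groups([x, y], min_n=3)
    normal, shapiro_p = _gate([gx, gy], alpha)
    if np.array_equal(gx, gy):
        # identical samples: no evidence of difference by definition
        return TestResult("t_test" if normal else "mann_whitney",
                          0.0, 1.0, alpha, shapiro_p)
    if normal:
        res = stats.ttest_ind(gx, gy)
        return TestResult("t_test", float(res.statistic), float(res.pvalue),
                          alpha, shapiro_p)
    res = stats.mannwhitneyu(gx, gy, alternative="two-sided")
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      alpha, shapiro_p)


def _dunn_pairwise(groups: list[np.ndarray]) -> dict[str, float]:
    """Unadjusted two-sided p-values of Dunn's pairwise z-tests on pooled
    ranks, with the standard tie correction."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out: dict[str, float] = {}
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        out[f"{i}-{j}"] = float(2 * stats.norm.sf(abs(z)))
    return out


def _pairwise_t(groups: list[np.ndarray]) -> dict[str, float]:
    out: dict[str, float] = {}
    for i, j in combinations(range(len(groups)), 2):
        out[f"{i}-{j}"] = float(stats.ttest_ind(groups[i], groups[j]).pvalue)
    return out


def compare_many_groups(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> TestResult:
    """Multi-group comparison behind the Shapiro-Wilk gate.

    All groups normal -> one-way ANOVA with Holm-Sidak-adjusted pairwise
    t-tests; otherwise Kruskal-Wallis with Dunn's pairwise z-tests,
    Holm-Sidak adjusted. Needs at least 3 groups of at least 3
    observations each. ``adjusted_p`` is populated for every pair.
    """
    if len(groups) < 3:
        raise ValueError("compare_many_groups requires at least 3 groups")
    gs = _as_groups(groups, min_n=3)
    normal, shapiro_p = _gate(gs, alpha)
    if normal:
        res = stats.f_oneway(*gs)
        name = "anova_holm_sidak"
        raw = _pairwise_t(gs)
    else:
        res = stats.kruskal(*gs)
        name = "kruskal_dunn"
        raw = _dunn_pairwise(gs)
    keys = list(raw)
    adjusted = multipletests([raw[k] for k in keys], method="holm-sidak")[1]
    # step-down adjustment can only raise a p-value, never above 1
    adj = {k: float(min(max(a, raw[k]), 1.0)) for k, a in zip(keys, adjusted)}
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      alpha, shapiro_p, adjusted_p=adj)
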