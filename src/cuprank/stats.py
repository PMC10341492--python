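"""Group-comparison statistics: Shapiro–Wilk normality gate routing to
one-way ANOVA + Tukey HSD (normal data) or Kruskal–Wallis + Dunn's test
(everything else), with Bonferroni-style family control for Dunn and the
conventional significance stars (* p<=0.05, ** p<=0.01, *** p<=0.001).

Kruskal–Wallis and Dunn are computed from first principles (midranks and
explicit tie corrections); ANOVA, Tukey and Shapiro–Wilk are delegated to
scipy behind this module's reporting surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SmallSampleWarning

__all__ = [
    "GroupedSample",
    "TestReport",
    "significance_stars",
    "kruskal_wallis",
    "dunn_pairwise",
    "one_way_anova_tukey",
    "normality_gate",
    "compare_groups",
]

#: group label -> values
GroupedSample = Mapping[str, Sequence[float]]


@dataclass
class TestReport:
    """An omnibus test plus optional pairwise comparisons."""

    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["group1", "group2", "statistic", "p_raw", "p_adj", "stars"]
        )
    )

    def summary(self) -> str:
        lines = [f"{self.test}: statistic={self.statistic:.4g}, p={self.pvalue:.4g}"]
        for _, row in self.pairwise.iterrows():
            lines.append(
                f"  {row.group1} vs {row.group2}: stat={row.statistic:.3g}, "
                f"adj. p={row.p_adj:.4g} {row.stars}"
            )
        return "\n".join(lines)


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _flatten(groups: GroupedSample) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    values, codes = [], []
    for i, g in enumerate(labels):
        v = np.asarray(groups[g], dtype=float)
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        values.append(v)
        codes.append(np.full(v.size, i))
    return labels, np.concatenate(values), np.concatenate(codes)


def _tie_term(all_values: np.ndarray) -> float:
    """Sum of (t^3 - t) over groups of tied values."""
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: GroupedSample) -> TestReport:
    """Kruskal–Wallis H with midranks and tie correction.

    H = [12 / (N(N+1))] * sum_j R_j^2 / n_j - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k-1 df.
    All-identical values give H = 0, p = 1 (the correction would otherwise
    divide by zero).
    """
    labels, values, codes = _flatten(groups)
    N = values.size
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = sps.rankdata(values)
    H = 0.0
    for i in range(len(labels)):
        sel = codes == i
        R = ranks[sel].sum()
        H += R * R / sel.sum()
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(values) / (N**3 - N)
    if correction <= 0:  # every observation identical
        return TestReport(test="Kruskal-Wallis", statistic=0.0, pvalue=1.0)
    H /= correction
    p = float(sps.chi2.sf(H, df=len(labels) - 1))
    return TestReport(test="Kruskal-Wallis", statistic=float(H), pvalue=p)


def dunn_pairwise(groups: GroupedSample, adjustment: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc z tests on the pooled midranks.

    z_jk = (Rbar_j - Rbar_k) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_j + 1/n_k))
    with T = sum(t^3 - t); two-sided normal p, Bonferroni-multiplied over
    the m = k(k-1)/2 comparisons (capped at 1).
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    labels, values, codes = _flatten(groups)
    N = values.size
    ranks = sps.rankdata(values)
    mean_ranks = {g: ranks[codes == i].mean() for i, g in enumerate(labels)}
    sizes = {g: int((codes == i).sum()) for i, g in enumerate(labels)}
    var_term = N * (N + 1) / 12.0 - _tie_term(values) / (12.0 * (N - 1))
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_term * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, m * p_raw) if adjustment == "bonferroni" else p_raw
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "statistic": float(z),
                "p_raw": p_raw,
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return pd.DataFrame(rows)


def one_way_anova_tukey(groups: GroupedSample) -> TestReport:
    """Ordinary one-way ANOVA with Tukey's HSD pairwise comparisons."""
    labels, values, codes = _flatten(groups)
    arrays = [values[codes == i] for i in range(len(labels))]
    for g, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2 for ANOVA")
    if np.all(values == values[0]):  # zero variance everywhere
        return TestReport(test="one-way ANOVA", statistic=0.0, pvalue=1.0)
    F, p = sps.f_oneway(*arrays)
    tuk = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        p_adj = float(tuk.pvalue[i, j])
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "statistic": float(tuk.statistic[i, j]),
                "p_raw": p_adj,  # Tukey p is intrinsically family-adjusted
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return TestReport(
        test="one-way ANOVA",
        statistic=float(F),
        pvalue=float(p),
        pairwise=pd.DataFrame(rows),
    )


def normality_gate(groups: GroupedSample, alpha: float = 0.05) -> str:
    """Route to 'parametric' only if every group passes Shapiro–Wilk.

    Groups too small (n < 3) or constant make the test undefined; such
    samples route nonparametric with a warning.
    """
    for g, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3 or np.all(v == v[0]):
            warnings.warn(
                f"group {g!r}: sample too small or constant for a normality "
                "test; using the nonparametric route",
                SmallSampleWarning,
                stacklevel=2,
            )
            return "nonparametric"
        if sps.shapiro(v).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


def compare_groups(groups: GroupedSample, alpha: float = 0.05) -> TestReport:
    """Full battery: gate on normality, then the matching omnibus + post hoc."""
    route = normality_gate(groups, alpha=alpha)
    if route == "parametric":
        return one_way_anova_tukey(groups)
    report = kruskal_wallis(groups)
    report.pairwise = dunn_pairwise(groups)
    return report
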