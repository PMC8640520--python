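"""Group-comparison statistics: omnibus tests with matched post hoc tests.

Routing follows the study design: variables that look normal in every group
(Shapiro-Wilk at alpha = 0.05) get one-way ANOVA with Student-Newman-Keuls
(SNK) post hoc comparisons; otherwise Kruskal-Wallis with the Nemenyi test,
or pairwise Wilcoxon rank-sum when any group is very small (n < 5).  SNK and
Nemenyi are computed directly on :data:`scipy.stats.studentized_range`.
All p-values are two-sided; stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparisonResult:
    variable: str
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    omnibus_test: str
    omnibus_p: float
    posthoc_test: str
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)

    def stars(self, a: str, b: str) -> str:
        p = self.pairwise_p[_pair(a, b)]
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise_p.items() if p < 0.05]


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _is_constant(arrays: Sequence[np.ndarray]) -> bool:
    pooled = np.concatenate(arrays)
    return bool(np.all(pooled == pooled[0]))


def _normal_route(arrays: Sequence[np.ndarray], alpha: float) -> bool:
    """True when every group passes Shapiro-Wilk at ``alpha``.

    Groups of n < 3 cannot be assessed and are treated as passing.
    """
    for a in arrays:
        if len(a) < 3 or np.ptp(a) == 0:
            continue
        if sps.shapiro(a).pvalue < alpha:
            return False
    return True


def snk_pairwise(
    values: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Student-Newman-Keuls stepwise studentized-range comparisons.

    Groups are ordered by mean; a pair spanning r rank positions is tested
    against the studentized range with parameter r and the pooled-error df.
    The stepwise protection is enforced by propagating p-values: a pair's
    reported p is the largest p among all ranges that enclose it, so an
    inner pair can never be called significant when an enclosing range is
    not.  Unequal group sizes use the harmonic-mean correction per pair.
    """
    names = sorted(values, key=lambda g: np.mean(values[g]))
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    k = len(names)
    n_total = sum(len(a) for a in arrays)
    df_err = n_total - k
    if df_err <= 0:
        raise ValueError("not enough observations for SNK")
    sse = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    mse = sse / df_err
    raw: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(k), 2):
        r = j - i + 1
        n_h = 2.0 / (1.0 / len(arrays[i]) + 1.0 / len(arrays[j]))
        se = np.sqrt(mse / n_h)
        if se == 0:
            q = 0.0 if arrays[i].mean() == arrays[j].mean() else np.inf
        else:
            q = abs(arrays[j].mean() - arrays[i].mean()) / se
        raw[(i, j)] = float(np.clip(sps.studentized_range.sf(q, r, df_err), 0, 1))
    out: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(k), 2):
        p = max(
            raw[(i2, j2)]
            for i2, j2 in raw
            if i2 <= i and j2 >= j
        )
        out[_pair(names[i], names[j])] = p
    return out


def nemenyi_pairwise(
    values: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Nemenyi all-pairs rank test after Kruskal-Wallis.

    Mean ranks over the pooled sample; the pair statistic is referred to the
    studentized range with k groups and infinite df (no tie correction).
    """
    names = list(values)
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    k = len(names)
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    pos = 0
    for a in arrays:
        mean_ranks.append(ranks[pos : pos + len(a)].mean())
        sizes.append(len(a))
        pos += len(a)
    out: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(k), 2):
        se = np.sqrt(n * (n + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
        out[_pair(names[i], names[j])] = float(
            np.clip(sps.studentized_range.sf(q, k, np.inf), 0, 1)
        )
    return out


def wilcoxon_pairwise(
    values: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Wilcoxon rank-sum (Mann-Whitney) tests."""
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(values, 2):
        x, y = np.asarray(values[a]), np.asarray(values[b])
        if np.ptp(np.concatenate([x, y])) == 0:
            out[_pair(a, b)] = 1.0
        else:
            out[_pair(a, b)] = float(
                sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
            )
    return out


def ttest_pairwise(
    values: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Pairwise unpaired two-tailed t-tests."""
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(values, 2):
        x = np.asarray(values[a], dtype=float)
        y = np.asarray(values[b], dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            out[_pair(a, b)] = 1.0
        else:
            out[_pair(a, b)] = float(sps.ttest_ind(x, y).pvalue)
    return out


def benjamini_hochberg(pvalues: Mapping[tuple[str, str], float]
                       ) -> dict[tuple[str, str], float]:
    """BH-adjusted p-values (optional; raw p-values are the default)."""
    keys = list(pvalues)
    p = np.asarray([pvalues[k] for k in keys])
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return {k: float(a) for k, a in zip(keys, adj)}


def compare_groups(
    values: Mapping[str, Sequence[float]],
    force_test: str | None = None,
    alpha: float = 0.05,
    variable: str = "",
    benjamini: bool = False,
) -> GroupComparisonResult:
    """Compare a variable across sample groups.

    Chooses the parametric route (ANOVA + SNK) when all groups pass
    Shapiro-Wilk at ``alpha``, otherwise Kruskal-Wallis with Nemenyi (or
    pairwise Wilcoxon when any group has n < 5).  ``force_test`` ("anova" or
    "kruskal_wallis") overrides the routing.  Groups of constant identical
    values across the board return p = 1 with no significant pairs.
    """
    if len(values) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    arr_list = list(arrays.values())

    if force_test is None:
        test = "anova" if _normal_route(arr_list, alpha) else "kruskal_wallis"
    elif force_test in ("anova", "kruskal_wallis"):
        test = force_test
    else:
        raise ValueError(f"unknown test {force_test!r}")

    degenerate = _is_constant(arr_list)
    if degenerate:
        omnibus_p = 1.0
        pairwise = {_pair(a, b): 1.0 for a, b in combinations(arrays, 2)}
        posthoc = "snk" if test == "anova" else "nemenyi"
    elif test == "anova":
        omnibus_p = float(sps.f_oneway(*arr_list).pvalue)
        posthoc = "snk"
        pairwise = snk_pairwise(arrays)
    else:
        omnibus_p = float(sps.kruskal(*arr_list).pvalue)
        if any(len(a) < 5 for a in arr_list):
            posthoc = "wilcoxon"
            pairwise = wilcoxon_pairwise(arrays)
        else:
            posthoc = "nemenyi"
            pairwise = nemenyi_pairwise(arrays)
    if benjamini:
        pairwise = benjamini_hochberg(pairwise)

    return GroupComparisonResult(
        variable=variable,
        group_n={g: len(a) for g, a in arrays.items()},
        group_mean={g: float(a.mean()) for g, a in arrays.items()},
        group_sd={g: float(a.std(ddof=1)) for g, a in arrays.items()},
        omnibus_test=test,
        omnibus_p=omnibus_p,
        posthoc_test=posthoc,
        pairwise_p=pairwise,
    )


def chi_square(table: np.ndarray) -> float:
    """Two-sided chi-square p-value for a contingency table."""
    return float(sps.chi2_contingency(np.asarray(table)).pvalue)
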