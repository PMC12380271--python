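"""Nonparametric group comparisons for the L* and score data.

Across-formulation differences are tested with Kruskal-Wallis followed
by Dunn's post hoc pairwise z comparisons on the pooled ranks (with tie
correction); before/after shifts within a formulation use the Wilcoxon
signed-rank test (exact null distribution at small n).  Questionnaire
responses are tabulated as count and percent per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "significance_stars",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_signed_rank",
    "tabulate_questionnaire",
]

#: n below which the Wilcoxon null is enumerated exactly.
WILCOXON_EXACT_CUTOFF = 25


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    degenerate: bool = False

    @property
    def stars(self) -> str:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return significance_stars(p)


def significance_stars(p: float) -> str:
    """Fixed star mapping: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if np.isnan(p):
        return "ns"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis H with tie correction and chi-square p (df = k-1).

    Identical observations across all groups give the degenerate
    H = 0, p = 1 result rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs >= 1 observation")
    names = tuple(labels) if labels else tuple(
        f"group_{i}" for i in range(len(arrays))
    )
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            "kruskal_wallis", names, 0.0, 1.0, degenerate=True
        )
    h, p = stats.kruskal(*arrays)
    return ComparisonResult("kruskal_wallis", names, float(h), float(p))


def _dunn_z(groups: list[np.ndarray]) -> np.ndarray:
    """Pairwise Dunn z statistics from pooled midranks with tie correction."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term sum(t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)

    k = len(groups)
    z = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_unit * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0:
            z[i, j] = z[j, i] = 0.0
        else:
            z[i, j] = (mean_ranks[i] - mean_ranks[j]) / se
            z[j, i] = -z[i, j]
    return z


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    *,
    correction: str = "bonferroni",
) -> list[ComparisonResult]:
    """Dunn's post hoc pairwise comparisons after Kruskal-Wallis.

    z statistics come from the pooled-rank means with tie-corrected
    variance; raw two-sided normal p-values are adjusted for the
    k(k-1)/2 comparisons with the configured method (any method name
    statsmodels' ``multipletests`` accepts; default Bonferroni, an
    interpretation of the Prism convention).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    names = list(labels) if labels else [
        f"group_{i}" for i in range(len(arrays))
    ]
    pooled = np.concatenate(arrays)
    pairs = list(combinations(range(len(arrays)), 2))
    if np.ptp(pooled) == 0:
        return [
            ComparisonResult(
                "dunn", (names[i], names[j]), 0.0, 1.0, 1.0, degenerate=True
            )
            for i, j in pairs
        ]
    z = _dunn_z(arrays)
    raw = [2.0 * stats.norm.sf(abs(z[i, j])) for i, j in pairs]
    adjusted = multipletests(raw, method=correction)[1]
    return [
        ComparisonResult(
            "dunn",
            (names[i], names[j]),
            float(z[i, j]),
            float(p),
            float(min(1.0, adj)),
        )
        for (i, j), p, adj in zip(pairs, raw, adjusted)
    ]


def wilcoxon_signed_rank(
    before: Sequence[float],
    after: Sequence[float],
    *,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired before/after samples.

    Zero differences are dropped (``wilcox`` policy) by default; the
    signed-zero ``pratt`` alternative is available.  The exact null
    distribution is used for up to 25 nonzero differences, the normal
    approximation above that.  All-zero differences give a degenerate,
    flagged result instead of an error.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before and after must be equal-length 1-D")
    diffs = a - b
    if np.all(diffs == 0):
        return ComparisonResult(
            "wilcoxon_signed_rank", ("before", "after"), 0.0, 1.0,
            degenerate=True,
        )
    n_nonzero = int(np.count_nonzero(diffs))
    method = "exact" if n_nonzero <= WILCOXON_EXACT_CUTOFF else "approx"
    res = stats.wilcoxon(
        a, b, alternative=alternative, zero_method=zero_method, method=method
    )
    return ComparisonResult(
        "wilcoxon_signed_rank",
        ("before", "after"),
        float(res.statistic),
        float(res.pvalue),
    )


def tabulate_questionnaire(
    responses: pd.DataFrame,
    levels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Count and percent table of categorical questionnaire answers.

    ``responses`` has one row per volunteer per item (columns
    volunteer_id, item_id, response).  ``levels`` optionally fixes the
    level order per item so zero-count levels appear.  Percentages are
    100 * n / N rounded to one decimal, N being the number of
    volunteers; absent answers are counted in an explicit ``missing``
    row, never dropped.
    """
    dup = responses.duplicated(["volunteer_id", "item_id"])
    if dup.any():
        raise ValueError("more than one response per volunteer per item")
    volunteers = responses["volunteer_id"].unique()
    n_total = len(volunteers)
    rows = []
    for item in responses["item_id"].unique():
        sub = responses[responses["item_id"] == item]
        answered = sub.dropna(subset=["response"])
        counts = answered["response"].value_counts()
        item_levels = (
            list(levels[item]) if levels and item in levels
            else list(counts.index)
        )
        for level in item_levels:
            n = int(counts.get(level, 0))
            rows.append(
                {
                    "item_id": item,
                    "response": level,
                    "n": n,
                    "pct": round(100.0 * n / n_total, 1),
                }
            )
        n_missing = n_total - int(len(answered))
        if n_missing > 0:
            rows.append(
                {
                    "item_id": item,
                    "response": "missing",
                    "n": n_missing,
                    "pct": round(100.0 * n_missing / n_total, 1),
                }
            )
    return pd.DataFrame(rows)
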