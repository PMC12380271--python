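"""Inter-rater reliability of white cast rankings.

Raters (expert graders or volunteers) rank the formulations from least
(1) to most white cast.  Agreement is quantified by the intraclass
correlation coefficient from the two-way (items x raters) ANOVA
decomposition under a mixed-effects, absolute-agreement definition —
ICC(A,1) for a single rater's ranking, ICC(A,k) for the average of k
raters (McGraw & Wong 1996).  Feeding ordinal ranks to an ICC designed
for continuous ratings mirrors the field's practice and is documented
as such.

Rank summaries are reported as per-item median [Q1, Q3] with Tukey's
inclusive quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankingMatrix",
    "ICCResult",
    "icc_absolute_agreement",
    "summarize_ranks",
    "resolve_line_scale",
]


@dataclass(frozen=True)
class RankingMatrix:
    """Rater x item table of ranks (1 = least white cast).

    Ties resolved to midranks are permitted; ``has_ties`` flags them.
    """

    ranks: pd.DataFrame  # index: rater ids, columns: item ids
    has_ties: bool = False

    def __post_init__(self) -> None:
        if self.ranks.shape[0] < 2 or self.ranks.shape[1] < 2:
            raise ValueError("need >= 2 raters and >= 2 items")
        k = self.ranks.shape[1]
        expected_sum = k * (k + 1) / 2
        sums = self.ranks.sum(axis=1)
        if not np.allclose(sums, expected_sum):
            bad = sums[~np.isclose(sums, expected_sum)].index.tolist()
            raise ValueError(
                f"rows are not (mid)rankings of 1..{k}: raters {bad}"
            )

    @property
    def raters(self) -> list[str]:
        return [str(r) for r in self.ranks.index]

    @property
    def items(self) -> list[str]:
        return [str(c) for c in self.ranks.columns]

    def to_long(self) -> pd.DataFrame:
        long = self.ranks.stack().rename("value").reset_index()
        long.columns = ["rater_id", "item_id", "value"]
        return long


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p_value: float
    unit: str  # "single" or "average"
    icc_single: float
    ci_single: tuple[float, float]
    icc_average: float
    ci_average: tuple[float, float]
    n_items: int
    n_raters: int
    degenerate: bool = False


def _as_matrix(data: RankingMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(data, RankingMatrix):
        return data.ranks.to_numpy(dtype=float)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def icc_absolute_agreement(
    data: RankingMatrix | pd.DataFrame | np.ndarray,
    *,
    unit: str = "single",
    confidence: float = 0.95,
) -> ICCResult:
    """Two-way absolute-agreement ICC with F-based confidence interval.

    ``data`` is a complete raters-in-columns-or-rows table: rows are
    scored items (rank targets), columns raters, for a plain array or
    a RankingMatrix (which stores raters in rows and is transposed
    internally).  Variance components come from the two-way ANOVA mean
    squares; the p-value tests ICC = 0 via F = MSR/MSE.

    A matrix with zero residual variance (perfect agreement) yields ICC
    1 with a degenerate interval and is flagged; so does a matrix with
    zero total variance.
    """
    if unit not in ("single", "average"):
        raise ValueError("unit must be 'single' or 'average'")
    x = _as_matrix(data)
    if isinstance(data, RankingMatrix):
        x = x.T  # items in rows
    if x.ndim != 2:
        raise ValueError("expected a 2-D ratings table")
    if np.isnan(x).any():
        raise ValueError("ICC requires a complete matrix (no missing cells)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 items and >= 2 raters")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    scale = max(x.var(), 1.0)
    tol = 1e-12 * scale

    if x.var() <= tol:  # all cells equal
        one = (1.0, (1.0, 1.0))
        return ICCResult(
            1.0, (1.0, 1.0), 1.0, unit, *one, *one, n, k, degenerate=True
        )

    def _icc_a1(msr_, msc_, mse_):
        return (msr_ - mse_) / (msr_ + (k - 1) * mse_ + k / n * (msc_ - mse_))

    def _sb(r1):  # Spearman-Brown step-up to the k-rater average
        return k * r1 / (1.0 + (k - 1) * r1)

    if mse <= tol:
        # perfect agreement up to rater offsets: variance ratio is exact
        icc1 = _icc_a1(msr, msc, 0.0)
        icck = (msr - 0.0) / (msr + msc / n) if (msr + msc / n) > 0 else 1.0
        ci1 = (icc1, icc1)
        cik = (icck, icck)
        chosen = (icc1, ci1) if unit == "single" else (icck, cik)
        return ICCResult(
            chosen[0], chosen[1], 0.0, unit, icc1, ci1, icck, cik, n, k,
            degenerate=True,
        )

    icc1 = _icc_a1(msr, msc, mse)
    icck = (msr - mse) / (msr + (msc - mse) / n)

    f_obs = msr / mse
    p_value = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))

    # Satterthwaite df for the absolute-agreement interval
    alpha = 1.0 - confidence
    r = icc1
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    denom_const = k * msc + (k * n - k - n) * mse
    lower1 = n * (msr - f_l * mse) / (f_l * denom_const + n * msr)
    upper1 = n * (f_u * msr - mse) / (denom_const + n * f_u * msr)
    ci1 = (float(lower1), float(upper1))
    cik = (float(_sb(lower1)), float(_sb(upper1)))

    chosen = (icc1, ci1) if unit == "single" else (icck, cik)
    return ICCResult(
        float(chosen[0]),
        chosen[1],
        p_value,
        unit,
        float(icc1),
        ci1,
        float(icck),
        cik,
        n,
        k,
    )


def _tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """Median and Tukey's inclusive hinges (halves include the median
    when n is odd)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    med = float(np.median(v))
    half = (n + 1) // 2
    q1 = float(np.median(v[:half]))
    q3 = float(np.median(v[n - half:]))
    return med, q1, q3


def summarize_ranks(matrix: RankingMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-item median [Q1, Q3] of ranks across raters."""
    ranks = matrix.ranks if isinstance(matrix, RankingMatrix) else matrix
    rows = []
    for item in ranks.columns:
        med, q1, q3 = _tukey_hinges(ranks[item].to_numpy(dtype=float))
        rows.append(
            {"item_id": item, "median": med, "q1": q1, "q3": q3,
             "n_raters": len(ranks)}
        )
    return pd.DataFrame(rows)


def resolve_line_scale(
    positions: pd.DataFrame, *, least_is_low: bool = True
) -> RankingMatrix:
    """Convert continuous line-scale marks into per-rater rankings.

    ``positions`` is a rater x item table of marks on the line scale
    (one mark per item per rater); with ``least_is_low`` the smallest
    mark receives rank 1.  Exact ties resolve to midranks and set the
    ``has_ties`` flag.
    """
    if positions.isna().any().any():
        raise ValueError("one position per item per rater is required")
    vals = positions.to_numpy(dtype=float)
    if not least_is_low:
        vals = -vals
    ranked = np.vstack([stats.rankdata(row, method="average") for row in vals])
    has_ties = any(len(np.unique(row)) < len(row) for row in vals)
    ranks = pd.DataFrame(
        ranked, index=positions.index, columns=positions.columns
    )
    return RankingMatrix(ranks, has_ties=has_ties)
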