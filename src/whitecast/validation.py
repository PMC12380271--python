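"""ICH-style method validation for the colorimetric protocols.

Covers the validation battery applied to the L* measurements: daily
device suitability (RSD <= 2% on acrylic standards), linearity of L*
against ZnO %, accuracy against reference values, inter-/intra-day
precision as %RSD, normality-gated correlation (Pearson after a passing
Shapiro-Wilk test, Spearman otherwise), and Fisher-Z equivalence testing
of correlation coefficients between protocols.

Acceptance limits are pure configuration, evaluated by one reusable
gate: accuracy within 80-120%, precision < 10% RSD, adjusted R^2 >
0.650.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colorimetry import delta_e

__all__ = [
    "LinearityResult",
    "CorrelationResult",
    "SuitabilityReport",
    "AccuracyEntry",
    "PrecisionEntry",
    "AcceptanceLimits",
    "DEFAULT_LIMITS",
    "device_suitability",
    "fit_linearity",
    "gated_correlation",
    "accuracy_in_vivo",
    "accuracy_in_vitro",
    "precision_rsd",
    "fisher_z",
    "z_difference",
    "check_gates",
]


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    slope_sd: float
    intercept: float
    intercept_sd: float
    r2: float
    adjusted_r2: float
    n: int
    linearity_range: tuple[float, float]


class CorrelationMethod(str, enum.Enum):
    PEARSON = "pearson"
    SPEARMAN = "spearman"


@dataclass(frozen=True)
class CorrelationResult:
    method: CorrelationMethod
    coefficient: float
    p_value: float
    n: int
    normality_p: float


@dataclass(frozen=True)
class SuitabilityReport:
    passed: bool
    rsd: pd.DataFrame  # sheet x channel RSDs, NaN where indeterminate
    indeterminate: list[tuple[str, str]]
    limit: float


@dataclass(frozen=True)
class AccuracyEntry:
    factor: str
    accuracy_pct: float
    ci_low: float
    ci_high: float
    n: int
    reference: float | tuple[float, float, float]
    convention: str


@dataclass(frozen=True)
class PrecisionEntry:
    factor: str
    timepoint: str
    mode: str
    rsd_min: float
    rsd_max: float
    n_groups: int


@dataclass(frozen=True)
class AcceptanceLimits:
    """Validation gates; defaults follow the ICH-style study limits."""

    accuracy_low: float = 80.0
    accuracy_high: float = 120.0
    max_rsd: float = 10.0
    min_adjusted_r2: float = 0.650


DEFAULT_LIMITS = AcceptanceLimits()


# --------------------------------------------------------------------------
# device suitability


def _rsd(values: np.ndarray) -> float:
    """Percent relative standard deviation, sample (n-1) SD."""
    mean = values.mean()
    return 100.0 * values.std(ddof=1) / abs(mean)


def device_suitability(
    readings: pd.DataFrame,
    *,
    limit: float = 2.0,
    mean_floor: float = 0.5,
) -> SuitabilityReport:
    """Daily colorimeter check on black and white acrylic sheets.

    ``readings`` needs columns background, L, a, b with >= 3 replicates
    per sheet.  Per sheet and channel, RSD = 100 * sd / |mean|; the
    device passes when every determinate RSD <= ``limit``.  Channels
    whose |mean| falls below ``mean_floor`` (e.g. a* on a neutral sheet)
    would divide by near-zero and are reported indeterminate instead.
    """
    out = {}
    indeterminate: list[tuple[str, str]] = []
    for sheet, grp in readings.groupby("background", sort=True):
        if len(grp) < 3:
            raise ValueError(
                f"need >= 3 replicates per sheet, got {len(grp)} for {sheet}"
            )
        row = {}
        for channel in ("L", "a", "b"):
            vals = grp[channel].to_numpy(dtype=float)
            if abs(vals.mean()) < mean_floor:
                row[channel] = float("nan")
                indeterminate.append((str(sheet), channel))
            else:
                row[channel] = _rsd(vals)
        out[str(sheet)] = row
    rsd = pd.DataFrame(out).T
    passed = bool(np.all((rsd.to_numpy() <= limit) | np.isnan(rsd.to_numpy())))
    return SuitabilityReport(passed, rsd, indeterminate, limit)


# --------------------------------------------------------------------------
# linearity


def fit_linearity(
    zno_pct: Sequence[float], L_star: Sequence[float]
) -> LinearityResult:
    """Ordinary least squares of L* on ZnO %.

    Reports slope and intercept with their standard errors and the
    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2) for the one-predictor
    model.  Requires >= 3 distinct ZnO levels.
    """
    x = np.asarray(zno_pct, dtype=float)
    y = np.asarray(L_star, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("zno_pct and L_star must be equal-length 1-D")
    if len(np.unique(x)) < 2:
        raise ValueError("singular design: all ZnO % identical")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct ZnO levels for a linearity claim")
    fit = stats.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LinearityResult(
        slope=float(fit.slope),
        slope_sd=float(fit.stderr),
        intercept=float(fit.intercept),
        intercept_sd=float(fit.intercept_stderr),
        r2=float(r2),
        adjusted_r2=float(adj),
        n=n,
        linearity_range=(float(x.min()), float(x.max())),
    )


# --------------------------------------------------------------------------
# normality-gated correlation


def gated_correlation(
    x: Sequence[float], y: Sequence[float], *, alpha: float = 0.05
) -> CorrelationResult:
    """Pearson if the response passes Shapiro-Wilk at ``alpha``, else Spearman.

    The normality gate is applied to the L* (response) values; its
    p-value is carried in the result so the routing is auditable.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if len(xv) < 4:
        raise ValueError("need n >= 4 for the normality gate")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    normality_p = float(stats.shapiro(yv).pvalue)
    if normality_p >= alpha:
        res = stats.pearsonr(xv, yv)
        method = CorrelationMethod.PEARSON
    else:
        res = stats.spearmanr(xv, yv)
        method = CorrelationMethod.SPEARMAN
    return CorrelationResult(
        method=method,
        coefficient=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(xv),
        normality_p=normality_p,
    )


# --------------------------------------------------------------------------
# accuracy


def _t_interval(values: np.ndarray) -> tuple[float, float, float]:
    """Mean and 95% t-interval; NaN bounds for n < 2."""
    n = len(values)
    mean = float(values.mean())
    if n < 2:
        return mean, float("nan"), float("nan")
    sem = values.std(ddof=1) / math.sqrt(n)
    half = float(stats.t.ppf(0.975, n - 1) * sem)
    return mean, mean - half, mean + half


def accuracy_in_vivo(
    measured: Mapping[str, Sequence[float]] | pd.DataFrame,
    reference: Mapping[str, float],
    *,
    convention: str = "ratio",
) -> list[AccuracyEntry]:
    """Accuracy of baseline L* per ITA subtype against reference values.

    ``measured`` maps each subtype to the per-subject baseline mean L*
    values observed for it (or a DataFrame with columns subtype,
    baseline_L).  ``reference`` supplies the literature mean L* per
    subtype; a subtype without a reference raises.

    With the default ``ratio`` convention each subject contributes
    100 * measured / reference and the entry is the mean with its 95%
    t-interval across subjects.  The ``absolute`` convention uses
    100 - |measured - reference| instead.
    """
    if isinstance(measured, pd.DataFrame):
        measured = {
            str(st): grp["baseline_L"].tolist()
            for st, grp in measured.groupby("subtype", sort=True)
        }
    if convention not in ("ratio", "absolute"):
        raise ValueError(f"unknown accuracy convention {convention!r}")
    entries = []
    for subtype, values in measured.items():
        if subtype not in reference:
            raise ValueError(f"no reference L* configured for subtype {subtype!r}")
        ref = float(reference[subtype])
        vals = np.asarray(values, dtype=float)
        if convention == "ratio":
            acc = 100.0 * vals / ref
        else:
            acc = 100.0 - np.abs(vals - ref)
        mean, lo, hi = _t_interval(acc)
        entries.append(
            AccuracyEntry(subtype, mean, lo, hi, len(vals), ref, convention)
        )
    return entries


THEORETICAL_BLACK = (0.0, 0.0, 0.0)
THEORETICAL_WHITE = (100.0, 0.0, 0.0)


def accuracy_in_vitro(
    measured: pd.DataFrame,
    *,
    targets: Mapping[str, tuple[float, float, float]] | None = None,
) -> list[AccuracyEntry]:
    """Accuracy of standard-paint readings against theoretical anchors.

    ``measured`` has columns paint ('black'/'white'), background, L, a,
    b.  Accuracy per reading is 100 - deltaE_CIE76 to the theoretical
    anchor (pure black L*=0 or pure white L*=100, a*=b*=0); a ratio is
    undefined against theoretical black, which motivates the distance
    convention.  Entries aggregate mean [CI95%] per paint x background.
    """
    if targets is None:
        targets = {"black": THEORETICAL_BLACK, "white": THEORETICAL_WHITE}
    entries = []
    for (paint, background), grp in measured.groupby(
        ["paint", "background"], sort=True
    ):
        if paint not in targets:
            raise ValueError(f"no theoretical target for paint {paint!r}")
        anchor = targets[paint]
        acc = np.asarray(
            [
                100.0 - delta_e((r.L, r.a, r.b), anchor)
                for r in grp.itertuples()
            ]
        )
        mean, lo, hi = _t_interval(acc)
        entries.append(
            AccuracyEntry(
                f"{paint}_paint_on_{background}",
                mean,
                lo,
                hi,
                len(acc),
                anchor,
                "delta_e",
            )
        )
    return entries


# --------------------------------------------------------------------------
# precision


def precision_rsd(
    readings: pd.DataFrame,
    factor: str,
    *,
    mode: str = "inter_day",
) -> list[PrecisionEntry]:
    """Min/max %RSD of L* per factor level, split by timepoint.

    Replicate groups are formed by (factor level, formulation) and, in
    ``intra_day`` mode, additionally by day; ``inter_day`` pools the
    days of a group.  The entry for a factor level reports the range of
    group RSDs before and after application.  Groups with fewer than 2
    readings are skipped with a warning, never silently.
    """
    if mode not in ("inter_day", "intra_day"):
        raise ValueError(f"mode must be inter_day or intra_day, got {mode!r}")
    group_cols = [factor, "timepoint", "formulation_id"]
    if mode == "intra_day":
        group_cols.append("day")

    per_group: dict[tuple[str, str], list[float]] = {}
    for keys, grp in readings.groupby(group_cols, sort=True):
        level, timepoint = str(keys[0]), str(keys[1])
        vals = grp["L"].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(
                f"precision group {keys} has a single replicate; skipped",
                stacklevel=2,
            )
            continue
        per_group.setdefault((level, timepoint), []).append(_rsd(vals))

    entries = []
    for (level, timepoint), rsds in sorted(per_group.items()):
        entries.append(
            PrecisionEntry(
                factor=level,
                timepoint=timepoint,
                mode=mode,
                rsd_min=float(min(rsds)),
                rsd_max=float(max(rsds)),
                n_groups=len(rsds),
            )
        )
    return entries


# --------------------------------------------------------------------------
# Fisher-Z equivalence


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"correlation must lie strictly in (-1, 1), got {r}")
    return float(np.arctanh(r))


def z_difference(
    r1: float, n1: int, r2: float, n2: int, *, criterion: float = 1.96
) -> tuple[float, bool]:
    """Standardized difference of two independent correlations.

    Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) with z = fisher_z(r).
    Returns (Z, significant) where significance means |Z| >= criterion
    (1.96 for a two-sided 5% level).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher-Z comparison needs n > 3 in both samples")
    z = (fisher_z(r1) - fisher_z(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(z), bool(abs(z) >= criterion)


# --------------------------------------------------------------------------
# acceptance gates


def check_gates(
    *,
    accuracy: Iterable[AccuracyEntry] = (),
    precision: Iterable[PrecisionEntry] = (),
    linearity: Iterable[LinearityResult] = (),
    limits: AcceptanceLimits = DEFAULT_LIMITS,
) -> dict[str, bool]:
    """Evaluate the configured validation gates on a set of results.

    Returns per-gate booleans plus an overall flag.  Gates with no
    inputs are vacuously true (and absent from the report).
    """
    report: dict[str, bool] = {}
    acc = list(accuracy)
    if acc:
        report["accuracy"] = all(
            limits.accuracy_low <= e.accuracy_pct <= limits.accuracy_high
            for e in acc
        )
    prec = list(precision)
    if prec:
        report["precision"] = all(e.rsd_max < limits.max_rsd for e in prec)
    lin = list(linearity)
    if lin:
        report["linearity"] = all(
            e.adjusted_r2 > limits.min_adjusted_r2 for e in lin
        )
    report["all"] = all(report.values()) if report else True
    return report
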