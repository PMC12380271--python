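"""The white cast score and its four-band interpretation.

The score normalizes the post-application lightness shift by the
headroom the substrate leaves below reference white:

    score = (L*_f - L*_i) / (100 - L*_i)

with L*_i the baseline and L*_f the post-application lightness.  It is
0 when nothing changed, 1 when the substrate saturates at pure white,
and negative (flagged, never clipped) when the post reading is darker
than baseline.  Because the denominator shrinks as the substrate
lightens, the same additive L* gain scores higher on lighter skin: the
score expresses white cast *relative to the skin tone it sits on*.

Scores are interpreted through four bands (no white cast / reasonable /
threshold / unacceptable) delimited by three ascending edges.  The
numeric edges are configuration, not universal constants; a calibration
helper derives them from scored data plus a desired formulation-to-band
mapping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormulationSpec",
    "LAB_FORMULATION_PCTS",
    "DEFAULT_FORMULATIONS",
    "Band",
    "BandEdges",
    "DEFAULT_BAND_EDGES_IN_VIVO",
    "DEFAULT_BAND_EDGES_IN_VITRO",
    "WhiteCastResult",
    "white_cast_score",
    "interpret_score",
    "score_study",
    "summarize_scores",
    "calibrate_band_edges",
]

#: ZnO mass percentages of the laboratory test formulations.
LAB_FORMULATION_PCTS = (0.0, 5.0, 10.0, 20.0, 30.0)
BENCHMARK_PCT = 14.7


@dataclass(frozen=True)
class FormulationSpec:
    """A test formulation: identity, ZnO mass percent, benchmark flag."""

    formulation_id: str
    zno_pct: float
    is_benchmark: bool = False

    def __post_init__(self) -> None:
        if self.is_benchmark:
            return
        if self.zno_pct not in LAB_FORMULATION_PCTS:
            raise ValueError(
                f"laboratory formulations use ZnO % in {LAB_FORMULATION_PCTS}, "
                f"got {self.zno_pct}"
            )


#: The study's six formulations: five laboratory ZnO levels plus the
#: commercial 14.7% ZnO benchmark.  The benchmark is excluded from model
#: fitting because it is formulated differently (particle size/coating).
DEFAULT_FORMULATIONS: tuple[FormulationSpec, ...] = (
    FormulationSpec("zno_0", 0.0),
    FormulationSpec("zno_5", 5.0),
    FormulationSpec("zno_10", 10.0),
    FormulationSpec("zno_20", 20.0),
    FormulationSpec("zno_30", 30.0),
    FormulationSpec("bm", BENCHMARK_PCT, is_benchmark=True),
)


class Band(str, enum.Enum):
    NO_WHITE_CAST = "no_white_cast"
    REASONABLE = "reasonable"
    THRESHOLD = "threshold"
    UNACCEPTABLE = "unacceptable"


_BAND_ORDER = (
    Band.NO_WHITE_CAST,
    Band.REASONABLE,
    Band.THRESHOLD,
    Band.UNACCEPTABLE,
)


@dataclass(frozen=True)
class BandEdges:
    """Three ascending score thresholds separating the four bands."""

    reasonable: float
    threshold: float
    unacceptable: float

    def __post_init__(self) -> None:
        e = (self.reasonable, self.threshold, self.unacceptable)
        if not (e[0] < e[1] < e[2]):
            raise ValueError(f"band edges must be strictly ascending, got {e}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.reasonable, self.threshold, self.unacceptable)


# Defaults calibrated on the synthetic default study (see
# whitecast.synthetic_data and docs/methods.md): they reproduce the
# published formulation-to-band mapping on data generated from the
# published linear L*-vs-ZnO% responses.  The in vitro black-background
# scale differs because the dark substrate leaves far more headroom.
DEFAULT_BAND_EDGES_IN_VIVO = BandEdges(0.02, 0.055, 0.12)
DEFAULT_BAND_EDGES_IN_VITRO = BandEdges(0.05, 0.15, 0.30)


@dataclass(frozen=True)
class WhiteCastResult:
    """Score of one substrate x formulation pair."""

    substrate_id: str
    formulation_id: str
    L_i: float
    L_f: float
    score: float
    band: Band
    negative_flag: bool = False


def white_cast_score(L_i: float, L_f: float) -> float:
    """Normalized white cast score (L_f - L_i) / (100 - L_i).

    ``L_i`` is the baseline lightness, ``L_f`` the post-application
    lightness.  Negative values (post darker than baseline) are returned
    as-is; they indicate a measurement problem and are flagged upstream.
    """
    if not 0.0 <= L_i <= 100.0 or not 0.0 <= L_f <= 100.0:
        raise ValueError("L* values must lie in [0, 100]")
    if L_i == 100.0:
        raise ZeroDivisionError(
            "substrate already at reference white: score undefined"
        )
    return (L_f - L_i) / (100.0 - L_i)


def interpret_score(
    score: float, band_edges: BandEdges | Sequence[float]
) -> Band:
    """Four-band lookup: half-open intervals, closed on the left.

    score < reasonable edge -> no white cast; then reasonable,
    threshold, unacceptable.  Scores on an edge belong to the band the
    edge opens.
    """
    if not isinstance(band_edges, BandEdges):
        band_edges = BandEdges(*band_edges)
    edges = band_edges.as_tuple()
    idx = int(np.searchsorted(edges, score, side="right"))
    return _BAND_ORDER[idx]


def _mean_L(group: pd.DataFrame) -> float:
    return float(group["L"].mean())


def score_study(
    readings: pd.DataFrame,
    band_edges: BandEdges | Sequence[float],
    *,
    per_site: bool = False,
) -> pd.DataFrame:
    """Score every substrate x formulation pair of a measurement table.

    Site-level L* readings are averaged within (substrate, formulation,
    timepoint) before scoring (default).  With ``per_site=True`` each
    site is scored first and the per-site scores averaged, an alternate
    aggregation exposed for sensitivity checks.

    Returns one row per pair: substrate_id, formulation_id, zno_pct,
    L_i, L_f, score, band, negative_flag.  Raises with a description of
    every missing (substrate, formulation, timepoint) cell.
    """
    if not isinstance(band_edges, BandEdges):
        band_edges = BandEdges(*band_edges)

    missing: list[str] = []
    rows = []
    for (substrate, formulation), grp in readings.groupby(
        ["substrate_id", "formulation_id"], sort=True
    ):
        before = grp[grp["timepoint"] == "before"]
        after = grp[grp["timepoint"] == "after"]
        if before.empty or after.empty:
            for tp, sub in (("before", before), ("after", after)):
                if sub.empty:
                    missing.append(f"({substrate}, {formulation}, {tp})")
            continue
        if per_site:
            merged = pd.merge(
                before[["site", "day", "L"]],
                after[["site", "day", "L"]],
                on=["site", "day"],
                suffixes=("_i", "_f"),
            )
            if merged.empty:
                missing.append(f"({substrate}, {formulation}, paired sites)")
                continue
            site_scores = [
                white_cast_score(r.L_i, r.L_f) for r in merged.itertuples()
            ]
            L_i, L_f = _mean_L(before), _mean_L(after)
            score = float(np.mean(site_scores))
        else:
            L_i, L_f = _mean_L(before), _mean_L(after)
            score = white_cast_score(L_i, L_f)
        rows.append(
            {
                "substrate_id": substrate,
                "formulation_id": formulation,
                "zno_pct": float(grp["zno_pct"].iloc[0]),
                "L_i": L_i,
                "L_f": L_f,
                "score": score,
                "band": interpret_score(score, band_edges).value,
                "negative_flag": score < 0.0,
            }
        )
    if missing:
        raise ValueError(
            "missing baseline or post readings for cells: " + ", ".join(missing)
        )
    return pd.DataFrame(rows)


def summarize_scores(
    results: pd.DataFrame, band_edges: BandEdges | Sequence[float]
) -> pd.DataFrame:
    """Formulation-level mean +/- SEM of scores, with the band of the mean.

    Mirrors the published per-formulation score chart: formulation, n,
    mean score, SEM, band.
    """
    if not isinstance(band_edges, BandEdges):
        band_edges = BandEdges(*band_edges)
    out = []
    for formulation, grp in results.groupby("formulation_id", sort=False):
        scores = grp["score"].to_numpy(dtype=float)
        n = len(scores)
        mean = float(scores.mean())
        sem = float(scores.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        out.append(
            {
                "formulation_id": formulation,
                "zno_pct": float(grp["zno_pct"].iloc[0]),
                "n": n,
                "mean_score": mean,
                "sem": sem,
                "band": interpret_score(mean, band_edges).value,
            }
        )
    df = pd.DataFrame(out).sort_values("zno_pct", ignore_index=True)
    return df


def calibrate_band_edges(
    mean_scores: Mapping[str, float], band_of: Mapping[str, Band | str]
) -> BandEdges:
    """Derive band edges from scored data plus a desired band mapping.

    Each edge is placed midway between the highest mean score of one
    band and the lowest mean score of the next.  Raises if the desired
    mapping is not separable (a lower band's scores overlap a higher
    band's) or a band other than the extremes is empty on one side.
    """
    per_band: dict[Band, list[float]] = {b: [] for b in _BAND_ORDER}
    for fid, band in band_of.items():
        if fid not in mean_scores:
            raise ValueError(f"no mean score for formulation {fid!r}")
        per_band[Band(band)].append(float(mean_scores[fid]))
    for band, scores in per_band.items():
        if not scores:
            raise ValueError(f"band {band.value} has no formulation assigned")

    edges = []
    for lo, hi in zip(_BAND_ORDER[:-1], _BAND_ORDER[1:]):
        lower_max = max(per_band[lo])
        upper_min = min(per_band[hi])
        if upper_min <= lower_max:
            raise ValueError(
                f"bands {lo.value} and {hi.value} are not separable: "
                f"{lower_max:.4f} >= {upper_min:.4f}"
            )
        edges.append(0.5 * (lower_max + upper_min))
    return BandEdges(*edges)
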