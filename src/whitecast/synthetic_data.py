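"""Synthetic white cast studies with the statistical structure the
analysis assumes.

No raw clinical measurements are deposited for this kind of study, so
the pipeline ships a generator that emulates both protocols end to end:

* **in vivo** — a panel of volunteers spanning the Very Light to Brown
  ITA° subtypes, six 3x3 cm forearm squares (one per formulation),
  three measurement sites per square, before/after timepoints.  Post
  lightness follows the published per-pigmentation-category linear
  L*-vs-ZnO% responses; noise is decomposed into between-subject,
  between-square and site components calibrated against the published
  per-category precision envelopes and correlation strengths (see
  docs/methods.md).
* **in vitro** — VITRO-SKIN pieces over black or white acrylic, with
  per-piece, per-day and per-site noise so inter- and intra-day
  precision are distinguishable.
* **rankings** — raters perturb a true least-to-most white cast order
  by adjacent transpositions at a configurable swap rate.
* **questionnaire** — categorical draws from configured response
  probabilities.

All generators are deterministic given (design, model, seed).
Generated L* values are clipped to [0, 100]; clip events are counted in
``df.attrs["n_clipped"]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .colorimetry import (
    ItaSubtype,
    Site,
    categorize_pigmentation,
    classify_ita,
    compute_ita,
    subtype_interval,
)
from .reliability import RankingMatrix
from .scoring import DEFAULT_FORMULATIONS, FormulationSpec

__all__ = [
    "StudyDesign",
    "GeneratorModel",
    "GenerationError",
    "DEFAULT_DESIGN",
    "DEFAULT_MODEL",
    "generate_in_vivo",
    "generate_in_vitro",
    "generate_rankings",
    "generate_questionnaire",
    "generate_suitability_checks",
    "generate_paint_checks",
    "calibrate_total_noise",
    "implied_pearson_r",
]


class GenerationError(RuntimeError):
    pass


_SITES = tuple(s.value for s in Site)


@dataclass(frozen=True)
class StudyDesign:
    """Panel composition and measurement layout of a study.

    The default volunteer composition (1 very light, 4 light, 1
    intermediate, 2 tan, 5 brown = 13) realizes the published category
    counts of 5 light / 3 medium / 5 dark pigmentation volunteers; the
    in vitro arm uses 6 replicates per formulation per background,
    decomposed as 3 sites x 2 days.
    """

    n_per_subtype: Mapping[str, int] = field(
        default_factory=lambda: {
            "very_light": 1,
            "light": 4,
            "intermediate": 1,
            "tan": 2,
            "brown": 5,
        }
    )
    formulations: tuple[FormulationSpec, ...] = DEFAULT_FORMULATIONS
    sites: tuple[str, ...] = _SITES
    vitro_days: int = 2
    backgrounds: tuple[str, ...] = ("black_acrylic", "white_acrylic")

    @property
    def n_volunteers(self) -> int:
        return sum(self.n_per_subtype.values())

    def lab_formulations(self) -> list[FormulationSpec]:
        return [f for f in self.formulations if not f.is_benchmark]


@dataclass(frozen=True)
class GeneratorModel:
    """Response and noise model behind the synthetic studies.

    Baselines and slopes are the published per-category (in vivo) and
    per-background (in vitro) linear model coefficients.  The noise SDs
    are calibrated so simulated within-category correlation strength
    and %RSD precision match the published validation metrics; the
    decomposition into subject/square/site (in vivo) and
    piece/day/site (in vitro) levels is documented in docs/methods.md.
    The benchmark's whitening is expressed as an equivalent laboratory
    ZnO %, lower in vitro than in vivo to reproduce the observed
    reversal of its position relative to the 5% formulation.
    """

    # in vivo linear response, keyed by pigmentation category
    category_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"light": 63.66, "medium": 55.94, "dark": 46.28}
    )
    category_slope: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.2801, "medium": 0.3570, "dark": 0.5057}
    )
    subject_sd: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.8, "medium": 0.8, "dark": 0.8}
    )
    square_sd: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.5, "medium": 0.5, "dark": 0.5}
    )
    site_sd_vivo: Mapping[str, float] = field(
        default_factory=lambda: {"light": 1.87, "medium": 2.28, "dark": 2.85}
    )
    bm_equivalent_zno_vivo: float = 7.5
    bm_equivalent_zno_vitro: float = 3.0

    # in vitro linear response, keyed by background
    background_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"black_acrylic": 36.59, "white_acrylic": 87.22}
    )
    background_slope: Mapping[str, float] = field(
        default_factory=lambda: {"black_acrylic": 1.274, "white_acrylic": 0.09224}
    )
    piece_sd: Mapping[str, float] = field(
        default_factory=lambda: {"black_acrylic": 1.3, "white_acrylic": 0.3}
    )
    day_sd: Mapping[str, float] = field(
        default_factory=lambda: {"black_acrylic": 1.2, "white_acrylic": 0.25}
    )
    site_sd_vitro: Mapping[str, float] = field(
        default_factory=lambda: {"black_acrylic": 0.8, "white_acrylic": 0.2}
    )
    background_ab: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "black_acrylic": (1.5, 6.0),
            "white_acrylic": (0.5, 4.0),
        }
    )

    # chromatic plumbing (a*, b* are carried but not analysis-bearing)
    category_a: Mapping[str, float] = field(
        default_factory=lambda: {"light": 7.5, "medium": 9.0, "dark": 10.5}
    )
    ab_noise_sd: float = 0.35
    chroma_attenuation_per_pct: float = 0.015
    skin_b_range: tuple[float, float] = (4.0, 30.0)

    # perception layers
    swap_rate: float = 0.05
    true_rank_order: tuple[str, ...] = (
        "zno_0", "bm", "zno_5", "zno_10", "zno_20", "zno_30",
    )
    questionnaire_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "concern": {
                "strongly_agree": 7 / 13,
                "agree": 4 / 13,
                "disagree": 2 / 13,
                "strongly_disagree": 0.0,
            },
            "face_tradeoff": {
                "zno_0": 3 / 13, "zno_5": 3 / 13, "zno_10": 4 / 13,
                "zno_20": 0.0, "zno_30": 1 / 13, "bm": 2 / 13,
            },
            "body_tradeoff": {
                "zno_0": 1 / 13, "zno_5": 1 / 13, "zno_10": 5 / 13,
                "zno_20": 1 / 13, "zno_30": 2 / 13, "bm": 3 / 13,
            },
        }
    )

    # standards used by the suitability / accuracy plumbing
    acrylic_L: Mapping[str, float] = field(
        default_factory=lambda: {"black_acrylic": 25.8, "white_acrylic": 92.5}
    )
    acrylic_noise_sd: float = 0.15
    paint_bias_L: Mapping[str, float] = field(
        default_factory=lambda: {"black": 10.8, "white": -7.4}
    )
    paint_noise_sd: float = 0.8


DEFAULT_DESIGN = StudyDesign()
DEFAULT_MODEL = GeneratorModel()
DEFAULT_SEED = 0


# --------------------------------------------------------------------------
# calibration helpers


def implied_pearson_r(
    slope: float, sigma_total: float,
    zno_levels: Sequence[float] = (0.0, 5.0, 10.0, 20.0, 30.0),
) -> float:
    """Population Pearson r of L* vs ZnO% implied by slope and noise SD."""
    z = np.asarray(zno_levels, dtype=float)
    signal = slope**2 * z.var()
    return math.sqrt(signal / (signal + sigma_total**2))


def calibrate_total_noise(
    slope: float, target_r: float,
    zno_levels: Sequence[float] = (0.0, 5.0, 10.0, 20.0, 30.0),
) -> float:
    """Total noise SD that makes the linear response correlate at
    ``target_r`` over a balanced design on ``zno_levels``."""
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must lie in (0, 1)")
    z = np.asarray(zno_levels, dtype=float)
    return float(slope * z.std() * math.sqrt(1.0 / target_r**2 - 1.0))


# --------------------------------------------------------------------------
# in vivo


def _solve_subject_b(
    L: float, subtype: str, b_range: tuple[float, float]
) -> tuple[float, float]:
    """Baseline b* putting a subject with lightness ``L`` at the middle
    of the feasible ITA° stretch of its assigned subtype.

    Returns (ita_deg, b_star).  Raises :class:`GenerationError` when no
    positive b* in ``b_range`` can reach the subtype's interval.
    """
    lo, hi = subtype_interval(ItaSubtype(subtype))
    lo_c, hi_c = max(lo, -80.0), min(hi, 80.0)
    b_min, b_max = b_range
    dl = L - 50.0
    if dl == 0.0:
        if not lo_c <= 0.0 < hi_c:
            raise GenerationError(
                f"L*=50 forces ITA=0, outside subtype {subtype}"
            )
        return 0.0, 0.5 * (b_min + b_max)
    ang1 = math.degrees(math.atan(dl / b_max))
    ang2 = math.degrees(math.atan(dl / b_min))
    feas_lo, feas_hi = min(ang1, ang2), max(ang1, ang2)
    inter_lo, inter_hi = max(feas_lo, lo_c), min(feas_hi, hi_c)
    if inter_lo > inter_hi:
        raise GenerationError(
            f"no b* in {b_range} reaches subtype {subtype} from L*={L:.2f}"
        )
    ita = 0.5 * (inter_lo + inter_hi)
    b = dl / math.tan(math.radians(ita))
    return ita, b


def generate_in_vivo(
    design: StudyDesign = DEFAULT_DESIGN,
    model: GeneratorModel = DEFAULT_MODEL,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the in vivo forearm panel.

    Returns ``(measurements, profiles)``: the measurement table (one
    row per site reading, both timepoints) and the per-subject profile
    table with realized baseline summaries and ITA° classification.
    Each volunteer visits on their own day, so pooling subjects doubles
    as the inter-day axis of the in vivo precision analysis.
    """
    rng = np.random.default_rng(seed)
    n_clipped = 0
    rows: list[dict] = []
    subjects: list[dict] = []

    idx = 0
    for subtype, count in design.n_per_subtype.items():
        category = categorize_pigmentation(ItaSubtype(subtype)).value
        for _ in range(count):
            idx += 1
            sid = f"S{idx:02d}"
            base_L = model.category_baseline[category] + rng.normal(
                0.0, model.subject_sd[category]
            )
            base_L = float(np.clip(base_L, 0.0, 99.0))
            _, subj_b = _solve_subject_b(base_L, subtype, model.skin_b_range)
            subj_a = model.category_a[category] + rng.normal(0.0, 0.5)
            subjects.append(
                {
                    "subject_id": sid,
                    "assigned_subtype": subtype,
                    "category": category,
                    "base_L": base_L,
                    "base_a": subj_a,
                    "base_b": subj_b,
                    "day": idx,
                }
            )

    for subj in subjects:
        category = subj["category"]
        slope = model.category_slope[category]
        for form in design.formulations:
            square = rng.normal(0.0, model.square_sd[category])
            mu = subj["base_L"] + square
            zno_eff = (
                model.bm_equivalent_zno_vivo if form.is_benchmark else form.zno_pct
            )
            shrink = max(0.0, 1.0 - model.chroma_attenuation_per_pct * zno_eff)
            for timepoint in ("before", "after"):
                shift = 0.0 if timepoint == "before" else slope * zno_eff
                f = 1.0 if timepoint == "before" else shrink
                for site in design.sites:
                    L = mu + shift + rng.normal(
                        0.0, model.site_sd_vivo[category]
                    )
                    clipped = float(np.clip(L, 0.0, 100.0))
                    n_clipped += clipped != L
                    rows.append(
                        {
                            "panel": "in_vivo",
                            "substrate_id": subj["subject_id"],
                            "background": "skin",
                            "formulation_id": form.formulation_id,
                            "zno_pct": form.zno_pct,
                            "timepoint": timepoint,
                            "site": site,
                            "day": subj["day"],
                            "L": clipped,
                            "a": f * subj["base_a"]
                            + rng.normal(0.0, model.ab_noise_sd),
                            "b": f * subj["base_b"]
                            + rng.normal(0.0, model.ab_noise_sd),
                        }
                    )

    measurements = pd.DataFrame(rows)
    measurements.attrs["n_clipped"] = int(n_clipped)

    profiles = []
    baseline = measurements[measurements["timepoint"] == "before"]
    for subj in subjects:
        mine = baseline[baseline["substrate_id"] == subj["subject_id"]]
        mean_L = float(mine["L"].mean())
        mean_b = float(mine["b"].mean())
        ita = compute_ita(mean_L, mean_b)
        subtype = classify_ita(ita)
        profiles.append(
            {
                "subject_id": subj["subject_id"],
                "baseline_L": mean_L,
                "baseline_b": mean_b,
                "ita_deg": ita,
                "subtype": subtype.value,
                "category": categorize_pigmentation(subtype).value,
                "assigned_subtype": subj["assigned_subtype"],
            }
        )
    return measurements, pd.DataFrame(profiles)


# --------------------------------------------------------------------------
# in vitro


def generate_in_vitro(
    design: StudyDesign = DEFAULT_DESIGN,
    model: GeneratorModel = DEFAULT_MODEL,
    seed: int = DEFAULT_SEED,
    backgrounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate the VITRO-SKIN panel over the configured acrylic
    backgrounds.

    Each (background, formulation, day) triple is a fresh VITRO-SKIN
    piece carrying its own baseline offset; a shared per-day offset
    provides the inter-day component, site noise the intra-day one.
    """
    rng = np.random.default_rng(seed + 1)
    backgrounds = tuple(backgrounds or design.backgrounds)
    n_clipped = 0
    rows: list[dict] = []
    for bg in backgrounds:
        if bg not in model.background_baseline:
            raise GenerationError(f"no in vitro model for background {bg!r}")
        day_offsets = {
            day: rng.normal(0.0, model.day_sd[bg])
            for day in range(1, design.vitro_days + 1)
        }
        a0, b0 = model.background_ab[bg]
        for form in design.formulations:
            zno_eff = (
                model.bm_equivalent_zno_vitro
                if form.is_benchmark
                else form.zno_pct
            )
            shrink = max(0.0, 1.0 - model.chroma_attenuation_per_pct * zno_eff)
            for day in range(1, design.vitro_days + 1):
                piece = rng.normal(0.0, model.piece_sd[bg])
                mu = model.background_baseline[bg] + day_offsets[day] + piece
                piece_id = f"{bg}_{form.formulation_id}_d{day}"
                for timepoint in ("before", "after"):
                    shift = (
                        0.0
                        if timepoint == "before"
                        else model.background_slope[bg] * zno_eff
                    )
                    f = 1.0 if timepoint == "before" else shrink
                    for site in design.sites:
                        L = mu + shift + rng.normal(0.0, model.site_sd_vitro[bg])
                        clipped = float(np.clip(L, 0.0, 100.0))
                        n_clipped += clipped != L
                        rows.append(
                            {
                                "panel": "in_vitro",
                                "substrate_id": piece_id,
                                "background": bg,
                                "formulation_id": form.formulation_id,
                                "zno_pct": form.zno_pct,
                                "timepoint": timepoint,
                                "site": site,
                                "day": day,
                                "L": clipped,
                                "a": f * a0
                                + rng.normal(0.0, model.ab_noise_sd),
                                "b": f * b0
                                + rng.normal(0.0, model.ab_noise_sd),
                            }
                        )
    df = pd.DataFrame(rows)
    df.attrs["n_clipped"] = int(n_clipped)
    return df


# --------------------------------------------------------------------------
# perception layers


def generate_rankings(
    n_raters: int,
    true_order: Sequence[str] | None = None,
    swap_rate: float | None = None,
    seed: int = DEFAULT_SEED,
    *,
    model: GeneratorModel = DEFAULT_MODEL,
    rater_prefix: str = "rater",
) -> RankingMatrix:
    """Rankings perturbed from a true least-to-most white cast order.

    Each rater starts from ``true_order`` and sweeps it once, swapping
    each adjacent pair independently with probability ``swap_rate``.
    """
    order = list(true_order or model.true_rank_order)
    rate = model.swap_rate if swap_rate is None else float(swap_rate)
    if not 0.0 <= rate <= 1.0:
        raise ValueError("swap_rate must lie in [0, 1]")
    if len(set(order)) != len(order):
        raise ValueError("true_order must be a permutation of distinct items")
    rng = np.random.default_rng(seed + 2)
    k = len(order)
    rows = {}
    for r in range(n_raters):
        perceived = list(order)
        for i in range(k - 1):
            if rng.random() < rate:
                perceived[i], perceived[i + 1] = perceived[i + 1], perceived[i]
        ranks = {item: pos + 1 for pos, item in enumerate(perceived)}
        rows[f"{rater_prefix}_{r + 1:02d}"] = [ranks[item] for item in order]
    ranks_df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(order)
    )
    return RankingMatrix(ranks_df)


def generate_questionnaire(
    n_volunteers: int,
    response_probs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Categorical questionnaire draws, one response per volunteer per
    item."""
    probs = response_probs or DEFAULT_MODEL.questionnaire_probs
    for item, levels in probs.items():
        total = sum(levels.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"probabilities for item {item!r} sum to {total}, not 1"
            )
        if any(p < 0 for p in levels.values()):
            raise ValueError(f"negative probability in item {item!r}")
    rng = np.random.default_rng(seed + 3)
    rows = []
    for item, levels in probs.items():
        names = list(levels.keys())
        p = np.asarray([levels[name] for name in names], dtype=float)
        draws = rng.choice(len(names), size=n_volunteers, p=p)
        for v, d in enumerate(draws):
            rows.append(
                {
                    "volunteer_id": f"S{v + 1:02d}",
                    "item_id": item,
                    "response": names[d],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# instrument standards plumbing


def generate_suitability_checks(
    model: GeneratorModel = DEFAULT_MODEL,
    seed: int = DEFAULT_SEED,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate acrylic-sheet readings for the daily device check."""
    rng = np.random.default_rng(seed + 4)
    rows = []
    for bg, mean_L in model.acrylic_L.items():
        for _ in range(n_replicates):
            # calibration sheets are color-neutral: a*, b* sit near zero
            # and fall under the suitability check's indeterminate floor
            rows.append(
                {
                    "background": bg,
                    "L": mean_L + rng.normal(0.0, model.acrylic_noise_sd),
                    "a": rng.normal(0.12, 0.04),
                    "b": rng.normal(0.25, 0.06),
                }
            )
    return pd.DataFrame(rows)


def generate_paint_checks(
    model: GeneratorModel = DEFAULT_MODEL,
    seed: int = DEFAULT_SEED,
    n_replicates: int = 3,
    backgrounds: Sequence[str] = ("black_acrylic", "white_acrylic"),
) -> pd.DataFrame:
    """Standard black/white paint readings on VITRO-SKIN for the in
    vitro accuracy check.

    The configured paint bias emulates the systematic offset of a
    tristimulus device reading a physical paint against the theoretical
    anchor (pure black misses upward, pure white downward).
    """
    rng = np.random.default_rng(seed + 5)
    anchors = {"black": 0.0, "white": 100.0}
    rows = []
    for bg in backgrounds:
        for paint, anchor in anchors.items():
            for _ in range(n_replicates):
                rows.append(
                    {
                        "paint": paint,
                        "background": bg,
                        "L": anchor
                        + model.paint_bias_L[paint]
                        + rng.normal(0.0, model.paint_noise_sd),
                        "a": rng.normal(0.3, 0.2),
                        "b": rng.normal(0.8, 0.3),
                    }
                )
    return pd.DataFrame(rows)
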