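"""CIEL*a*b* color data model for white cast measurement.

The pipeline works entirely in the CIE 1976 L*a*b* space: L* is the
black (0) to white (100) lightness axis, a* the red-green axis, b* the
yellow-blue axis.  Constitutive skin pigmentation is classified through
the Individual Typology Angle (ITA°), the angle of the (b*, L* - 50)
vector, which increases from dark to very light skin.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "Panel",
    "Background",
    "Timepoint",
    "Site",
    "ItaSubtype",
    "PigmentationCategory",
    "ColorReading",
    "SubjectProfile",
    "DEFAULT_ITA_BOUNDARIES",
    "compute_ita",
    "classify_ita",
    "categorize_pigmentation",
    "lab_to_hex",
    "hex_to_lab",
    "delta_e",
]


class Panel(str, enum.Enum):
    IN_VIVO = "in_vivo"
    IN_VITRO = "in_vitro"


class Background(str, enum.Enum):
    SKIN = "skin"
    BLACK_ACRYLIC = "black_acrylic"
    WHITE_ACRYLIC = "white_acrylic"


class Timepoint(str, enum.Enum):
    BEFORE = "before"
    AFTER = "after"


class Site(str, enum.Enum):
    TOP_LEFT = "top_left"
    MIDDLE = "middle"
    BOTTOM_RIGHT = "bottom_right"


class ItaSubtype(str, enum.Enum):
    VERY_LIGHT = "very_light"
    LIGHT = "light"
    INTERMEDIATE = "intermediate"
    TAN = "tan"
    BROWN = "brown"
    DARK = "dark"


class PigmentationCategory(str, enum.Enum):
    LIGHT = "light"
    MEDIUM = "medium"
    DARK = "dark"


#: ITA° lower bounds of each subtype, strictly decreasing.  An angle equal
#: to a bound belongs to the lighter subtype (half-open intervals, closed
#: at the bottom).  These are the conventional Chardon/Del Bino cut-offs:
#: very light > 55°, light 41-55°, intermediate 28-41°, tan 10-28°,
#: brown -30-10°, dark <= -30°.
DEFAULT_ITA_BOUNDARIES: tuple[tuple[float, ItaSubtype], ...] = (
    (55.0, ItaSubtype.VERY_LIGHT),
    (41.0, ItaSubtype.LIGHT),
    (28.0, ItaSubtype.INTERMEDIATE),
    (10.0, ItaSubtype.TAN),
    (-30.0, ItaSubtype.BROWN),
)

#: Grouping of ITA° subtypes into the three pigmentation categories used
#: throughout the analysis.  The dark *subtype* has no category: the study
#: design spans Very Light through Brown only.
_CATEGORY_OF_SUBTYPE: Mapping[ItaSubtype, PigmentationCategory] = {
    ItaSubtype.VERY_LIGHT: PigmentationCategory.LIGHT,
    ItaSubtype.LIGHT: PigmentationCategory.LIGHT,
    ItaSubtype.INTERMEDIATE: PigmentationCategory.MEDIUM,
    ItaSubtype.TAN: PigmentationCategory.MEDIUM,
    ItaSubtype.BROWN: PigmentationCategory.DARK,
}


class UndefinedAngleError(ValueError):
    """L* = 50 with b* = 0: the ITA° vector has no direction."""


class CategoryUndefinedError(ValueError):
    """The Dark ITA° subtype has no pigmentation category in this design."""


@dataclass(frozen=True)
class ColorReading:
    """One L*a*b* triple with its measurement context."""

    L_star: float
    a_star: float
    b_star: float
    panel: Panel
    substrate_id: str
    background: Background
    formulation_id: str
    timepoint: Timepoint
    site: Site
    day: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L_star}")
        in_vivo = self.panel == Panel.IN_VIVO
        on_skin = self.background == Background.SKIN
        if in_vivo != on_skin:
            raise ValueError(
                "background must be 'skin' exactly when the panel is in vivo"
            )

    @property
    def lab(self) -> tuple[float, float, float]:
        return (self.L_star, self.a_star, self.b_star)


@dataclass(frozen=True)
class SubjectProfile:
    """A volunteer's baseline color summary and ITA° classification."""

    subject_id: str
    baseline_L: float
    baseline_b: float
    ita_deg: float
    ita_subtype: ItaSubtype
    pigmentation_category: PigmentationCategory
    fitzpatrick: str | None = None


def compute_ita(L_star: float, b_star: float) -> float:
    """Individual Typology Angle in degrees.

    ITA° = arctan((L* - 50) / b*) * 180 / pi, the standard convention of
    Chardon et al. (Int J Cosmet Sci 1991).  Returns an angle in
    (-90, 90]; b* = 0 maps to +/-90 by the sign of L* - 50 and is
    undefined when L* = 50 as well.
    """
    if not 0.0 <= L_star <= 100.0:
        raise ValueError(f"L* must lie in [0, 100], got {L_star}")
    if not math.isfinite(b_star):
        raise ValueError("b* must be finite")
    dl = L_star - 50.0
    if b_star == 0.0:
        if dl == 0.0:
            raise UndefinedAngleError("ITA undefined at L*=50, b*=0")
        return 90.0 if dl > 0 else -90.0
    return math.degrees(math.atan(dl / b_star))


def _validate_boundaries(
    boundaries: Sequence[tuple[float, ItaSubtype]],
) -> list[tuple[float, ItaSubtype]]:
    bounds = list(boundaries)
    if not bounds:
        raise ValueError("empty boundary table")
    values = [b for b, _ in bounds]
    if any(v2 >= v1 for v1, v2 in zip(values, values[1:])):
        raise ValueError(f"boundaries must be strictly decreasing, got {values}")
    names = [s for _, s in bounds]
    if len(set(names)) != len(names):
        raise ValueError("duplicate subtype in boundary table")
    return bounds


def classify_ita(
    ita_deg: float,
    boundaries: Sequence[tuple[float, ItaSubtype]] = DEFAULT_ITA_BOUNDARIES,
) -> ItaSubtype:
    """Map an ITA° value to its subtype.

    ``boundaries`` lists (lower bound, subtype) pairs in strictly
    decreasing order of bound; an angle on a bound is assigned to the
    lighter side (the subtype whose interval it closes from below).
    Angles below every bound fall in the dark subtype.
    """
    bounds = _validate_boundaries(boundaries)
    for lower, subtype in bounds:
        if ita_deg >= lower:
            return subtype
    return ItaSubtype.DARK


def subtype_interval(
    subtype: ItaSubtype,
    boundaries: Sequence[tuple[float, ItaSubtype]] = DEFAULT_ITA_BOUNDARIES,
) -> tuple[float, float]:
    """Half-open ITA° interval [lo, hi) occupied by ``subtype``.

    The lightest subtype is unbounded above (hi = +90) and the dark
    subtype unbounded below (lo = -90).
    """
    bounds = _validate_boundaries(boundaries)
    hi = 90.0
    for lower, st in bounds:
        if st == subtype:
            return (lower, hi)
        hi = lower
    if subtype == ItaSubtype.DARK:
        return (-90.0, hi)
    raise ValueError(f"subtype {subtype} not in boundary table")


def categorize_pigmentation(subtype: ItaSubtype) -> PigmentationCategory:
    """Light / medium / dark pigmentation category of an ITA° subtype.

    Light comprises Very Light and Light, medium comprises Intermediate
    and Tan, dark is the Brown subtype alone.  The Dark subtype was not
    represented in the study panel and raises.
    """
    subtype = ItaSubtype(subtype)
    if subtype == ItaSubtype.DARK:
        raise CategoryUndefinedError(
            "the dark ITA subtype has no pigmentation category in this design"
        )
    return _CATEGORY_OF_SUBTYPE[subtype]


def lab_to_hex(
    L_star: float, a_star: float, b_star: float, *, illuminant: str = "D65",
    observer: str = "2",
) -> str:
    """Convert a CIELAB triple to an sRGB "#RRGGBB" hex code.

    Conversion goes CIELAB -> XYZ under the configured white point ->
    gamma-encoded sRGB; out-of-gamut channels are clamped to [0, 255],
    making the function total.
    """
    lab = np.asarray([[[float(L_star), float(a_star), float(b_star)]]])
    rgb = _skcolor.lab2rgb(lab, illuminant=illuminant, observer=observer)
    channels = np.clip(np.round(rgb[0, 0] * 255.0), 0, 255).astype(int)
    return "#{:02X}{:02X}{:02X}".format(*channels)


def hex_to_lab(
    hex_code: str, *, illuminant: str = "D65", observer: str = "2"
) -> tuple[float, float, float]:
    """Inverse of :func:`lab_to_hex` up to 8-bit quantization."""
    code = hex_code.lstrip("#")
    if len(code) != 6:
        raise ValueError(f"expected #RRGGBB, got {hex_code!r}")
    rgb = np.asarray(
        [[[int(code[i : i + 2], 16) / 255.0 for i in (0, 2, 4)]]]
    )
    lab = _skcolor.rgb2lab(rgb, illuminant=illuminant, observer=observer)
    return tuple(float(v) for v in lab[0, 0])


def delta_e(lab1: Sequence[float], lab2: Sequence[float]) -> float:
    """CIE76 color difference: Euclidean distance in L*a*b* space."""
    p = np.asarray(lab1, dtype=float)
    q = np.asarray(lab2, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise ValueError("delta_e expects two (L*, a*, b*) triples")
    return float(np.linalg.norm(p - q))
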