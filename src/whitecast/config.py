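"""YAML configuration for the pipeline.

A single config file bundles the tunable conventions: ITA° subtype
boundaries, score band edges per protocol, the study design and the
generator model.  ``default_config()`` returns the in-code defaults;
``load_config`` overlays a user file on top of them, so a file needs to
mention only the keys it changes.  The shipped
``data/default_config.yaml`` is a complete, commented dump of the
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .colorimetry import DEFAULT_ITA_BOUNDARIES, ItaSubtype
from .scoring import (
    DEFAULT_BAND_EDGES_IN_VITRO,
    DEFAULT_BAND_EDGES_IN_VIVO,
    BandEdges,
    FormulationSpec,
)
from .synthetic_data import DEFAULT_SEED, GeneratorModel, StudyDesign


@dataclass(frozen=True)
class Config:
    ita_boundaries: tuple[tuple[float, ItaSubtype], ...]
    band_edges_in_vivo: BandEdges
    band_edges_in_vitro: BandEdges
    design: StudyDesign
    model: GeneratorModel
    shapiro_alpha: float = 0.05
    seed: int = DEFAULT_SEED


def default_config() -> Config:
    return Config(
        ita_boundaries=DEFAULT_ITA_BOUNDARIES,
        band_edges_in_vivo=DEFAULT_BAND_EDGES_IN_VIVO,
        band_edges_in_vitro=DEFAULT_BAND_EDGES_IN_VITRO,
        design=StudyDesign(),
        model=GeneratorModel(),
    )


def _to_dict(cfg: Config) -> dict[str, Any]:
    return {
        "ita_boundaries": [
            {"lower": lower, "subtype": subtype.value}
            for lower, subtype in cfg.ita_boundaries
        ],
        "band_edges": {
            "in_vivo": list(cfg.band_edges_in_vivo.as_tuple()),
            "in_vitro": list(cfg.band_edges_in_vitro.as_tuple()),
        },
        "design": {
            "n_per_subtype": dict(cfg.design.n_per_subtype),
            "formulations": [
                {
                    "formulation_id": f.formulation_id,
                    "zno_pct": f.zno_pct,
                    "is_benchmark": f.is_benchmark,
                }
                for f in cfg.design.formulations
            ],
            "sites": list(cfg.design.sites),
            "vitro_days": cfg.design.vitro_days,
            "backgrounds": list(cfg.design.backgrounds),
        },
        "model": {
            f.name: _plain(getattr(cfg.model, f.name))
            for f in dataclasses.fields(cfg.model)
        },
        "shapiro_alpha": cfg.shapiro_alpha,
        "seed": cfg.seed,
    }


def _plain(value: Any) -> Any:
    if isinstance(value, Mapping):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, tuple):
        return list(value)
    return value


def dump_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def _from_dict(raw: Mapping[str, Any]) -> Config:
    base = default_config()
    ita = base.ita_boundaries
    if "ita_boundaries" in raw:
        ita = tuple(
            (float(e["lower"]), ItaSubtype(e["subtype"]))
            for e in raw["ita_boundaries"]
        )
    edges_vivo, edges_vitro = base.band_edges_in_vivo, base.band_edges_in_vitro
    if "band_edges" in raw:
        be = raw["band_edges"]
        if "in_vivo" in be:
            edges_vivo = BandEdges(*be["in_vivo"])
        if "in_vitro" in be:
            edges_vitro = BandEdges(*be["in_vitro"])
    design = base.design
    if "design" in raw:
        d = dict(raw["design"])
        if "formulations" in d:
            d["formulations"] = tuple(
                FormulationSpec(
                    f["formulation_id"],
                    float(f["zno_pct"]),
                    bool(f.get("is_benchmark", False)),
                )
                for f in d["formulations"]
            )
        for key in ("sites", "backgrounds"):
            if key in d:
                d[key] = tuple(d[key])
        design = dataclasses.replace(design, **d)
    model = base.model
    if "model" in raw:
        m = dict(raw["model"])
        for f in dataclasses.fields(GeneratorModel):
            if f.name in m and isinstance(getattr(model, f.name), tuple):
                m[f.name] = tuple(m[f.name])
        if "background_ab" in m:
            m["background_ab"] = {
                k: tuple(v) for k, v in m["background_ab"].items()
            }
        model = dataclasses.replace(model, **m)
    return Config(
        ita_boundaries=ita,
        band_edges_in_vivo=edges_vivo,
        band_edges_in_vitro=edges_vitro,
        design=design,
        model=model,
        shapiro_alpha=float(raw.get("shapiro_alpha", base.shapiro_alpha)),
        seed=int(raw.get("seed", base.seed)),
    )


def load_config(path: str | Path | None = None) -> Config:
    """Load a config file, overlaying it on the defaults.

    With ``path=None`` the packaged default file is used.
    """
    if path is None:
        text = (
            resources.files("whitecast") / "data" / "default_config.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return _from_dict(raw)
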