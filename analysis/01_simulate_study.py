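#!/usr/bin/env python
"""Generate the default synthetic white cast study.

Writes the in vivo and in vitro measurement tables, subject profiles,
expert/volunteer ranking panels and the questionnaire under
results/simulated/.  Every downstream driver consumes these tables.
"""

from pathlib import Path

from whitecast import io as wio
from whitecast.config import load_config
from whitecast.synthetic_data import (
    generate_in_vitro,
    generate_in_vivo,
    generate_paint_checks,
    generate_questionnaire,
    generate_rankings,
    generate_suitability_checks,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    cfg = load_config()
    OUT.mkdir(parents=True, exist_ok=True)

    vivo, profiles = generate_in_vivo(cfg.design, cfg.model, cfg.seed)
    vitro = generate_in_vitro(cfg.design, cfg.model, cfg.seed)
    wio.write_measurements(vivo, OUT / "in_vivo_measurements.tsv")
    wio.write_measurements(vitro, OUT / "in_vitro_measurements.tsv")
    profiles.to_csv(OUT / "subject_profiles.tsv", sep="\t", index=False)

    experts = generate_rankings(3, seed=cfg.seed, model=cfg.model)
    experts.to_long().to_csv(OUT / "expert_rankings.tsv", sep="\t", index=False)
    volunteers = generate_rankings(
        cfg.design.n_volunteers, seed=cfg.seed + 10, model=cfg.model,
        rater_prefix="volunteer",
    )
    volunteers.to_long().to_csv(
        OUT / "volunteer_rankings.tsv", sep="\t", index=False
    )

    questionnaire = generate_questionnaire(
        cfg.design.n_volunteers, cfg.model.questionnaire_probs, cfg.seed
    )
    questionnaire.to_csv(OUT / "questionnaire.tsv", sep="\t", index=False)

    generate_suitability_checks(cfg.model, cfg.seed).to_csv(
        OUT / "suitability_checks.tsv", sep="\t", index=False
    )
    generate_paint_checks(cfg.model, cfg.seed).to_csv(
        OUT / "paint_checks.tsv", sep="\t", index=False
    )

    print(f"seed {cfg.seed}: {cfg.design.n_volunteers} volunteers, "
          f"{len(vivo)} in vivo and {len(vitro)} in vitro readings")
    print(f"volunteer categories: "
          f"{profiles['category'].value_counts().to_dict()}")
    print(f"clipped L* values: {vivo.attrs['n_clipped']} in vivo, "
          f"{vitro.attrs['n_clipped']} in vitro")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
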