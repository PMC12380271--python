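#!/usr/bin/env python
"""Method validation battery on the simulated study.

Device suitability, per-stratum linearity and normality-gated
correlation, accuracy (in vivo against subtype references, in vitro
against the theoretical paint anchors), inter-/intra-day precision,
and the Fisher-Z equivalence of the in vivo vs in vitro correlations.
Writes the validation tables under results/ and prints the gate
summary.
"""

from pathlib import Path

import pandas as pd

from whitecast import io as wio
from whitecast.config import load_config
from whitecast.validation import (
    accuracy_in_vitro,
    accuracy_in_vivo,
    check_gates,
    device_suitability,
    fisher_z,
    fit_linearity,
    gated_correlation,
    precision_rsd,
    z_difference,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"

# References for the accuracy check: the generator's per-category
# baseline truth mapped onto subtypes (a real study supplies literature
# values here).
TRUTH_BASELINE = {"light": 63.66, "medium": 55.94, "dark": 46.28}
SUBTYPE_CATEGORY = {
    "very_light": "light", "light": "light",
    "intermediate": "medium", "tan": "medium", "brown": "dark",
}


def main() -> None:
    cfg = load_config()
    vivo = wio.read_measurements(SIM / "in_vivo_measurements.tsv")
    vitro = wio.read_measurements(SIM / "in_vitro_measurements.tsv")
    profiles = pd.read_csv(SIM / "subject_profiles.tsv", sep="\t")
    vivo = vivo.merge(
        profiles[["subject_id", "category", "subtype"]],
        left_on="substrate_id", right_on="subject_id",
    )

    # --- daily device suitability
    checks = pd.read_csv(SIM / "suitability_checks.tsv", sep="\t")
    report = device_suitability(checks)
    print(f"device suitability: {'PASS' if report.passed else 'FAIL'} "
          f"(limit {report.limit}% RSD; "
          f"indeterminate channels: {report.indeterminate or 'none'})")

    # --- linearity + gated correlation per stratum
    rows = []
    post_vivo = vivo[
        (vivo["timepoint"] == "after") & (vivo["formulation_id"] != "bm")
    ]
    strata = [("all_volunteers", post_vivo)] + [
        (cat, grp) for cat, grp in post_vivo.groupby("category")
    ]
    post_vitro = vitro[
        (vitro["timepoint"] == "after") & (vitro["formulation_id"] != "bm")
    ]
    strata += [(bg, grp) for bg, grp in post_vitro.groupby("background")]
    linearity = []
    correlations = {}
    for name, grp in strata:
        lin = fit_linearity(grp["zno_pct"], grp["L"])
        corr = gated_correlation(
            grp["zno_pct"], grp["L"], alpha=cfg.shapiro_alpha
        )
        if name != "all_volunteers":
            linearity.append(lin)
        correlations[name] = corr
        rows.append(
            {
                "stratum": name, "n": lin.n,
                "slope": lin.slope, "slope_sd": lin.slope_sd,
                "intercept": lin.intercept, "intercept_sd": lin.intercept_sd,
                "adjusted_r2": lin.adjusted_r2,
                "corr_method": corr.method.value,
                "corr": corr.coefficient, "corr_p": corr.p_value,
                "normality_p": corr.normality_p,
            }
        )
    lin_table = pd.DataFrame(rows)
    lin_table.to_csv(OUT / "validation_linearity.tsv", sep="\t", index=False)
    print("\nlinearity / correlation per stratum:")
    print(lin_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    # --- accuracy
    reference = {
        st: TRUTH_BASELINE[cat] for st, cat in SUBTYPE_CATEGORY.items()
    }
    acc = accuracy_in_vivo(profiles, reference)
    paints = pd.read_csv(SIM / "paint_checks.tsv", sep="\t")
    acc += accuracy_in_vitro(paints)
    acc_table = pd.DataFrame(
        [
            {"factor": e.factor, "accuracy_pct": e.accuracy_pct,
             "ci_low": e.ci_low, "ci_high": e.ci_high, "n": e.n,
             "convention": e.convention}
            for e in acc
        ]
    )
    acc_table.to_csv(OUT / "validation_accuracy.tsv", sep="\t", index=False)
    print("\naccuracy (mean [CI95%]):")
    print(acc_table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

    # --- precision
    precision = precision_rsd(vivo, "subtype", mode="inter_day")
    precision += precision_rsd(vivo, "category", mode="inter_day")
    precision += precision_rsd(vitro, "background", mode="inter_day")
    precision += precision_rsd(vitro, "background", mode="intra_day")
    prec_table = pd.DataFrame(
        [
            {"factor": e.factor, "timepoint": e.timepoint, "mode": e.mode,
             "rsd_min": e.rsd_min, "rsd_max": e.rsd_max,
             "n_groups": e.n_groups}
            for e in precision
        ]
    )
    prec_table.to_csv(OUT / "validation_precision.tsv", sep="\t", index=False)
    print(f"\nprecision: {len(prec_table)} factor/timepoint entries, "
          f"max RSD {prec_table['rsd_max'].max():.2f}%")

    # --- Fisher-Z equivalence of in vivo vs in vitro correlation strength
    rho_vitro = correlations["black_acrylic"]
    eq_rows = []
    for name in ("all_volunteers", "light", "medium", "dark"):
        c = correlations[name]
        z, sig = z_difference(
            c.coefficient, c.n, rho_vitro.coefficient, rho_vitro.n
        )
        eq_rows.append(
            {
                "comparison": f"{name}_vs_black_acrylic",
                "r_vivo": c.coefficient, "r_vitro": rho_vitro.coefficient,
                "fisher_z_vivo": fisher_z(c.coefficient),
                "fisher_z_vitro": fisher_z(rho_vitro.coefficient),
                "z_difference": z, "significant_at_1.96": sig,
            }
        )
    eq_table = pd.DataFrame(eq_rows)
    eq_table.to_csv(OUT / "validation_equivalence.tsv", sep="\t", index=False)
    print("\ncorrelation equivalence (Z differences, criterion 1.96):")
    print(eq_table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    # --- gates
    gates = check_gates(
        accuracy=acc, precision=precision, linearity=linearity
    )
    print(f"\nacceptance gates (accuracy 80-120%, RSD < 10%, "
          f"adjusted R2 > 0.650): {gates}")


if __name__ == "__main__":
    main()
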