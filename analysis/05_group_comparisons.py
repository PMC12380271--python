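#!/usr/bin/env python
"""Group-comparison statistics and questionnaire tabulation.

Kruskal-Wallis with Dunn's post hoc across formulations (per protocol
and per pigmentation category), Wilcoxon signed-rank before/after
shifts per formulation, and the count/percent questionnaire table.
"""

from pathlib import Path

import pandas as pd

from whitecast import io as wio
from whitecast.group_stats import (
    dunn_posthoc,
    kruskal_wallis,
    tabulate_questionnaire,
    wilcoxon_signed_rank,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"

FORM_ORDER = ["zno_0", "zno_5", "bm", "zno_10", "zno_20", "zno_30"]


def _groups(df):
    by = {fid: g["L"].to_numpy() for fid, g in df.groupby("formulation_id")}
    labels = [f for f in FORM_ORDER if f in by]
    return labels, [by[f] for f in labels]


def main() -> None:
    vivo = wio.read_measurements(SIM / "in_vivo_measurements.tsv")
    vitro = wio.read_measurements(SIM / "in_vitro_measurements.tsv")
    profiles = pd.read_csv(SIM / "subject_profiles.tsv", sep="\t")
    vivo = vivo.merge(
        profiles[["subject_id", "category"]],
        left_on="substrate_id", right_on="subject_id",
    )

    panels = [("all_volunteers", vivo[vivo["timepoint"] == "after"])]
    panels += [
        (f"category_{cat}", grp)
        for cat, grp in vivo[vivo["timepoint"] == "after"].groupby("category")
    ]
    panels.append(
        (
            "vitro_black",
            vitro[
                (vitro["timepoint"] == "after")
                & (vitro["background"] == "black_acrylic")
            ],
        )
    )

    dunn_rows = []
    for name, panel in panels:
        labels, groups = _groups(panel)
        kw = kruskal_wallis(groups, labels)
        print(f"\n{name}: Kruskal-Wallis H = {kw.statistic:.2f}, "
              f"p = {kw.p_value:.2e} ({kw.stars})")
        for res in dunn_posthoc(groups, labels):
            dunn_rows.append(
                {"panel": name, "group_1": res.groups[0],
                 "group_2": res.groups[1], "z": res.statistic,
                 "p_raw": res.p_value, "p_adjusted": res.adjusted_p,
                 "stars": res.stars}
            )
        notable = [
            r for r in dunn_rows
            if r["panel"] == name and r["stars"] != "ns"
            and "zno_30" in (r["group_1"], r["group_2"])
        ]
        print(f"  significant 30% contrasts after Bonferroni: "
              f"{len(notable)} of 5")
    pd.DataFrame(dunn_rows).to_csv(
        OUT / "dunn_comparisons.tsv", sep="\t", index=False
    )

    # before/after whiteness shift per formulation (paired per site)
    shift_rows = []
    for fid, grp in vivo.groupby("formulation_id"):
        wide = grp.pivot_table(
            index=["substrate_id", "site"], columns="timepoint", values="L"
        ).dropna()
        res = wilcoxon_signed_rank(wide["before"], wide["after"])
        shift_rows.append(
            {"formulation_id": fid, "n_pairs": len(wide),
             "statistic": res.statistic, "p": res.p_value,
             "stars": res.stars, "degenerate": res.degenerate}
        )
    shifts = pd.DataFrame(shift_rows).set_index("formulation_id").loc[
        FORM_ORDER
    ]
    shifts.to_csv(OUT / "wilcoxon_shifts.tsv", sep="\t")
    print("\nbefore/after L* shift (Wilcoxon signed-rank, n = 39 site pairs):")
    print(shifts.to_string(float_format=lambda v: f"{v:.3g}"))

    # questionnaire
    questionnaire = wio.read_questionnaire(SIM / "questionnaire.tsv")
    table = tabulate_questionnaire(questionnaire)
    table.to_csv(OUT / "questionnaire_summary.tsv", sep="\t", index=False)
    concern = table[table["item_id"] == "concern"]
    agree_pct = concern[
        concern["response"].isin(["strongly_agree", "agree"])
    ]["pct"].sum()
    print(f"\nquestionnaire: {agree_pct:.1f}% of volunteers are concerned "
          f"about white cast")


if __name__ == "__main__":
    main()
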