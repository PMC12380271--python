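"""Reading and writing the delimited measurement tables.

One row per color reading.  Columns:

panel, substrate_id, background, formulation_id, zno_pct, timepoint,
site, day, L, a, b

Baseline readings carry the formulation of the square they were taken in
with ``timepoint = before``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MEASUREMENT_COLUMNS = [
    "panel",
    "substrate_id",
    "background",
    "formulation_id",
    "zno_pct",
    "timepoint",
    "site",
    "day",
    "L",
    "a",
    "b",
]

RANKING_COLUMNS = ["rater_id", "item_id", "value"]
QUESTIONNAIRE_COLUMNS = ["volunteer_id", "item_id", "response"]


def read_measurements(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    bad = df[(df["L"] < 0) | (df["L"] > 100)]
    if len(bad):
        raise ValueError(f"{len(bad)} rows with L* outside [0, 100]")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.loc[:, MEASUREMENT_COLUMNS].to_csv(path, sep=sep, index=False)


def read_rankings(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in RANKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ranking table missing columns: {missing}")
    return df


def read_questionnaire(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"questionnaire table missing columns: {missing}")
    return df
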