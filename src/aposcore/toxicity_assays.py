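"""Daphnia mortality scoring.

Toxicity of a butterfly species is proxied by the fraction of Daphnia
magna killed within 4 h by its methanolic body extract; each assay exposes
10 animals.  Solvent controls (water, methanol) and extracts of reference
insects (cricket, cockroach) establish the baseline mortality attributable
to the extraction protocol itself.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "CONTROL_CATEGORIES",
    "read_assay_table",
    "species_mortality",
    "control_summary",
    "flag_toxic",
]

CONTROL_CATEGORIES = ("water", "methanol", "cricket", "cockroach")
CATEGORIES = ("butterfly",) + CONTROL_CATEGORIES

ASSAY_COLUMNS = ["subject_id", "category", "n_daphnia", "deaths"]


def read_assay_table(path: str) -> pd.DataFrame:
    """Read a delimited assay table (subject_id, category, n_daphnia, deaths)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    bad_cat = set(df["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown assay categories: {sorted(bad_cat)}")
    df = df.astype({"n_daphnia": int, "deaths": int})
    if (df["n_daphnia"] < 1).any():
        raise ValueError("n_daphnia must be >= 1")
    if ((df["deaths"] < 0) | (df["deaths"] > df["n_daphnia"])).any():
        raise ValueError("deaths must lie in [0, n_daphnia]")
    return df[ASSAY_COLUMNS].copy()


def species_mortality(assays: pd.DataFrame, min_assays: int = 3) -> pd.DataFrame:
    """Per-species mean mortality over butterfly assays.

    Mortality of an assay is deaths/n_daphnia; the species score is the
    unweighted mean over its assays.  Species below ``min_assays`` assays
    are kept but trigger a warning (the study's design aimed for at least
    three individuals per species).  Species without assays are absent.
    """
    b = assays[assays["category"] == "butterfly"].copy()
    b["mortality"] = b["deaths"] / b["n_daphnia"]
    out = (
        b.groupby("subject_id")["mortality"]
        .agg(n_assays="size", mean_mortality="mean")
        .reset_index()
        .rename(columns={"subject_id": "species_id"})
        .sort_values("species_id", ignore_index=True)
    )
    out["n_assays"] = out["n_assays"].astype(int)
    low = out[out["n_assays"] < min_assays]
    if len(low):
        warnings.warn(
            f"{len(low)} species have fewer than {min_assays} assays: "
            f"{low['species_id'].tolist()}",
            stacklevel=2,
        )
    return out


def control_summary(assays: pd.DataFrame) -> pd.DataFrame:
    """Mean/median mortality and single-assay maximum deaths per control.

    Butterfly assays are excluded; control categories with no assays are
    simply absent from the result.
    """
    c = assays[assays["category"].isin(CONTROL_CATEGORIES)].copy()
    if len(c) == 0:
        return pd.DataFrame(
            columns=["category", "n_assays", "mean_mortality",
                     "median_mortality", "max_deaths"]
        )
    c["mortality"] = c["deaths"] / c["n_daphnia"]
    out = (
        c.groupby("category")
        .agg(
            n_assays=("mortality", "size"),
            mean_mortality=("mortality", "mean"),
            median_mortality=("mortality", "median"),
            max_deaths=("deaths", "max"),
        )
        .reset_index()
        .sort_values("category", ignore_index=True)
    )
    out["n_assays"] = out["n_assays"].astype(int)
    out["max_deaths"] = out["max_deaths"].astype(int)
    return out


def flag_toxic(species_toxicity: pd.DataFrame, threshold: float = 0.20) -> pd.DataFrame:
    """Flag species whose mean mortality strictly exceeds ``threshold``.

    The 20% default mirrors the reporting rule that a species counts as
    toxic when its mean mortality is higher than any single control assay
    (> 20%); the inequality is strict, so exactly 20% is not flagged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = species_toxicity.copy()
    out["flagged"] = out["mean_mortality"] > threshold
    return out
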