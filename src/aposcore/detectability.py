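"""Detectability statistics from cleaned detection-game logs.

Detection time of a butterfly image by human searchers is the study's
proxy for (inverse) conspicuousness.  For each image the mean detection
time is computed against every background; the background with the longest
mean time is that image's *most cryptic background* and its mean time is
the image's detectability score.  Cryptic species are expected to be hard
to find on at least one background, whereas aposematic species should be
quickly found on most.

A second statistic compares wing surfaces: per background, the difference
between the ventral and dorsal mean detection times of a morphotype.  Two
aggregations of that per-background difference are offered (see
``dorsal_ventral_diff``), because "the absolute mean of the time
difference" admits both |mean(d)| and mean(|d|) readings; the default is
the literal ``abs_of_mean``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mean_times",
    "most_cryptic",
    "cryptic_scores",
    "dorsal_ventral_diff",
    "diff_scores",
    "impute_missing",
    "zscore",
    "species_predictors",
]

DIFF_MODES = ("abs_of_mean", "mean_of_abs")


def mean_times(records: pd.DataFrame) -> pd.DataFrame:
    """Mean detection time and round count per (image, background).

    ``records`` must already be censored (timeouts at exactly the timeout
    value).  Combinations never shown are absent from the result rather
    than zero-filled.
    """
    if len(records) == 0:
        return pd.DataFrame(
            columns=["image_id", "background_id", "mean_time", "n_rounds"]
        )
    g = records.groupby(["image_id", "background_id"], sort=True)["time_s"]
    out = g.agg(mean_time="mean", n_rounds="size").reset_index()
    out["n_rounds"] = out["n_rounds"].astype(int)
    return out


def most_cryptic(table: pd.DataFrame, image_id: str) -> tuple[str, float]:
    """Background with the maximal mean detection time for one image.

    Ties are broken by the lexicographically smallest background id so the
    result is deterministic.
    """
    sub = table[table["image_id"] == image_id]
    if len(sub) == 0:
        raise KeyError(f"image not present in detection table: {image_id!r}")
    sub = sub.sort_values(
        ["mean_time", "background_id"], ascending=[False, True]
    )
    row = sub.iloc[0]
    return str(row["background_id"]), float(row["mean_time"])


def cryptic_scores(table: pd.DataFrame) -> pd.DataFrame:
    """``most_cryptic`` applied to every image in the table."""
    rows = [
        (img, *most_cryptic(table, img))
        for img in sorted(table["image_id"].unique())
    ]
    return pd.DataFrame(
        rows, columns=["image_id", "most_cryptic_background", "cryptic_time"]
    )


def _side_means(table: pd.DataFrame, image_id: str) -> pd.Series:
    sub = table[table["image_id"] == image_id]
    return sub.set_index("background_id")["mean_time"]


def dorsal_ventral_diff(
    table: pd.DataFrame,
    images: pd.DataFrame,
    morphotype_id: str,
    mode: str = "abs_of_mean",
) -> float:
    """Dorsal-ventral detectability difference statistic for one morphotype.

    Per background *b* shown for both sides, ``d_b = mean_ventral(b) -
    mean_dorsal(b)``.  ``mode='abs_of_mean'`` returns ``|mean_b(d_b)|``;
    ``mode='mean_of_abs'`` returns ``mean_b(|d_b|)``.

    ``images`` maps image_id -> (species_id, morphotype_id, side); the
    ventral image is shared by the morphotypes of a dimorphic species.
    """
    if mode not in DIFF_MODES:
        raise ValueError(f"mode must be one of {DIFF_MODES}, got {mode!r}")
    sub = images[images["morphotype_id"] == morphotype_id]
    if len(sub) == 0:
        raise KeyError(f"unknown morphotype: {morphotype_id!r}")
    dorsal = sub[sub["side"] == "dorsal"]
    species = sub["species_id"].iloc[0]
    ventral = images[
        (images["species_id"] == species) & (images["side"] == "ventral")
    ]
    if len(dorsal) == 0 or len(ventral) == 0:
        missing = "dorsal" if len(dorsal) == 0 else "ventral"
        raise ValueError(
            f"morphotype {morphotype_id!r} has no {missing} image; "
            "impute at the species level instead"
        )
    d_means = _side_means(table, dorsal["image_id"].iloc[0])
    v_means = _side_means(table, ventral["image_id"].iloc[0])
    common = d_means.index.intersection(v_means.index)
    if len(common) == 0:
        raise ValueError(
            f"no background observed for both sides of {morphotype_id!r}"
        )
    d = (v_means[common] - d_means[common]).to_numpy(float)
    if mode == "abs_of_mean":
        return float(abs(d.mean()))
    return float(np.abs(d).mean())


def diff_scores(
    table: pd.DataFrame, images: pd.DataFrame, mode: str = "abs_of_mean"
) -> pd.DataFrame:
    """Difference statistic for every morphotype that has both sides.

    Morphotypes missing a side get NaN (to be imputed downstream).
    """
    rows = []
    for morph in sorted(images["morphotype_id"].unique()):
        try:
            val = dorsal_ventral_diff(table, images, morph, mode)
        except ValueError:
            val = np.nan
        species = images.loc[
            images["morphotype_id"] == morph, "species_id"
        ].iloc[0]
        rows.append((morph, species, val))
    return pd.DataFrame(rows, columns=["morphotype_id", "species_id", "diff_stat"])


def impute_missing(values: pd.Series, missing_ids=None) -> pd.Series:
    """Replace missing entries by the mean of the observed entries.

    ``missing_ids`` marks entries to treat as missing in addition to NaNs.
    After z-scoring, imputed entries sit at (approximately) zero, so the
    species concerned do not pull on the slope estimates.
    """
    out = values.astype(float).copy()
    if missing_ids is not None:
        out.loc[[i for i in missing_ids if i in out.index]] = np.nan
    observed = out.dropna()
    if len(observed) == 0:
        raise ValueError("cannot impute: all values are missing")
    return out.fillna(observed.mean())


def zscore(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Standardise to mean 0 and sample (n-1) standard deviation 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise ValueError("z-scoring needs at least two distinct values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("z-scoring undefined for zero-variance input")
    z = (arr - arr.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(z, index=values.index, name=values.name)
    return z


def species_predictors(
    table: pd.DataFrame,
    images: pd.DataFrame,
    diff_mode: str = "abs_of_mean",
    morph_agg: str = "mean",
) -> pd.DataFrame:
    """Model-ready per-species predictor table.

    Columns: raw ``dorsal_time``/``ventral_time`` (most-cryptic-background
    detection times, seconds; NaN where the species has no dorsal image)
    and ``diff_stat``; plus imputed, z-scored ``z_dorsal``, ``z_ventral``,
    ``z_diff``.  Dimorphic species contribute one row: morphotype scores
    are aggregated by ``morph_agg`` (default mean over morphotypes).
    """
    if morph_agg != "mean":
        raise ValueError("only morph_agg='mean' is supported")
    cs = cryptic_scores(table).merge(images, on="image_id")
    per_species = (
        cs.pivot_table(
            index="species_id", columns="side", values="cryptic_time",
            aggfunc="mean",
        )
        .rename(columns={"dorsal": "dorsal_time", "ventral": "ventral_time"})
    )
    for col in ("dorsal_time", "ventral_time"):
        if col not in per_species:
            per_species[col] = np.nan
    ds = diff_scores(table, images, diff_mode)
    per_species["diff_stat"] = ds.groupby("species_id")["diff_stat"].mean()

    out = per_species.sort_index()
    out["z_dorsal"] = zscore(impute_missing(out["dorsal_time"]))
    out["z_ventral"] = zscore(impute_missing(out["ventral_time"]))
    out["z_diff"] = zscore(impute_missing(out["diff_stat"]))
    return out
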