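"""Ingest, validate and quality-filter detection-game round logs.

One row of a round log records a single game round: which player, which
butterfly image against which background, whether the butterfly was found,
and the time to the first correct click.  Rounds where the butterfly was
not found within the time limit are right-censored: they enter every
statistic at exactly the timeout (10 s by default).

Players who found fewer than three butterflies in total are assumed not
to have understood the instructions and all of their rounds are dropped.
A small mixed model of detection time on the within-player replay number
quantifies how much players improve by replaying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LOG_COLUMNS",
    "QCReport",
    "LearningEstimate",
    "read_round_log",
    "apply_censoring",
    "filter_players",
    "estimate_replay_learning",
]

LOG_COLUMNS = [
    "user_id",
    "game_id",
    "round_index",
    "image_id",
    "species_id",
    "side",
    "background_id",
    "outcome",
    "time_s",
]

SIDES = ("dorsal", "ventral")
OUTCOMES = ("found", "timeout")


@dataclass
class QCReport:
    """Bookkeeping of how many users/rounds survived each cleaning step."""

    n_users_in: int = 0
    n_users_excluded: int = 0
    n_rounds_in: int = 0
    n_rounds_kept: int = 0
    mean_found_per_game: float = float("nan")
    row_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_rounds_kept > self.n_rounds_in:
            raise ValueError("n_rounds_kept cannot exceed n_rounds_in")


def read_round_log(
    path: str,
    timeout_s: float = 10.0,
    max_round_index: int = 30,
) -> tuple[pd.DataFrame, QCReport]:
    """Read a delimited round log, rejecting malformed rows with a reason.

    Rows with a non-numeric, non-positive or super-timeout time, an
    unknown side/outcome, a bad round index, or missing fields are dropped
    and the reason recorded in ``QCReport.row_errors``; they are never
    silently clamped.  A missing column is a schema error and raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"round log missing columns: {missing}")
    df = df[LOG_COLUMNS].copy()

    qc = QCReport(n_rounds_in=len(df))
    bad = pd.Series(False, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        for i in df.index[mask & ~bad]:
            qc.row_errors.append(f"row {i}: {reason}")
        bad |= mask

    reject(df.isna().any(axis=1), "missing field")
    time = pd.to_numeric(df["time_s"], errors="coerce")
    reject(time.isna() & df["time_s"].notna(), "non-numeric time_s")
    reject(time <= 0, "non-positive time_s")
    reject(time > timeout_s, f"time_s exceeds timeout {timeout_s}")
    ridx = pd.to_numeric(df["round_index"], errors="coerce")
    reject(ridx.isna() | (ridx != ridx.round()), "non-integer round_index")
    reject((ridx < 1) | (ridx > max_round_index), "round_index out of range")
    reject(~df["side"].isin(SIDES) & df["side"].notna(), "unknown side")
    reject(~df["outcome"].isin(OUTCOMES) & df["outcome"].notna(), "unknown outcome")

    out = df[~bad].copy()
    out["time_s"] = time[~bad].astype(float)
    out["round_index"] = ridx[~bad].astype(int)
    out = out.reset_index(drop=True)
    qc.n_rounds_kept = len(out)
    qc.n_users_in = out["user_id"].nunique()
    return out, qc


def apply_censoring(records: pd.DataFrame, timeout_s: float = 10.0) -> pd.DataFrame:
    """Set every timeout round's time to exactly the timeout.

    Found rounds are untouched; detection failures enter all downstream
    statistics as right-censored observations at ``timeout_s``.
    """
    out = records.copy()
    out.loc[out["outcome"] == "timeout", "time_s"] = float(timeout_s)
    return out


def filter_players(
    records: pd.DataFrame, min_found: int = 3
) -> tuple[pd.DataFrame, QCReport]:
    """Drop all rounds of users who found fewer than ``min_found`` butterflies.

    The found-count is per user, totalled across all of their games.  A
    user with exactly ``min_found`` finds is kept ("fewer than" is
    strict).  Idempotent: filtering a filtered log changes nothing.
    """
    if min_found < 0:
        raise ValueError("min_found must be >= 0")
    found = (
        (records["outcome"] == "found")
        .groupby(records["user_id"])
        .sum()
    )
    keep_users = found[found >= min_found].index
    out = records[records["user_id"].isin(keep_users)].reset_index(drop=True)

    if len(out):
        found_per_game = (
            (out["outcome"] == "found").groupby(out["game_id"]).sum()
        )
        mean_found = float(found_per_game.mean())
    else:
        mean_found = float("nan")
    qc = QCReport(
        n_users_in=int(records["user_id"].nunique()),
        n_users_excluded=int(records["user_id"].nunique() - len(keep_users)),
        n_rounds_in=len(records),
        n_rounds_kept=len(out),
        mean_found_per_game=mean_found,
    )
    return out, qc


@dataclass
class LearningEstimate:
    """Replay-learning effect: seconds per additional game played."""

    slope: float
    marginal_r2: float
    n_users: int
    n_games: int


def _game_number(records: pd.DataFrame) -> pd.Series:
    """Within-user replay number (1, 2, ...) by order of first appearance."""
    first_seen = ~records.duplicated(["user_id", "game_id"])
    order = first_seen.groupby(records["user_id"]).cumsum()
    # propagate the game's number to all of its rounds
    key = pd.MultiIndex.from_frame(records[["user_id", "game_id"]])
    game_no = pd.Series(order[first_seen].to_numpy(),
                        index=key[first_seen.to_numpy()])
    return pd.Series(game_no.loc[key].to_numpy(), index=records.index,
                     name="game_number").astype(int)


def estimate_replay_learning(records: pd.DataFrame) -> LearningEstimate:
    """Random-intercept model of detection time on replay number.

    Restricted to users who played at least twice, fits (by REML)
    ``time_s ~ game_number + (1 | user_id)`` and returns the fixed slope
    together with its marginal (fixed-effect) R-squared, i.e. the share of
    fixed-effect variance in fixed + user-intercept + residual variance.
    """
    import statsmodels.formula.api as smf

    gn = _game_number(records)
    df = records[["user_id", "time_s"]].copy()
    df["game_number"] = gn
    games_per_user = df.groupby("user_id")["game_number"].max()
    repeat_users = games_per_user[games_per_user >= 2].index
    df = df[df["user_id"].isin(repeat_users)]
    if df.empty or df["user_id"].nunique() < 1:
        raise ValueError(
            "replay-learning model needs at least one user with >= 2 games"
        )
    fit = smf.mixedlm(
        "time_s ~ game_number", df, groups=df["user_id"], missing="raise"
    ).fit(reml=True)
    slope = float(fit.params["game_number"])
    var_fixed = float(np.var(slope * df["game_number"].to_numpy(float), ddof=0))
    var_user = float(fit.cov_re.iloc[0, 0])
    var_resid = float(fit.scale)
    marginal = var_fixed / (var_fixed + var_user + var_resid)
    return LearningEstimate(
        slope=slope,
        marginal_r2=marginal,
        n_users=int(df["user_id"].nunique()),
        n_games=int(df.groupby("user_id")["game_number"].max().sum()),
    )
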