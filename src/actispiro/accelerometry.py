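"""Epoch-level accelerometry processing.

Turns 5-second-epoch wrist-acceleration series plus a sleep log into
per-participant activity summaries: restriction to waking periods of the
full recorded days, day-level wear-validity screening, nonwear imputation,
intensity classification (sedentary / light / MVPA) and weekday/weekend-
weighted daily minutes.

Conventions
-----------
Epoch tables carry columns ``participant_id, day_index, epoch_start_s,
acc_g, worn`` with ``epoch_start_s`` in seconds since midnight on a fixed
epoch grid shared across days.  The sleep log carries ``participant_id,
day_index, weekday, wake_onset_s, sleep_onset_s`` with ``weekday`` coded
0=Monday .. 6=Sunday.  The waking window is half-open:
``wake_onset_s <= t < sleep_onset_s``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: intensity cut-points in g units; the MVPA bound is inclusive
LIGHT_CUT = 0.03
MVPA_CUT = 0.10
#: minimum fraction of waking time worn for a day to be valid
MIN_WEAR_FRACTION = 2.0 / 3.0

LEVELS = ("sedentary", "light", "mvpa")

EPOCH_COLUMNS = ["participant_id", "day_index", "epoch_start_s", "acc_g", "worn"]
SLEEP_COLUMNS = [
    "participant_id",
    "day_index",
    "weekday",
    "wake_onset_s",
    "sleep_onset_s",
]


def infer_epoch_seconds(epochs: pd.DataFrame) -> float:
    """Epoch spacing in seconds, read off the first participant-day."""
    pid = epochs["participant_id"].iloc[0]
    day = epochs["day_index"].iloc[0]
    t = epochs.loc[
        (epochs["participant_id"] == pid) & (epochs["day_index"] == day),
        "epoch_start_s",
    ].to_numpy()
    if t.size < 2:
        raise ValueError("cannot infer epoch spacing from a single epoch")
    return float(np.median(np.diff(np.sort(t))))


def classify_epochs(
    acc: np.ndarray,
    light_cut: float = LIGHT_CUT,
    mvpa_cut: float = MVPA_CUT,
) -> np.ndarray:
    """Classify epoch accelerations into intensity levels.

    Parameters
    ----------
    acc : array of acceleration magnitudes in g units, all >= 0.
    light_cut, mvpa_cut : lower bounds (inclusive) for light activity and
        MVPA respectively.

    Returns
    -------
    integer array: 0 = sedentary (acc < light_cut), 1 = light
    (light_cut <= acc < mvpa_cut), 2 = MVPA (acc >= mvpa_cut).
    """
    acc = np.asarray(acc, dtype=float)
    if np.any(acc < 0):
        raise ValueError("negative acceleration magnitude encountered")
    if not 0 < light_cut < mvpa_cut:
        raise ValueError("require 0 < light_cut < mvpa_cut")
    return (acc >= light_cut).astype(np.int8) + (acc >= mvpa_cut).astype(np.int8)


def extract_waking_epochs(
    epochs: pd.DataFrame,
    sleep_log: pd.DataFrame,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Restrict epochs to waking periods of the fully recorded days.

    Day 1 (device fitting) and the final recorded day are dropped, so a
    9-day recording yields 7 retained days.  Within each retained day only
    epochs with ``wake_onset_s <= epoch_start_s < sleep_onset_s`` are kept.
    Days without a sleep-log row are dropped entirely (they are flagged
    invalid downstream by :func:`validate_days`, never silently kept).
    """
    if n_days is None:
        n_days = int(epochs["day_index"].max())
    keep = (epochs["day_index"] >= 2) & (epochs["day_index"] <= n_days - 1)
    core = epochs.loc[keep]
    merged = core.merge(
        sleep_log[SLEEP_COLUMNS],
        on=["participant_id", "day_index"],
        how="inner",
    )
    in_window = (merged["epoch_start_s"] >= merged["wake_onset_s"]) & (
        merged["epoch_start_s"] < merged["sleep_onset_s"]
    )
    return merged.loc[in_window].reset_index(drop=True)


def validate_days(
    waking_epochs: pd.DataFrame,
    sleep_log: pd.DataFrame,
    n_days: int | None = None,
    min_wear_fraction: float = MIN_WEAR_FRACTION,
) -> pd.DataFrame:
    """Day-level validity: wear fraction of the waking window >= 2/3.

    Wear fractions are computed on the raw ``worn`` flags, before any
    imputation.  Days listed in the sleep log for the retained range but
    absent from ``waking_epochs`` (e.g. missing sleep-log rows removed the
    epochs, or no epochs at all) appear with ``valid=False``.

    Returns a frame with columns ``participant_id, day_index, is_weekend,
    waking_minutes, wear_fraction_waking, valid``.
    """
    if n_days is None:
        n_days = int(sleep_log["day_index"].max())
    retained = sleep_log.loc[
        (sleep_log["day_index"] >= 2) & (sleep_log["day_index"] <= n_days - 1),
        SLEEP_COLUMNS,
    ].copy()
    per_day = (
        waking_epochs.groupby(["participant_id", "day_index"])
        .agg(n_epochs=("worn", "size"), n_worn=("worn", "sum"))
        .reset_index()
    )
    out = retained.merge(per_day, on=["participant_id", "day_index"], how="left")
    out["n_epochs"] = out["n_epochs"].fillna(0).astype(int)
    out["n_worn"] = out["n_worn"].fillna(0).astype(int)
    out["is_weekend"] = out["weekday"] >= 5
    out["waking_minutes"] = (out["sleep_onset_s"] - out["wake_onset_s"]) / 60.0
    with np.errstate(invalid="ignore"):
        out["wear_fraction_waking"] = np.where(
            out["n_epochs"] > 0, out["n_worn"] / out["n_epochs"], 0.0
        )
    out["valid"] = out["wear_fraction_waking"] >= min_wear_fraction
    return out[
        [
            "participant_id",
            "day_index",
            "is_weekend",
            "waking_minutes",
            "wear_fraction_waking",
            "valid",
        ]
    ]


def select_participants(
    validities: pd.DataFrame,
    min_weekdays: int = 2,
    min_weekend_days: int = 2,
) -> pd.DataFrame:
    """Participant inclusion: >=2 valid weekdays and >=2 valid weekend days.

    Returns ``participant_id, n_valid_weekdays, n_valid_weekend_days,
    included, reason`` (reason empty when included).
    """
    grp = validities.groupby("participant_id")
    n_wd = grp.apply(
        lambda d: int((d["valid"] & ~d["is_weekend"]).sum()), include_groups=False
    )
    n_we = grp.apply(
        lambda d: int((d["valid"] & d["is_weekend"]).sum()), include_groups=False
    )
    out = pd.DataFrame(
        {
            "participant_id": n_wd.index,
            "n_valid_weekdays": n_wd.to_numpy(),
            "n_valid_weekend_days": n_we.to_numpy(),
        }
    )
    out["included"] = (out["n_valid_weekdays"] >= min_weekdays) & (
        out["n_valid_weekend_days"] >= min_weekend_days
    )
    reasons = np.where(
        out["included"],
        "",
        np.where(
            out["n_valid_weekdays"] < min_weekdays,
            "fewer than %d valid weekdays" % min_weekdays,
            "fewer than %d valid weekend days" % min_weekend_days,
        ),
    )
    out["reason"] = reasons
    return out


def correct_nonwear(
    waking_epochs: pd.DataFrame, validities: pd.DataFrame
) -> pd.DataFrame:
    """Impute nonworn waking epochs on valid days.

    Each nonworn epoch's acceleration is replaced by the mean acceleration
    at the same clock slot (``epoch_start_s``) over the participant's other
    valid days where the device was worn.  Clock slots never worn on any
    day fall back to the participant's overall worn-waking mean.  Only
    valid days are retained and imputed.  Adds a boolean ``imputed``
    column.
    """
    valid_days = validities.loc[validities["valid"], ["participant_id", "day_index"]]
    df = waking_epochs.merge(
        valid_days, on=["participant_id", "day_index"], how="inner"
    ).copy()
    if df.empty:
        df["imputed"] = pd.Series(dtype=bool)
        return df

    worn = df.loc[df["worn"]]
    slot_mean = worn.groupby(["participant_id", "epoch_start_s"])["acc_g"].mean()
    overall_mean = worn.groupby("participant_id")["acc_g"].mean()

    df["imputed"] = ~df["worn"]
    gap_idx = pd.MultiIndex.from_frame(
        df.loc[df["imputed"], ["participant_id", "epoch_start_s"]]
    )
    fill = slot_mean.reindex(gap_idx).to_numpy()
    missing_slot = np.isnan(fill)
    if missing_slot.any():
        pid = df.loc[df["imputed"], "participant_id"].to_numpy()[missing_slot]
        fill[missing_slot] = overall_mean.reindex(pid).to_numpy()
    df.loc[df["imputed"], "acc_g"] = fill
    return df


def _weighted_daily_mean(per_day: pd.DataFrame, value_col: str) -> float:
    """Mean/day of ``value_col``: plain mean over 7 valid days, else the
    5:2 weekday/weekend reweighting (5*wd_mean + 2*we_mean)/7."""
    if len(per_day) == 7:
        return float(per_day[value_col].mean())
    wd = per_day.loc[~per_day["is_weekend"], value_col]
    we = per_day.loc[per_day["is_weekend"], value_col]
    if wd.empty or we.empty:
        raise ValueError(
            "participant lacks valid weekdays or weekend days; "
            "should have been excluded by select_participants"
        )
    return float((5.0 * wd.mean() + 2.0 * we.mean()) / 7.0)


def summarize_activity(
    corrected_epochs: pd.DataFrame,
    validities: pd.DataFrame,
    epoch_seconds: float | None = None,
    light_cut: float = LIGHT_CUT,
    mvpa_cut: float = MVPA_CUT,
) -> pd.DataFrame:
    """Per-participant daily minutes in each intensity level and waking time.

    Per-day minutes in a level = (#epochs at that level) * epoch_seconds/60.
    Daily values are plain means over the 7 valid days when all 7 are valid,
    otherwise weighted 5:2 (weekday:weekend) to represent a full week.  The
    same weighting yields the waking duration T_i.

    Returns ``participant_id, sedentary_min, light_min, mvpa_min,
    waking_min, n_valid_weekdays, n_valid_weekend_days``.
    """
    if epoch_seconds is None:
        epoch_seconds = infer_epoch_seconds(corrected_epochs)
    df = corrected_epochs.copy()
    df["level"] = classify_epochs(df["acc_g"].to_numpy(), light_cut, mvpa_cut)
    counts = (
        df.groupby(["participant_id", "day_index", "level"])
        .size()
        .unstack("level", fill_value=0)
        .reindex(columns=[0, 1, 2], fill_value=0)
        .reset_index()
    )
    counts.columns = ["participant_id", "day_index", "n_sed", "n_light", "n_mvpa"]
    for lev, col in zip(LEVELS, ["n_sed", "n_light", "n_mvpa"]):
        counts[f"{lev}_min"] = counts[col] * (epoch_seconds / 60.0)
    counts["waking_obs_min"] = (
        counts["sedentary_min"] + counts["light_min"] + counts["mvpa_min"]
    )
    valid = validities.loc[
        validities["valid"], ["participant_id", "day_index", "is_weekend"]
    ]
    per_day = counts.merge(valid, on=["participant_id", "day_index"], how="inner")

    rows = []
    for pid, d in per_day.groupby("participant_id"):
        rows.append(
            {
                "participant_id": pid,
                "sedentary_min": _weighted_daily_mean(d, "sedentary_min"),
                "light_min": _weighted_daily_mean(d, "light_min"),
                "mvpa_min": _weighted_daily_mean(d, "mvpa_min"),
                "waking_min": _weighted_daily_mean(d, "waking_obs_min"),
                "n_valid_weekdays": int((~d["is_weekend"]).sum()),
                "n_valid_weekend_days": int(d["is_weekend"].sum()),
            }
        )
    return pd.DataFrame(rows)


def process_participants(
    epochs: pd.DataFrame,
    sleep_log: pd.DataFrame,
    n_days: int | None = None,
    epoch_seconds: float | None = None,
    light_cut: float = LIGHT_CUT,
    mvpa_cut: float = MVPA_CUT,
    min_wear_fraction: float = MIN_WEAR_FRACTION,
) -> dict:
    """Full accelerometry pipeline.

    Returns a dict with keys ``waking`` (imputed waking epochs of included
    participants), ``validities``, ``selection`` and ``summary``.
    """
    waking = extract_waking_epochs(epochs, sleep_log, n_days)
    validities = validate_days(waking, sleep_log, n_days, min_wear_fraction)
    selection = select_participants(validities)
    included = selection.loc[selection["included"], "participant_id"]
    waking_inc = waking[waking["participant_id"].isin(included)]
    validities_inc = validities[validities["participant_id"].isin(included)]
    corrected = correct_nonwear(waking_inc, validities_inc)
    summary = summarize_activity(
        corrected, validities_inc, epoch_seconds, light_cut, mvpa_cut
    )
    return {
        "waking": corrected,
        "validities": validities,
        "selection": selection,
        "summary": summary,
    }
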