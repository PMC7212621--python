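"""Diary I/O and preprocessing: dedup, windowing, week collapsing.

Conventions (fixed throughout the package):

- day 0 is the baseline date; the intervention window is half-open,
  ``[baseline, followup)``;
- week ``w`` (1-based) contains days ``7*(w-1) .. 7*w - 1``;
- ``total_weeks = ceil(duration_days / 7)``; a final partial week counts
  as a full week index, with ``days_present`` reflecting only observed
  entry days;
- normalized treatment time is ``week_index / total_weeks`` in (0, 1];
- weeks with no entries are not materialized as rows — missingness
  within an observed week is carried by ``7 - days_present``;
- sample SD (n-1 denominator) everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError

__all__ = [
    "read_participants",
    "read_diary",
    "write_table",
    "deduplicate",
    "window_entries",
    "collapse_weeks",
    "weekly_summary_stats",
    "CohortSummary",
]

logger = logging.getLogger(__name__)

DIARY_COLUMNS = ["participant_id", "date", "drinks"]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "sex",
    "baseline_date",
    "followup_date",
    "baseline_tlfb",
    "followup_tlfb",
    "audit_baseline",
    "audit_followup",
]


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["baseline_date", "followup_date"])
    missing = set(PARTICIPANT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValidationError(f"participant table missing columns: {sorted(missing)}")
    return df


def read_diary(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(DIARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"diary table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as CSV with ISO-8601 dates and stable float format."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def deduplicate(entries: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (participant, date) entries, keeping the maximum
    reported drinks.

    Raises
    ------
    ValidationError
        If any entry has negative drinks (offending rows listed).
    """
    neg = entries.index[entries["drinks"] < 0]
    if len(neg):
        raise ValidationError(f"negative drinks in rows {list(neg[:20])}")
    before = len(entries)
    out = (
        entries.groupby(["participant_id", "date"], as_index=False, sort=True)["drinks"]
        .max()
        .reset_index(drop=True)
    )
    logger.info("deduplicate: %d -> %d entries (%d duplicates removed)", before, len(out), before - len(out))
    return out


def window_entries(entries: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Keep entries inside the intervention window [baseline, followup).

    Raises
    ------
    ValidationError
        If any entry references a participant id absent from the
        participant table.
    """
    known = set(participants["participant_id"])
    unknown = sorted(set(entries["participant_id"]) - known)
    if unknown:
        raise ValidationError(f"diary entries for unknown participant ids: {unknown[:10]}")
    merged = entries.merge(
        participants[["participant_id", "baseline_date", "followup_date"]],
        on="participant_id",
        how="left",
    )
    keep = (merged["date"] >= merged["baseline_date"]) & (merged["date"] < merged["followup_date"])
    dropped = int((~keep).sum())
    logger.info("window_entries: dropped %d entries outside [baseline, followup)", dropped)
    return entries.loc[keep.to_numpy()].reset_index(drop=True)


def collapse_weeks(entries: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Collapse deduplicated, windowed entries into participant-weeks.

    Returns one row per (participant, week) with at least one entry:
    ``participant_id, week_index, total_weeks, raw_drinks, days_present,
    n_entries, normalized_time``. ``raw_drinks`` is the within-week sum,
    ``days_present`` the count of distinct entry days (1..7).
    """
    merged = entries.merge(
        participants[["participant_id", "baseline_date", "followup_date"]],
        on="participant_id",
        how="left",
    )
    day = (merged["date"] - merged["baseline_date"]).dt.days
    if (day < 0).any() or (merged["date"] >= merged["followup_date"]).any():
        raise ValidationError("entries must be windowed to [baseline, followup) before collapsing")
    merged["week_index"] = day // 7 + 1
    duration = (merged["followup_date"] - merged["baseline_date"]).dt.days
    merged["total_weeks"] = np.ceil(duration / 7).astype(int)

    weeks = (
        merged.groupby(["participant_id", "week_index", "total_weeks"], as_index=False, sort=True)
        .agg(
            raw_drinks=("drinks", "sum"),
            days_present=("date", "nunique"),
            n_entries=("date", "size"),
        )
    )
    weeks["normalized_time"] = weeks["week_index"] / weeks["total_weeks"]
    logger.info(
        "collapse_weeks: %d participant-weeks from %d entries (%d participants)",
        len(weeks),
        len(entries),
        weeks["participant_id"].nunique(),
    )
    return weeks


@dataclass
class CohortSummary:
    """Cohort descriptives used for generator calibration checks."""

    n_participants: int
    n_weeks: int
    n_entries: int
    mean_weeks: float
    sd_weeks: float
    min_weeks: int
    max_weeks: int
    mean_entries: float
    sd_entries: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def weekly_summary_stats(weeks: pd.DataFrame) -> CohortSummary:
    """Descriptive statistics of diary-weeks and entries per participant."""
    if len(weeks) == 0:
        raise ValidationError("no participant-weeks to summarize")
    per = weeks.groupby("participant_id").agg(
        n_weeks=("week_index", "size"), n_entries=("n_entries", "sum")
    )
    wk = per["n_weeks"].to_numpy(dtype=float)
    en = per["n_entries"].to_numpy(dtype=float)
    return CohortSummary(
        n_participants=len(per),
        n_weeks=int(wk.sum()),
        n_entries=int(en.sum()),
        mean_weeks=float(wk.mean()),
        sd_weeks=float(wk.std(ddof=1)) if len(wk) > 1 else 0.0,
        min_weeks=int(wk.min()),
        max_weeks=int(wk.max()),
        mean_entries=float(en.mean()),
        sd_entries=float(en.std(ddof=1)) if len(en) > 1 else 0.0,
    )
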