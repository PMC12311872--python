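"""Reading and repairing minute-level wearable records.

Consumer wrist devices export heart rate (bpm) and step counts (steps/min)
on a one-minute grid, with nonwear periods zero-coded in the heart-rate
channel.  This module parses those exports, regrids them to a strict
1-minute grid trimmed to whole calendar days, repairs missing heart-rate
samples by linear interpolation, and applies the wear-time eligibility
rules used throughout the package: at least five consecutive weekdays of
data and no calendar day with more than six hours of nonwear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
#: a calendar day with more than this many missing minutes counts as nonwear
MAX_NONWEAR_MINUTES_PER_DAY = 360
#: minimum run of consecutive weekdays required for eligibility
MIN_CONSECUTIVE_WEEKDAYS = 5


class WearableParseError(ValueError):
    """Malformed minute file, sleep log or manifest row."""


@dataclass(frozen=True)
class MinuteSeries:
    """A uniformly gridded one-minute signal for one participant.

    ``values`` sits on a strict 60-second grid starting at ``start`` (always
    a midnight after regridding).  ``missing`` marks samples that were
    zero-coded or absent in the raw export; after
    :func:`interpolate_missing_hr` the mask is preserved for audit while the
    values are repaired.
    """

    start: pd.Timestamp
    values: np.ndarray
    missing: np.ndarray
    kind: str  # "heart_rate" | "steps"

    def __post_init__(self) -> None:
        if self.kind not in ("heart_rate", "steps"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if len(self.values) != len(self.missing):
            raise ValueError("values and missing mask length mismatch")
        if len(self.values) % MINUTES_PER_DAY != 0:
            raise ValueError("series length must be a whole number of days")

    @property
    def n_days(self) -> int:
        return len(self.values) // MINUTES_PER_DAY

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.values), freq="min")

    def daily(self) -> np.ndarray:
        """Values reshaped to (days, 1440)."""
        return self.values.reshape(self.n_days, MINUTES_PER_DAY)


@dataclass(frozen=True)
class SleepEpisode:
    """One device-logged sleep interval."""

    onset: pd.Timestamp
    offset: pd.Timestamp

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("sleep offset must follow onset")
        if self.offset - self.onset >= pd.Timedelta(hours=24):
            raise ValueError("sleep episode of 24 h or more is not plausible")

    @property
    def duration_minutes(self) -> float:
        return (self.offset - self.onset) / pd.Timedelta(minutes=1)

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.onset + (self.offset - self.onset) / 2


@dataclass
class ParticipantRecord:
    """All wearable data for one participant over the same calendar span."""

    participant_id: str
    hr: MinuteSeries
    steps: MinuteSeries
    sleep: list[SleepEpisode]
    group: str  # "case" | "control"
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if self.hr.start != self.steps.start or len(self.hr.values) != len(self.steps.values):
            raise ValueError("hr and steps must cover the same calendar span")


@dataclass(frozen=True)
class EligibilityVerdict:
    eligible: bool
    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.eligible


def _parse_timestamps(raw: pd.Series, source: str) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise WearableParseError(
            f"{source}: malformed timestamp {raw[bad].iloc[0]!r} at line {line}"
        )
    return pd.DatetimeIndex(parsed)


def read_minute_file(path: str | Path) -> pd.DataFrame:
    """Read a minute-level CSV (timestamp, heart_rate, steps), validated."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"timestamp", "heart_rate", "steps"}
    if not required.issubset(df.columns):
        raise WearableParseError(
            f"{path.name}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    idx = _parse_timestamps(df["timestamp"], path.name).floor("min")
    if idx.duplicated().any():
        dup = idx[idx.duplicated()][0]
        raise WearableParseError(f"{path.name}: duplicate minute {dup}")
    df = df.drop(columns="timestamp")
    df.index = idx
    return df.sort_index()


def _trim_to_whole_days(df: pd.DataFrame) -> pd.DataFrame:
    """Regrid to 1-min resolution and keep only whole midnight-to-midnight days."""
    start = df.index[0].ceil("D") if df.index[0] != df.index[0].floor("D") else df.index[0]
    end = (df.index[-1] + pd.Timedelta(minutes=1)).floor("D")
    if end <= start:
        raise WearableParseError("record does not span a whole calendar day")
    grid = pd.date_range(start, end - pd.Timedelta(minutes=1), freq="min")
    return df.reindex(grid)


def read_participant(
    minute_file: str | Path,
    sleep_file: str | Path,
    manifest_row: Mapping,
) -> ParticipantRecord:
    """Read one participant's minute file and sleep log into a record.

    The minute grid is trimmed to whole calendar days; minutes absent from
    the file and zero-coded heart-rate samples are flagged in the missing
    mask.  Step gaps are treated as genuine zeros (rest), not nonwear.
    """
    df = _trim_to_whole_days(read_minute_file(minute_file))
    hr_raw = df["heart_rate"].to_numpy(dtype=float)
    steps_raw = df["steps"].to_numpy(dtype=float)

    hr_missing = np.isnan(hr_raw) | (hr_raw <= 0)
    hr_vals = np.where(hr_missing, 0.0, hr_raw)
    steps_vals = np.nan_to_num(steps_raw, nan=0.0)
    if (steps_vals < 0).any():
        raise WearableParseError(f"{Path(minute_file).name}: negative step count")

    start = pd.Timestamp(df.index[0])
    hr = MinuteSeries(start=start, values=hr_vals, missing=hr_missing, kind="heart_rate")
    steps = MinuteSeries(
        start=start,
        values=steps_vals,
        missing=np.zeros_like(hr_missing),
        kind="steps",
    )

    sleep_df = pd.read_csv(sleep_file, comment="#")
    if not {"onset", "offset"}.issubset(sleep_df.columns):
        raise WearableParseError(f"{Path(sleep_file).name}: expected onset/offset columns")
    onsets = _parse_timestamps(sleep_df["onset"], Path(sleep_file).name)
    offsets = _parse_timestamps(sleep_df["offset"], Path(sleep_file).name)
    episodes = sorted(
        (SleepEpisode(on, off) for on, off in zip(onsets, offsets)),
        key=lambda e: e.onset,
    )

    covariates = {
        k: manifest_row[k]
        for k in ("age", "sex", "bmi")
        if k in manifest_row and not pd.isna(manifest_row[k])
    }
    return ParticipantRecord(
        participant_id=str(manifest_row["participant_id"]),
        hr=hr,
        steps=steps,
        sleep=episodes,
        group=str(manifest_row["group"]),
        covariates=covariates,
    )


def interpolate_missing_hr(series: MinuteSeries) -> MinuteSeries:
    """Repair masked heart-rate runs by linear interpolation.

    Interior gaps are bridged linearly between the nearest valid neighbours;
    leading/trailing runs take the nearest valid value.  The missing mask is
    preserved unchanged for audit.  Idempotent.
    """
    if series.kind != "heart_rate":
        raise ValueError("interpolation is defined for heart-rate series only")
    valid = ~series.missing
    if not valid.any():
        raise ValueError("no valid heart-rate data")
    if valid.all():
        return series
    idx = np.arange(len(series.values), dtype=float)
    repaired = np.interp(idx, idx[valid], series.values[valid])
    if (repaired <= 0).any():
        raise ValueError("heart-rate values must be strictly positive after repair")
    return replace(series, values=repaired)


def _weekday_runs(dates: Sequence[pd.Timestamp]) -> int:
    """Longest run of calendar-consecutive days that are all weekdays."""
    best = run = 0
    prev = None
    for d in dates:
        if d.dayofweek >= 5:  # weekend breaks the run
            run = 0
        elif prev is not None and (d - prev).days == 1 and run > 0:
            run += 1
        else:
            run = 1
        best = max(best, run)
        prev = d
    return best


def check_wear_eligibility(record: ParticipantRecord) -> EligibilityVerdict:
    """Apply the wear-time rules: >=5 consecutive weekdays, <=6 h nonwear/day."""
    hr = record.hr
    days = [hr.start.normalize() + pd.Timedelta(days=i) for i in range(hr.n_days)]
    missing_per_day = hr.missing.reshape(hr.n_days, MINUTES_PER_DAY).sum(axis=1)
    worst = int(missing_per_day.max(initial=0))
    if worst > MAX_NONWEAR_MINUTES_PER_DAY:
        day = days[int(np.argmax(missing_per_day))].date()
        return EligibilityVerdict(False, f"nonwear > 6 h on {day} ({worst} missing minutes)")
    run = _weekday_runs(days)
    if run < MIN_CONSECUTIVE_WEEKDAYS:
        return EligibilityVerdict(
            False,
            f"only {run} consecutive weekdays of data (need {MIN_CONSECUTIVE_WEEKDAYS})",
        )
    return EligibilityVerdict(True, "eligible")
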