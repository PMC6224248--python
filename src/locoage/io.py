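"""Reading, writing and filtering of activity tracks and cohort tables.

Tracks are 7-day per-minute activity-count records.  Two inclusion
filters are applied before any modelling: participants with abnormally
low (mean count < 50) or high (> 5000) overall activity are excluded,
and days with fewer than 200 minutes in a non-sedentary state (> 0) are
marked invalid; a participant needs at least 4 valid days to be retained.
Days are consecutive 1440-minute blocks from the start of the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import DiscretizationScheme, StateSequence, discretize

__all__ = [
    "MINUTES_PER_DAY",
    "ActivityTrack",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "read_cohort",
    "write_cohort",
    "filter_participants",
    "filter_days",
    "apply_filters",
    "mean_log_activity",
    "valid_segments",
    "state_sequence",
]

MINUTES_PER_DAY = 1440

MEAN_COUNT_LOW = 50.0
MEAN_COUNT_HIGH = 5000.0
MIN_ACTIVE_MINUTES = 200
MIN_VALID_DAYS = 4

COHORT_COLUMNS = [
    "participant_id",
    "age",
    "gender",
    "delta_death",
    "delta_disease",
    "followup_years",
    "smoking_status",
]


class TrackFormatError(ValueError):
    """Malformed track file (missing columns, bad values, duplicate minutes)."""


@dataclass
class ActivityTrack:
    """Per-minute activity counts for one participant.

    ``valid_day_flags`` (one per complete 1440-minute day) is filled in by
    :func:`filter_days`; a trailing partial day is never a valid day.
    """

    participant_id: str
    counts: np.ndarray
    valid_day_flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-d")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.valid_day_flags is not None:
            flags = np.asarray(self.valid_day_flags, dtype=bool)
            if flags.size != self.n_days:
                raise ValueError("one validity flag per complete day required")
            self.valid_day_flags = flags

    @property
    def n_minutes(self) -> int:
        return self.counts.size

    @property
    def n_days(self) -> int:
        return self.counts.size // MINUTES_PER_DAY


def read_tracks(path) -> list[ActivityTrack]:
    """Read tracks from CSV (participant_id, minute_index, count).

    Minutes must be contiguous from 0 within each participant; counts
    non-negative.  Violations raise :class:`TrackFormatError` naming the
    offending row (0-based data row).
    """
    df = pd.read_csv(path)
    required = {"participant_id", "minute_index", "count"}
    missing = required - set(df.columns)
    if missing:
        raise TrackFormatError(f"missing columns: {sorted(missing)}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna()
    if bad.any():
        raise TrackFormatError(f"non-numeric count at row {int(bad.idxmax())}")
    neg = counts < 0
    if neg.any():
        raise TrackFormatError(f"negative count at row {int(neg.idxmax())}")
    tracks = []
    for pid, grp in df.groupby("participant_id", sort=False):
        minutes = grp["minute_index"].to_numpy()
        dup = pd.Series(minutes).duplicated()
        if dup.any():
            row = int(grp.index[np.flatnonzero(dup.to_numpy())[0]])
            raise TrackFormatError(
                f"duplicated minute index for participant {pid!r} at row {row}"
            )
        order = np.argsort(minutes, kind="stable")
        minutes = minutes[order]
        if not np.array_equal(minutes, np.arange(minutes.size)):
            raise TrackFormatError(
                f"minutes not contiguous from 0 for participant {pid!r}"
            )
        tracks.append(
            ActivityTrack(str(pid), counts.to_numpy()[grp.index][order])
        )
    return tracks


def write_tracks(tracks: list[ActivityTrack], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": t.participant_id,
                "minute_index": np.arange(t.n_minutes),
                "count": t.counts,
            }
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise TrackFormatError(f"cohort table missing columns: {sorted(missing)}")
    if (df["followup_years"] < 0).any():
        raise TrackFormatError("followup_years must be non-negative")
    if not df["delta_death"].isin([0, 1]).all():
        raise TrackFormatError("delta_death must be 0/1")
    if (df["age"] <= 0).any():
        raise TrackFormatError("ages must be positive")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def filter_participants(
    tracks: list[ActivityTrack],
    low: float = MEAN_COUNT_LOW,
    high: float = MEAN_COUNT_HIGH,
) -> tuple[list[ActivityTrack], list[dict]]:
    """Drop participants with abnormal overall activity (mean < low or > high).

    Boundary values are retained.  Returns the retained tracks and an
    exclusion log; retained + excluded partition the input.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    retained, excluded = [], []
    for t in tracks:
        if t.n_minutes == 0:
            excluded.append({"participant_id": t.participant_id, "reason": "empty"})
            continue
        m = float(t.counts.mean())
        if m < low:
            excluded.append(
                {"participant_id": t.participant_id, "reason": "low_activity",
                 "mean_count": m}
            )
        elif m > high:
            excluded.append(
                {"participant_id": t.participant_id, "reason": "high_activity",
                 "mean_count": m}
            )
        else:
            retained.append(t)
    return retained, excluded


def filter_days(
    track: ActivityTrack,
    states: StateSequence,
    min_active_minutes: int = MIN_ACTIVE_MINUTES,
    min_valid_days: int = MIN_VALID_DAYS,
) -> tuple[np.ndarray, bool]:
    """Flag valid days and decide participant retention.

    A day (consecutive 1440-minute block) is valid iff it contains at
    least ``min_active_minutes`` minutes in states > 0.  The participant
    is retained iff at least ``min_valid_days`` days are valid.  The flags
    are stored on the track.
    """
    if states.states.size != track.n_minutes:
        raise ValueError("state sequence not aligned to track minutes")
    n_days = track.n_days
    if n_days == 0:
        track.valid_day_flags = np.zeros(0, dtype=bool)
        return track.valid_day_flags, False
    active = (
        states.states[: n_days * MINUTES_PER_DAY].reshape(n_days, MINUTES_PER_DAY) > 0
    )
    flags = active.sum(axis=1) >= min_active_minutes
    track.valid_day_flags = flags
    return flags, bool(flags.sum() >= min_valid_days)


def valid_segments(track: ActivityTrack) -> list[tuple[int, int]]:
    """Maximal runs of consecutive valid days as (start, stop) minute ranges.

    Transitions are counted only within these segments, so no pair spans
    an invalid (non-wear) day.
    """
    if track.valid_day_flags is None:
        flags = np.ones(track.n_days, dtype=bool)
    else:
        flags = track.valid_day_flags
    segments: list[tuple[int, int]] = []
    start = None
    for d, ok in enumerate(flags):
        if ok and start is None:
            start = d
        elif not ok and start is not None:
            segments.append((start * MINUTES_PER_DAY, d * MINUTES_PER_DAY))
            start = None
    if start is not None:
        segments.append((start * MINUTES_PER_DAY, flags.size * MINUTES_PER_DAY))
    return segments


def state_sequence(
    track: ActivityTrack, scheme: DiscretizationScheme | None = None
) -> StateSequence:
    """Discretize a track and attach its valid-day segments."""
    seq = discretize(track.counts, scheme)
    seq.segments = valid_segments(track)
    return seq


def apply_filters(
    tracks: list[ActivityTrack], scheme: DiscretizationScheme | None = None
) -> tuple[list[ActivityTrack], list[dict]]:
    """Participant-mean filter then day filter, as applied to NHANES-style data."""
    retained, excluded = filter_participants(tracks)
    kept = []
    for t in retained:
        seq = discretize(t.counts, scheme)
        _, ok = filter_days(t, seq)
        if ok:
            kept.append(t)
        else:
            excluded.append(
                {"participant_id": t.participant_id, "reason": "too_few_valid_days",
                 "n_valid_days": int(t.valid_day_flags.sum())}
            )
    return kept, excluded


def mean_log_activity(track: ActivityTrack) -> float:
    """Negative natural log of the mean count over valid days.

    A simple single-number activity summary; higher values mean lower
    average daily activity.
    """
    if track.valid_day_flags is None or track.n_days == 0:
        counts = track.counts
    else:
        days = track.counts[: track.n_days * MINUTES_PER_DAY].reshape(
            track.n_days, MINUTES_PER_DAY
        )
        counts = days[track.valid_day_flags].ravel()
    if counts.size == 0:
        raise ValueError("no valid days")
    m = counts.mean()
    if m <= 0:
        raise ValueError("mean activity is zero; negative log undefined")
    return float(-np.log(m))
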