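"""From episode records to day x channel matrices, cohorts, windows, splits.

The pipeline is: pick the 7 most prevalent behaviors population-wide, fold
everything else into "Other" (8 behavior channels), OR-aggregate the three
daily shifts into one binary value per day, optionally append a 9th seizure
channel, slide a 7- or 14-day window over each subject's timeline to produce
(W x C feature block, next-day binary label) samples, and split each subject's
samples 80/20 in time order so every training target day precedes every test
target day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import SEIZURE_CHANNEL

__all__ = [
    "OTHER_CHANNEL",
    "DailyMatrix",
    "WindowSample",
    "SplitDataset",
    "select_top_behaviors",
    "aggregate_daily",
    "build_daily_matrices",
    "append_seizure_channel",
    "filter_cohort",
    "severe_cohort",
    "make_windows",
    "temporal_split",
    "samples_to_arrays",
]

log = logging.getLogger(__name__)

OTHER_CHANNEL = "Other"


@dataclass
class DailyMatrix:
    """Per-subject day x channel binary matrix.

    Day index is 0-based from ``start_date``.  Channel order is fixed:
    the 7 selected behaviors (by descending population prevalence), then
    ``Other``, then optionally ``Seizure`` as channel 9.
    """

    subject_id: str
    start_date: pd.Timestamp
    values: np.ndarray  # (T, C) int8 in {0, 1}
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise ValueError("values shape must be (days, len(channel_names))")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("entries must be binary")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None


@dataclass
class WindowSample:
    """One sliding-window sample: W days of history predicting day t.

    ``X`` rows are ordered oldest -> newest (days t-W .. t-1); ``y`` is the
    binary occurrence of the target channel on day ``target_day`` = t.
    """

    X: np.ndarray  # (W, C) int8
    y: int
    target_day: int
    subject_id: str


@dataclass
class SplitDataset:
    """Temporally ordered train/test split of one subject's samples."""

    train: list[WindowSample]
    test: list[WindowSample]


def select_top_behaviors(
    records: pd.DataFrame, k: int = 7, exclude: Iterable[str] = (SEIZURE_CHANNEL,)
) -> list[str]:
    """The ``k`` behavior names with the most recorded episodes
    population-wide, descending by count, ties broken lexicographically.
    Everything else maps to ``Other``; channels in ``exclude`` (the seizure
    channel by default) are not behaviors and never compete."""
    if records.empty:
        raise ValueError("cannot select behaviors from an empty record table")
    counts = records.loc[~records["behavior"].isin(set(exclude)), "behavior"].value_counts()
    if len(counts) < k:
        raise ValueError(
            f"only {len(counts)} distinct behaviors present, need at least {k}"
        )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


def aggregate_daily(
    records: pd.DataFrame,
    channels: Sequence[str],
    start_date: str | pd.Timestamp,
    n_days: int,
    subject_id: str,
) -> DailyMatrix:
    """OR-aggregate one subject's per-shift records into a day x 8 matrix.

    ``channels`` are the selected top behaviors; any other behavior (except
    the seizure channel, which is handled by :func:`append_seizure_channel`)
    sets the trailing ``Other`` channel.  A day with no records is all-zero.
    Records dated outside ``[start_date, start_date + n_days)`` raise.
    """
    start = pd.Timestamp(start_date)
    names = tuple(channels) + (OTHER_CHANNEL,)
    values = np.zeros((n_days, len(names)), dtype=np.int8)
    sub = records[records["subject_id"] == subject_id]
    sub = sub[sub["behavior"] != SEIZURE_CHANNEL]
    if not sub.empty:
        day = (pd.to_datetime(sub["date"]) - start).dt.days.to_numpy()
        if (day < 0).any() or (day >= n_days).any():
            bad = sub["date"].to_numpy()[(day < 0) | (day >= n_days)][:5]
            raise ValueError(
                f"records for {subject_id} outside declared span "
                f"[{start.date()}, +{n_days}d): {list(bad)}"
            )
        idx = {name: i for i, name in enumerate(channels)}
        col = np.array(
            [idx.get(b, len(names) - 1) for b in sub["behavior"]], dtype=int
        )
        values[day, col] = 1
    return DailyMatrix(subject_id, start, values, names)


def build_daily_matrices(
    records: pd.DataFrame,
    channels: Sequence[str],
    start_date: str | pd.Timestamp,
    n_days: int,
    subject_ids: Sequence[str],
) -> dict[str, DailyMatrix]:
    """Convenience: :func:`aggregate_daily` for every subject in a population
    sharing one observation span."""
    return {
        sid: aggregate_daily(records, channels, start_date, n_days, sid)
        for sid in subject_ids
    }


def append_seizure_channel(
    matrix: DailyMatrix,
    seizures: pd.DataFrame,
    seizure_cohort: Iterable[str],
) -> DailyMatrix:
    """Append the binary seizure channel (channel 9) to an 8-channel matrix.

    ``seizures`` holds the seizure episode records (rows with ``behavior ==
    "Seizure"`` are used; a (subject_id, date)-only table also works).
    ``seizure_cohort`` declares which subjects belong to the seizure dataset:
    the seizure task is restricted to subjects present in both datasets, so a
    subject outside the cohort raises rather than silently getting an
    all-zero channel.
    """
    if SEIZURE_CHANNEL in matrix.channel_names:
        raise ValueError("matrix already has a seizure channel")
    if len(matrix.channel_names) != 8 or matrix.channel_names[-1] != OTHER_CHANNEL:
        raise ValueError("expected an 8-channel behavior matrix ending in 'Other'")
    if matrix.subject_id not in set(seizure_cohort):
        raise ValueError(
            f"subject {matrix.subject_id} is not in the seizure cohort; "
            "the seizure task only covers subjects present in both datasets"
        )
    sub = seizures[seizures["subject_id"] == matrix.subject_id]
    if "behavior" in sub.columns:
        sub = sub[sub["behavior"] == SEIZURE_CHANNEL]
    col = np.zeros((matrix.n_days, 1), dtype=np.int8)
    if not sub.empty:
        day = (pd.to_datetime(sub["date"]) - matrix.start_date).dt.days.to_numpy()
        ok = (day >= 0) & (day < matrix.n_days)
        if not ok.all():
            raise ValueError(
                f"seizure records for {matrix.subject_id} outside declared span"
            )
        col[day, 0] = 1
    return DailyMatrix(
        matrix.subject_id,
        matrix.start_date,
        np.hstack([matrix.values, col]),
        matrix.channel_names + (SEIZURE_CHANNEL,),
    )


def filter_cohort(
    matrices: dict[str, DailyMatrix], target_channel: str
) -> list[str]:
    """Subjects with at least one occurrence of the target channel over their
    span (subjects with none are excluded from that prediction task)."""
    kept = []
    for sid, m in matrices.items():
        if m.values[:, m.channel_index(target_channel)].any():
            kept.append(sid)
    return kept


def severe_cohort(
    records: pd.DataFrame,
    target_behavior: str,
    min_fraction: float = 0.10,
    subjects: Sequence[str] | None = None,
) -> list[str]:
    """Subjects for whom at least ``min_fraction`` of recorded target
    episodes are tagged severe.  Subjects with zero target episodes are
    excluded (not a division error)."""
    sub = records[records["behavior"] == target_behavior]
    if subjects is not None:
        order = list(subjects)
        sub = sub[sub["subject_id"].isin(set(order))]
    else:
        order = sorted(sub["subject_id"].unique())
    kept = []
    grouped = sub.groupby("subject_id")["severe"]
    frac = grouped.mean()
    count = grouped.size()
    for sid in order:
        if count.get(sid, 0) > 0 and frac[sid] >= min_fraction:
            kept.append(sid)
    return kept


def make_windows(
    matrix: DailyMatrix, window: int, target_channel: str
) -> list[WindowSample]:
    """Stride-1 sliding windows: sample i has features = days ``i..i+W-1``
    and label = target channel on day ``i+W``.  The target channel's own
    history is part of the features.  ``T <= W`` yields an empty list."""
    if window < 1:
        raise ValueError("window length must be >= 1")
    tgt = matrix.channel_index(target_channel)
    t_days = matrix.n_days
    if t_days <= window:
        log.info(
            "subject %s: %d days <= window %d, no samples",
            matrix.subject_id, t_days, window,
        )
        return []
    return [
        WindowSample(
            X=matrix.values[i : i + window].copy(),
            y=int(matrix.values[i + window, tgt]),
            target_day=i + window,
            subject_id=matrix.subject_id,
        )
        for i in range(t_days - window)
    ]


def temporal_split(
    samples: Sequence[WindowSample],
    train_frac: float = 0.8,
    min_test: int = 1,
) -> SplitDataset | None:
    """Chronological split: first ``floor(train_frac * N)`` samples train,
    remainder test, no shuffling.  Returns ``None`` (subject flagged and
    skipped) when the train set would be empty or the test set smaller than
    ``min_test``."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    ordered = sorted(samples, key=lambda s: s.target_day)
    n = len(ordered)
    n_train = int(np.floor(train_frac * n))
    if n_train < 1 or n - n_train < min_test:
        sid = ordered[0].subject_id if ordered else "<empty>"
        log.warning("subject %s skipped: %d samples cannot be split", sid, n)
        return None
    return SplitDataset(train=ordered[:n_train], test=ordered[n_train:])


def samples_to_arrays(
    samples: Sequence[WindowSample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into ``X`` of shape (N, W, C, 1) and ``y`` of shape (N,)."""
    if not samples:
        raise ValueError("no samples to stack")
    x = np.stack([s.X for s in samples]).astype(np.float64)[..., None]
    y = np.array([s.y for s in samples], dtype=np.float64)
    return x, y
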