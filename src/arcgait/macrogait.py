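"""Macro-gait outcomes: ambulatory-bout segmentation and daily walking metrics.

An ambulatory bout (AB) is a run of consecutive steps in which no inter-step
rest exceeds ``max_rest_s`` (default 2.5 s); runs with fewer than ``min_steps``
steps (default 3) are discarded. Six day-level outcomes summarise each
participant-day:

volume
    total walking time (s), total steps, total bouts;
pattern
    mean bout length (s) and the power-law exponent *alpha* of the bout-length
    distribution — a high alpha means walking time is dominated by
    proportionally short bouts;
variability
    the within-day sample SD of bout lengths (s) — lower values indicate a
    more repetitive activity pattern.

Alpha is the continuous power-law maximum-likelihood estimate
``alpha = 1 + n / sum(ln(d_i / x_min))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import WEEKEND_DAYS, WEEKDAYS, StepEventDay

__all__ = [
    "SegmentationParams",
    "Bout",
    "DayOutcomes",
    "OUTCOME_COLUMNS",
    "segment_bouts",
    "day_outcomes",
    "estimate_alpha",
    "build_day_table",
    "steps_from_bouts",
]

#: day-table outcome columns in reporting order (volume, pattern, variability)
OUTCOME_COLUMNS = [
    "total_walk_time_s",
    "total_steps",
    "total_bouts",
    "mean_bout_length_s",
    "alpha",
    "variability_s",
]


@dataclass(frozen=True)
class SegmentationParams:
    max_rest_s: float = 2.5
    min_steps: int = 3

    def __post_init__(self) -> None:
        if self.max_rest_s <= 0:
            raise ValueError("max_rest_s must be > 0")
        if self.min_steps < 1:
            raise ValueError("min_steps must be >= 1")


@dataclass(frozen=True)
class Bout:
    start_s: float
    duration_s: float
    n_steps: int


@dataclass
class DayOutcomes:
    participant_id: str
    care_level: str
    facility_id: str
    calendar_day: int
    day_of_week: str
    is_weekend: bool
    total_walk_time_s: float
    total_steps: int
    total_bouts: int
    mean_bout_length_s: float  # NaN when no bouts
    alpha: float  # NaN when too few bouts or degenerate
    variability_s: float  # NaN when fewer than 2 bouts


def segment_bouts(
    day: StepEventDay | Sequence[float] | np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> list[Bout]:
    """Split a day's step times into ambulatory bouts.

    A rest strictly longer than ``params.max_rest_s`` closes the current bout;
    candidate bouts with fewer than ``params.min_steps`` steps are dropped.
    Bout duration is last-step time minus first-step time.
    """
    times = day.step_times if isinstance(day, StepEventDay) else np.asarray(day, dtype=float)
    if times.size == 0:
        return []
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("step times must be strictly increasing")

    breaks = np.flatnonzero(np.diff(times) > params.max_rest_s) + 1
    bouts = []
    for seg in np.split(times, breaks):
        if seg.size >= params.min_steps:
            bouts.append(Bout(float(seg[0]), float(seg[-1] - seg[0]), int(seg.size)))
    return bouts


def day_outcomes(bouts: Sequence[Bout], meta: StepEventDay | dict, min_bouts_for_alpha: int = 5) -> DayOutcomes:
    """Reduce a day's bouts to the six walking outcomes.

    Degenerate days never raise: with no bouts the volume outcomes are zero
    and pattern/variability outcomes are NaN; alpha additionally requires
    ``min_bouts_for_alpha`` bouts and a non-degenerate duration spread.
    """
    if isinstance(meta, StepEventDay):
        meta = {
            "participant_id": meta.participant_id,
            "care_level": meta.care_level,
            "facility_id": meta.facility_id,
            "calendar_day": meta.calendar_day,
            "day_of_week": meta.day_of_week,
        }
    durations = np.asarray([b.duration_s for b in bouts])
    n = durations.size
    total_time = float(durations.sum()) if n else 0.0
    if n >= min_bouts_for_alpha:
        alpha = estimate_alpha(durations, min_bouts=min_bouts_for_alpha)
    else:
        alpha = math.nan
    dow = meta["day_of_week"]
    return DayOutcomes(
        participant_id=meta["participant_id"],
        care_level=meta["care_level"],
        facility_id=meta["facility_id"],
        calendar_day=int(meta["calendar_day"]),
        day_of_week=dow,
        is_weekend=dow in WEEKEND_DAYS,
        total_walk_time_s=total_time,
        total_steps=int(sum(b.n_steps for b in bouts)),
        total_bouts=int(n),
        mean_bout_length_s=total_time / n if n else math.nan,
        alpha=alpha,
        variability_s=float(durations.std(ddof=1)) if n >= 2 else math.nan,
    )


def estimate_alpha(
    durations: Sequence[float] | np.ndarray,
    x_min: float | None = None,
    min_bouts: int = 5,
) -> float:
    """Continuous power-law MLE of the bout-length exponent.

    ``alpha = 1 + n / sum(ln(d_i / x_min))``; ``x_min`` defaults to the
    minimum observed duration. Returns NaN for fewer than ``min_bouts``
    durations or a degenerate distribution (all durations at ``x_min``, where
    the MLE diverges). Scale-invariant: rescaling durations and ``x_min``
    together leaves alpha unchanged.
    """
    d = np.asarray(durations, dtype=float)
    if x_min is None:
        x_min = float(d.min()) if d.size else math.nan
    if not x_min > 0:
        raise ValueError("x_min must be > 0")
    if d.size and d.min() < x_min * (1 - 1e-12):
        raise ValueError(f"durations below x_min={x_min} (min={d.min()})")
    if d.size < min_bouts:
        return math.nan
    s = float(np.log(d / x_min).sum())
    if s <= 0:
        return math.nan  # all mass at x_min: alpha -> infinity
    return 1.0 + d.size / s


@dataclass
class DayTable:
    """Per-day outcomes plus the participant-level exclusion log."""

    table: pd.DataFrame
    excluded: dict[str, int] = field(default_factory=dict)  # id -> days recorded


def build_day_table(
    step_days: Iterable[StepEventDay],
    params: SegmentationParams = SegmentationParams(),
    min_full_days: int = 3,
    min_bouts_for_alpha: int = 5,
) -> DayTable:
    """Segment every participant-day and apply the minimum-days inclusion rule.

    Participants contributing fewer than ``min_full_days`` days are excluded
    (and logged, never raised). Rows are reordered into a uniform Monday-first
    week structure within participant, so day-of-week comparisons align across
    participants regardless of when recording started.
    """
    rows = []
    days_per_participant: dict[str, int] = {}
    for day in step_days:
        days_per_participant[day.participant_id] = (
            days_per_participant.get(day.participant_id, 0) + 1
        )
        rows.append(day_outcomes(segment_bouts(day, params), day, min_bouts_for_alpha))

    excluded = {
        pid: n for pid, n in days_per_participant.items() if n < min_full_days
    }
    df = pd.DataFrame([vars(r) for r in rows], columns=list(DayOutcomes.__annotations__))
    if not df.empty:
        df = df[~df["participant_id"].isin(excluded)]
        df["_dow"] = df["day_of_week"].map({d: i for i, d in enumerate(WEEKDAYS)})
        df = (
            df.sort_values(["participant_id", "_dow", "calendar_day"], kind="mergesort")
            .drop(columns="_dow")
            .reset_index(drop=True)
        )
    return DayTable(table=df, excluded=excluded)


def steps_from_bouts(bouts: Sequence[Bout]) -> np.ndarray:
    """Reconstruct an isochronous step-time sequence realising the bouts."""
    times = []
    for b in bouts:
        if b.n_steps == 1:
            times.append(np.array([b.start_s]))
        else:
            times.append(b.start_s + np.linspace(0.0, b.duration_s, b.n_steps))
    return np.concatenate(times) if times else np.empty(0)
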