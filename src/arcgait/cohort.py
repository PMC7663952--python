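"""Synthetic aged-residential-care (ARC) cohort generator.

Emulates the data structure of a week-long trunk-worn accelerometry study in
residential care: participants nested in facilities and stratified by care
level (intermediate / high / dementia), each contributing up to seven days of
step-event data, with a wear-compliance log recording why data were lost.

The generative model is deliberately simple and fully known, so every
downstream stage (bout segmentation, outcome computation, variance
partitioning) can be validated against recorded truth:

* each participant draws a subject random intercept ``b_i ~ N(0, sigma_between^2)``
  and inherits a facility intercept ``f_k ~ N(0, sigma_facility^2)``;
* a day's latent walking volume (total seconds of walking) is log-normal,
  ``exp(mu_level + b_i + f_k + weekend_effect * 1[weekend] + e_ij)`` with
  ``e_ij ~ N(0, sigma_within^2)``, censored at a physiological daily ceiling;
* bout durations are drawn from a truncated Pareto (power law) with a
  care-level exponent until the latent volume is reached; steps within a bout
  are isochronous at ``step_cadence_hz``;
* inter-bout rests are always longer than the segmentation threshold, so the
  generated bouts are exactly recoverable from the step events.

All randomness flows from a single seed; each participant uses a
deterministic substream, so cohorts are reproducible and insensitive to
generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CARE_LEVELS",
    "WEEKDAYS",
    "WEEKEND_DAYS",
    "DropoutConfig",
    "CohortConfig",
    "StepEventDay",
    "WearLogEntry",
    "generate_cohort",
    "simulate_latent_cohort",
    "write_step_events",
    "read_step_events",
    "write_wear_log",
    "read_wear_log",
]

CARE_LEVELS = ("intermediate", "high", "dementia")
WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
WEEKEND_DAYS = frozenset({"Sat", "Sun"})

#: loss reasons as fractions of explained data loss
_DEFAULT_REASONS = {
    "skin_irritation": 0.516,
    "device_loss": 0.158,
    "equipment_failure": 0.147,
    "other": 0.179,
}

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class DropoutConfig:
    """Wear-compliance model: full week / partial week / complete loss."""

    p_full: float = 0.44
    p_partial: float = 0.44
    p_zero: float = 0.12
    reasons: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_REASONS))

    def validate(self) -> None:
        probs = (self.p_full, self.p_partial, self.p_zero)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                f"dropout probabilities must be non-negative and sum to 1, got {probs}"
            )
        if not self.reasons:
            raise ValueError("dropout reason distribution is empty")
        if any(p < 0 for p in self.reasons.values()):
            raise ValueError("dropout reason probabilities must be non-negative")
        if abs(sum(self.reasons.values()) - 1.0) > 1e-6:
            raise ValueError(
                f"dropout reason probabilities must sum to 1, got {self.reasons}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters; defaults emulate the target ARC setting.

    ``mu_by_level`` is the log-scale median of daily walking seconds per care
    level; ``sigma_between``/``sigma_within`` partition the log-scale variance
    between subjects and between days within subject, so the latent single-day
    ICC is ``sigma_between^2 / (sigma_between^2 + sigma_within^2)``.
    """

    n_participants_by_level: dict[str, int] = field(
        default_factory=lambda: {"intermediate": 104, "high": 68, "dementia": 24}
    )
    n_facilities: int = 17
    days_full: int = 7
    start_weekday: str = "random"  # a weekday name, or "random" per participant
    mu_by_level: dict[str, float] = field(
        default_factory=lambda: {"intermediate": 7.2, "high": 6.9, "dementia": 7.1}
    )
    sigma_between: float = 0.7
    sigma_facility: float = 0.15
    weekend_effect: float = -0.02
    sigma_within: float = 0.45
    bout_alpha_by_level: dict[str, float] = field(
        default_factory=lambda: {"intermediate": 2.3, "high": 2.5, "dementia": 2.1}
    )
    min_bout_duration_s: float = 1.5
    max_bout_duration_s: float = 1800.0
    step_cadence_hz: float = 1.8
    max_daily_walk_s: float = 21_600.0  # physiological ceiling, censors the tail
    min_inter_bout_gap_s: float = 2.6  # strictly above the 2.5 s rest threshold
    dropout: DropoutConfig = field(default_factory=DropoutConfig)
    seed: int = 0

    def validate(self) -> None:
        if not self.n_participants_by_level:
            raise ValueError("n_participants_by_level is empty")
        for level, n in self.n_participants_by_level.items():
            if level not in CARE_LEVELS:
                raise ValueError(f"unknown care level {level!r}; expected one of {CARE_LEVELS}")
            if n < 0:
                raise ValueError(f"negative participant count for level {level!r}")
            if level not in self.mu_by_level:
                raise ValueError(f"mu_by_level missing level {level!r}")
            if level not in self.bout_alpha_by_level:
                raise ValueError(f"bout_alpha_by_level missing level {level!r}")
        if self.n_facilities < 1:
            raise ValueError("n_facilities must be >= 1")
        if not 1 <= self.days_full <= 7:
            raise ValueError("days_full must be within [1, 7]")
        if self.start_weekday != "random" and self.start_weekday not in WEEKDAYS:
            raise ValueError(f"start_weekday must be 'random' or one of {WEEKDAYS}")
        for name in ("sigma_between", "sigma_facility", "sigma_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for level, a in self.bout_alpha_by_level.items():
            if a <= 1:
                raise ValueError(f"bout power-law exponent for {level!r} must exceed 1, got {a}")
        if self.min_bout_duration_s <= 0:
            raise ValueError("min_bout_duration_s must be > 0")
        if self.max_bout_duration_s <= self.min_bout_duration_s:
            raise ValueError("max_bout_duration_s must exceed min_bout_duration_s")
        if self.step_cadence_hz <= 0:
            raise ValueError("step_cadence_hz must be > 0")
        if self.min_bout_duration_s * self.step_cadence_hz < 2.0:
            raise ValueError(
                "min_bout_duration_s * step_cadence_hz must be >= 2 so every "
                "generated bout contains at least 3 steps"
            )
        if self.min_inter_bout_gap_s <= 2.5:
            raise ValueError("min_inter_bout_gap_s must exceed the 2.5 s rest threshold")
        if not 0 < self.max_daily_walk_s < SECONDS_PER_DAY:
            raise ValueError("max_daily_walk_s must lie in (0, 86400)")
        for level in self.n_participants_by_level:
            median_volume = float(np.exp(self.mu_by_level[level]))
            if median_volume > self.max_daily_walk_s:
                raise ValueError(
                    f"impossible config: median daily walking volume for level "
                    f"{level!r} is {median_volume:.0f} s, above the "
                    f"{self.max_daily_walk_s:.0f} s daily ceiling"
                )
        self.dropout.validate()


@dataclass
class StepEventDay:
    """One participant-day of detected step events (seconds from midnight)."""

    participant_id: str
    care_level: str
    facility_id: str
    calendar_day: int
    day_of_week: str
    step_times: np.ndarray

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        if self.step_times.size:
            if np.any(np.diff(self.step_times) <= 0):
                raise ValueError(
                    f"step_times must be strictly increasing "
                    f"(participant {self.participant_id}, day {self.calendar_day})"
                )
            if self.step_times[0] < 0 or self.step_times[-1] >= SECONDS_PER_DAY:
                raise ValueError(
                    f"step_times must lie in [0, 86400) "
                    f"(participant {self.participant_id}, day {self.calendar_day})"
                )

    @property
    def is_weekend(self) -> bool:
        return self.day_of_week in WEEKEND_DAYS


@dataclass(frozen=True)
class WearLogEntry:
    participant_id: str
    care_level: str
    days_recorded: int
    loss_reason: str  # "none" iff the full week was recorded

    def __post_init__(self) -> None:
        if not 0 <= self.days_recorded <= 7:
            raise ValueError("days_recorded must lie in [0, 7]")


def _weekday_cycle(start: str, n_days: int) -> list[str]:
    i0 = WEEKDAYS.index(start)
    return [WEEKDAYS[(i0 + d) % 7] for d in range(n_days)]


def _draw_bouts(
    rng: np.random.Generator,
    target_volume_s: float,
    alpha: float,
    x_min: float,
    x_max: float,
    cadence: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw bouts until realized walking time reaches the latent volume.

    Returns (realized durations, step counts). Drawn Pareto durations are
    snapped to the isochronous step grid: a bout of target duration d gets
    ``floor(d * cadence) + 1`` steps and realized duration ``(n-1)/cadence``.
    """
    durations: list[float] = []
    steps: list[int] = []
    total = 0.0
    while total < target_volume_s:
        # draw in blocks for speed; exponent alpha => pareto shape alpha - 1
        block = x_min * (1.0 + rng.pareto(alpha - 1.0, size=64))
        block = np.minimum(block, x_max)
        for d in block:
            n = int(np.floor(d * cadence)) + 1
            realized = (n - 1) / cadence
            durations.append(realized)
            steps.append(n)
            total += realized
            if total >= target_volume_s:
                break
    return np.asarray(durations), np.asarray(steps, dtype=int)


def _place_bouts(
    rng: np.random.Generator,
    durations: np.ndarray,
    steps: np.ndarray,
    cadence: float,
    min_gap: float,
) -> np.ndarray:
    """Lay bouts into a day with every rest strictly above the threshold."""
    n_bouts = durations.size
    walk = float(durations.sum())
    overhead = min_gap * (n_bouts + 1)
    free = SECONDS_PER_DAY - walk - overhead
    if free <= 0:
        raise ValueError(
            f"impossible config: {walk:.0f} s of walking in {n_bouts} bouts plus "
            f"minimum rests does not fit into one day"
        )
    if n_bouts == 0:
        return np.empty(0)
    # split the slack over the n_bouts + 1 gaps (before, between, after)
    w = rng.dirichlet(np.ones(n_bouts + 1))
    gaps = min_gap + w * free
    starts = np.cumsum(gaps[:-1]) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    times = [s + np.arange(n) / cadence for s, n in zip(starts, steps)]
    return np.concatenate(times) if times else np.empty(0)


def _day_truth(durations: np.ndarray, steps: np.ndarray, min_bouts_for_alpha: int = 5) -> dict:
    """Macro-gait outcomes implied by the generated bouts (ground truth)."""
    n = int(durations.size)
    out = {
        "total_walk_time_s": float(durations.sum()),
        "total_steps": int(steps.sum()),
        "total_bouts": n,
        "mean_bout_length_s": float(durations.mean()) if n else None,
        "variability_s": float(durations.std(ddof=1)) if n >= 2 else None,
    }
    alpha = None
    if n >= min_bouts_for_alpha:
        log_ratio = np.log(durations / durations.min())
        s = float(log_ratio.sum())
        if s > 0:
            alpha = 1.0 + n / s
    out["alpha"] = alpha
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[StepEventDay], list[WearLogEntry], dict]:
    """Generate step events, a wear log and a full truth record.

    Deterministic given ``config.seed``; each participant draws from a
    substream keyed by (seed, level index, participant index).
    """
    config.validate()
    rng_global = np.random.default_rng([config.seed, 915])
    facility_effects = rng_global.normal(0.0, config.sigma_facility, config.n_facilities)

    step_days: list[StepEventDay] = []
    wear_log: list[WearLogEntry] = []
    truth: dict = {
        "config": _config_to_jsonable(config),
        "facility_effects": facility_effects.tolist(),
        "participants": [],
    }

    reason_names = list(config.dropout.reasons)
    reason_probs = np.asarray([config.dropout.reasons[r] for r in reason_names])
    reason_probs = reason_probs / reason_probs.sum()

    for level_idx, level in enumerate(CARE_LEVELS):
        n_level = config.n_participants_by_level.get(level, 0)
        for j in range(n_level):
            rng = np.random.default_rng([config.seed, level_idx, j])
            pid = f"{level[:3]}-{j + 1:03d}"
            facility = int(rng.integers(config.n_facilities))
            b_i = float(rng.normal(0.0, config.sigma_between))

            u = rng.random()
            if u < config.dropout.p_full:
                category, days_recorded = "full", config.days_full
                reason = "none"
            elif u < config.dropout.p_full + config.dropout.p_partial:
                category = "partial"
                days_recorded = int(rng.integers(1, config.days_full))
                reason = reason_names[rng.choice(len(reason_names), p=reason_probs)]
            else:
                category, days_recorded = "zero", 0
                reason = reason_names[rng.choice(len(reason_names), p=reason_probs)]

            start = (
                WEEKDAYS[rng.integers(7)]
                if config.start_weekday == "random"
                else config.start_weekday
            )
            weekdays = _weekday_cycle(start, days_recorded)

            p_truth = {
                "participant_id": pid,
                "care_level": level,
                "facility_id": f"F{facility + 1:02d}",
                "subject_intercept": b_i,
                "facility_intercept": float(facility_effects[facility]),
                "wear_category": category,
                "loss_reason": reason,
                "start_weekday": start,
                "days": [],
            }

            for d, dow in enumerate(weekdays, start=1):
                is_weekend = dow in WEEKEND_DAYS
                e_ij = float(rng.normal(0.0, config.sigma_within))
                log_volume = (
                    config.mu_by_level[level]
                    + b_i
                    + float(facility_effects[facility])
                    + (config.weekend_effect if is_weekend else 0.0)
                    + e_ij
                )
                volume = min(float(np.exp(log_volume)), config.max_daily_walk_s)
                # bout composition is a deterministic function of the day's
                # latent volume (and level): equal volumes yield identical
                # days, so degenerate-variance configs produce exact clones
                vbits = np.frombuffer(np.float64(volume).tobytes(), dtype=np.uint32)
                day_rng = np.random.default_rng(
                    [config.seed, level_idx, int(vbits[0]), int(vbits[1])]
                )
                durations, steps = _draw_bouts(
                    day_rng,
                    volume,
                    config.bout_alpha_by_level[level],
                    config.min_bout_duration_s,
                    config.max_bout_duration_s,
                    config.step_cadence_hz,
                )
                times = _place_bouts(
                    day_rng, durations, steps, config.step_cadence_hz, config.min_inter_bout_gap_s
                )
                step_days.append(
                    StepEventDay(
                        participant_id=pid,
                        care_level=level,
                        facility_id=f"F{facility + 1:02d}",
                        calendar_day=d,
                        day_of_week=dow,
                        step_times=times,
                    )
                )
                day_rec = {
                    "calendar_day": d,
                    "day_of_week": dow,
                    "is_weekend": is_weekend,
                    "latent_log_volume": log_volume,
                    "latent_volume_s": volume,
                    "bout_durations_s": durations.tolist(),
                }
                day_rec.update(_day_truth(durations, steps))
                p_truth["days"].append(day_rec)

            wear_log.append(WearLogEntry(pid, level, days_recorded, reason))
            truth["participants"].append(p_truth)

    return step_days, wear_log, truth


def simulate_latent_cohort(
    n_subjects: int,
    n_days: int,
    sigma_between: float,
    sigma_within: float,
    mu: float = 0.0,
    weekend_effect: float = 0.0,
    start_weekday: str = "random",
    seed: int = 0,
) -> pd.DataFrame:
    """Day-level draws from the latent random-intercept model only.

    Fast path for estimator validation (parameter recovery, type-I error
    studies): skips bout/step synthesis and returns a tidy frame with the
    latent outcome ``y`` whose true single-day ICC is exactly
    ``sigma_between^2 / (sigma_between^2 + sigma_within^2)``.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_between, n_subjects)
    rows = []
    for i in range(n_subjects):
        start = WEEKDAYS[rng.integers(7)] if start_weekday == "random" else start_weekday
        for d, dow in enumerate(_weekday_cycle(start, n_days), start=1):
            is_weekend = dow in WEEKEND_DAYS
            y = (
                mu
                + b[i]
                + (weekend_effect if is_weekend else 0.0)
                + rng.normal(0.0, sigma_within)
            )
            rows.append(
                {
                    "participant_id": f"S{i + 1:04d}",
                    "calendar_day": d,
                    "day_of_week": dow,
                    "is_weekend": is_weekend,
                    "y": y,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text IO

_STEP_COLUMNS = [
    "participant_id",
    "care_level",
    "facility_id",
    "calendar_day",
    "day_of_week",
    "step_time_s",
]


def write_step_events(step_days: Iterable[StepEventDay], path: str | Path) -> None:
    """One row per step event; header always written, even for no data."""
    frames = []
    for day in step_days:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": day.participant_id,
                    "care_level": day.care_level,
                    "facility_id": day.facility_id,
                    "calendar_day": day.calendar_day,
                    "day_of_week": day.day_of_week,
                    "step_time_s": day.step_times,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_STEP_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_step_events(path: str | Path) -> list[StepEventDay]:
    """Parse a step-event CSV back into per-day records.

    Malformed numeric fields are reported with 1-based file line numbers;
    non-monotone step times are reported with the offending participant-day.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _STEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"step-event file {path} is missing columns: {missing}")
    if df.empty:
        return []

    for col in ("calendar_day", "step_time_s"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()] + 2  # header is line 1
        if len(bad):
            raise ValueError(
                f"malformed {col!r} values in {path} at line(s) {list(bad[:10])}"
            )
        if converted.isna().any():
            empty = df.index[converted.isna()] + 2
            raise ValueError(f"empty {col!r} values in {path} at line(s) {list(empty[:10])}")
        df[col] = converted
    df["calendar_day"] = df["calendar_day"].astype(int)

    out = []
    for (pid, day), grp in df.groupby(["participant_id", "calendar_day"], sort=True):
        times = grp["step_time_s"].to_numpy()
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError(
                f"step_times not strictly increasing for participant {pid}, day {day}"
            )
        out.append(
            StepEventDay(
                participant_id=str(pid),
                care_level=str(grp["care_level"].iloc[0]),
                facility_id=str(grp["facility_id"].iloc[0]),
                calendar_day=int(day),
                day_of_week=str(grp["day_of_week"].iloc[0]),
                step_times=times,
            )
        )
    return out


def write_wear_log(entries: Iterable[WearLogEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "care_level": e.care_level,
                "days_recorded": e.days_recorded,
                "loss_reason": e.loss_reason,
            }
            for e in entries
        ],
        columns=["participant_id", "care_level", "days_recorded", "loss_reason"],
    )
    df.to_csv(path, index=False)


def read_wear_log(path: str | Path) -> list[WearLogEntry]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    return [
        WearLogEntry(
            participant_id=str(r.participant_id),
            care_level=str(r.care_level),
            days_recorded=int(r.days_recorded),
            loss_reason=str(r.loss_reason),
        )
        for r in df.itertuples()
    ]


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d))  # normalize tuples etc. to JSON types
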