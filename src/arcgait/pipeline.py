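"""End-to-end orchestration: simulate/ingest -> segment -> outcomes -> reliability.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and a
seed; identical configs produce byte-identical artifacts. Each run directory
contains the day-level outcome table, the reliability table, week-structure
tests, a wear-compliance summary and a machine-readable manifest echoing the
full configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    DropoutConfig,
    WearLogEntry,
    generate_cohort,
    read_step_events,
    write_step_events,
    write_wear_log,
)
from .macrogait import OUTCOME_COLUMNS, SegmentationParams, build_day_table
from .reliability import (
    DEFAULT_TRANSFORMS,
    day_of_week_effects,
    reliability_table,
)

__all__ = ["RunConfig", "ComplianceSummary", "run_pipeline", "summarize_compliance"]

log = logging.getLogger("arcgait")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    step_events_path: str = "simulate"  # path to a step-event CSV, or "simulate"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    transforms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    target_icc: float = 0.8
    min_full_days: int = 3
    min_bouts_for_alpha: int = 5
    n_boot: int = 200
    out_dir: str = "arcgait_run"
    seed: int = 0
    log_level: str = "INFO"
    write_step_events: bool = False  # raw events can be large; opt in

    def validate(self) -> None:
        if not 0 < self.target_icc < 1:
            raise ValueError("target_icc must lie in (0, 1)")
        if self.min_full_days < 1:
            raise ValueError("min_full_days must be >= 1")
        if self.step_events_path != "simulate" and not Path(self.step_events_path).exists():
            raise ValueError(f"step-event file not found: {self.step_events_path}")
        self.cohort.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        cohort_raw = dict(raw.pop("cohort", {}))
        dropout_raw = cohort_raw.pop("dropout", None)
        if dropout_raw is not None:
            cohort_raw["dropout"] = DropoutConfig(**dropout_raw)
        seg_raw = raw.pop("segmentation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            cohort=CohortConfig(**cohort_raw),
            segmentation=SegmentationParams(**seg_raw),
            **raw,
        )
        if "seed" in cohort_raw:
            pass  # explicit cohort seed wins
        else:
            cfg.cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        return cfg


@dataclass
class ComplianceSummary:
    n_total: int
    pct_full_week: float
    pct_partial: float
    pct_zero: float
    mean_days_recorded: float
    mean_days_by_level: dict[str, float]
    mean_days_among_wearers: float
    reason_distribution: dict[str, float]  # % over explained losses
    by_level: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_compliance(
    wear_log: Sequence[WearLogEntry] | pd.DataFrame, full_days: int = 7
) -> ComplianceSummary:
    """Descriptive wear-compliance accounting from the wear log."""
    if isinstance(wear_log, pd.DataFrame):
        df = wear_log.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "participant_id": e.participant_id,
                    "care_level": e.care_level,
                    "days_recorded": e.days_recorded,
                    "loss_reason": e.loss_reason,
                }
                for e in wear_log
            ]
        )
    if df.empty:
        raise ValueError("wear log is empty")

    def _block(d: pd.DataFrame) -> dict[str, float]:
        n = len(d)
        full = (d["days_recorded"] >= full_days).sum()
        zero = (d["days_recorded"] == 0).sum()
        wearers = d[d["days_recorded"] > 0]
        return {
            "n": float(n),
            "pct_full_week": 100.0 * full / n,
            "pct_partial": 100.0 * (n - full - zero) / n,
            "pct_zero": 100.0 * zero / n,
            "mean_days_recorded": float(d["days_recorded"].mean()),
            "mean_days_among_wearers": (
                float(wearers["days_recorded"].mean()) if len(wearers) else math.nan
            ),
        }

    overall = _block(df)
    explained = df[(df["loss_reason"] != "none") & df["loss_reason"].notna()]
    reasons = (
        (100.0 * explained["loss_reason"].value_counts() / len(explained)).to_dict()
        if len(explained)
        else {}
    )
    return ComplianceSummary(
        n_total=len(df),
        pct_full_week=overall["pct_full_week"],
        pct_partial=overall["pct_partial"],
        pct_zero=overall["pct_zero"],
        mean_days_recorded=overall["mean_days_recorded"],
        mean_days_by_level={
            level: float(grp["days_recorded"].mean())
            for level, grp in df.groupby("care_level")
        },
        mean_days_among_wearers=overall["mean_days_among_wearers"],
        reason_distribution=reasons,
        by_level={level: _block(grp) for level, grp in df.groupby("care_level")},
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all artifacts to the run directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    wear_log = None
    stage = "input"
    try:
        if config.step_events_path == "simulate":
            step_days, wear_log, truth = generate_cohort(config.cohort)
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)
            write_wear_log(wear_log, out / "wear_log.csv")
            if config.write_step_events:
                write_step_events(step_days, out / "step_events.csv")
        else:
            step_days = read_step_events(config.step_events_path)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(stage, exc) from exc

    stage = "outcomes"
    try:
        day_table = build_day_table(
            step_days,
            config.segmentation,
            min_full_days=config.min_full_days,
            min_bouts_for_alpha=config.min_bouts_for_alpha,
        )
        for pid, n in sorted(day_table.excluded.items()):
            log.info("excluded participant %s: only %d full day(s) recorded", pid, n)
        _write_csv(day_table.table, out / "day_outcomes.csv")
        pd.DataFrame(
            [{"participant_id": p, "days_recorded": n, "reason": "below_min_full_days"}
             for p, n in sorted(day_table.excluded.items())]
        ).to_csv(out / "exclusions.csv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "reliability"
    try:
        rel = reliability_table(
            day_table.table,
            transforms=config.transforms,
            target_icc=config.target_icc,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        _write_csv(rel, out / "reliability.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "day_effects"
    try:
        pair_frames, weekend_rows = [], []
        for outcome in OUTCOME_COLUMNS:
            res = day_of_week_effects(
                day_table.table, outcome, config.transforms.get(outcome, "identity")
            )
            pw = res.pairwise.copy()
            pw.insert(0, "outcome", outcome)
            pair_frames.append(pw)
            weekend_rows.append({"outcome": outcome, **res.weekend_beta})
        _write_csv(pd.concat(pair_frames, ignore_index=True), out / "day_effects.csv")
        _write_csv(pd.DataFrame(weekend_rows), out / "weekend_effects.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "compliance"
    try:
        if wear_log is not None:
            summary = summarize_compliance(wear_log, full_days=config.cohort.days_full)
            with open(out / "compliance.json", "w") as fh:
                json.dump(summary.to_dict(), fh, indent=1)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "arcgait_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "n_participants_included": int(day_table.table["participant_id"].nunique())
        if not day_table.table.empty
        else 0,
        "n_participants_excluded": len(day_table.excluded),
        "n_days_analyzed": int(len(day_table.table)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
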