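"""Published single-day ICC values for walking outcomes in residential care.

Reference table from a week-long trunk-worn accelerometry reliability study
of 196 aged-residential-care residents (104 intermediate-level, 68 high-level,
24 dementia-unit). Each row carries the reported single-day ICC (with 95% CI)
and the reported number of monitoring days needed to reach a composite
reliability of 0.8. The ICCs are inputs for validating the prophecy-formula
day projection: feeding each reported ICC through :func:`arcgait.reliability.
days_needed` must reproduce every reported day count.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PUBLISHED_ICC_TABLE", "published_icc_table"]

# (domain, outcome, stratum, n_participants, icc, ci_low, ci_high, days_reported)
PUBLISHED_ICC_TABLE: list[tuple[str, str, str, int, float, float, float, int]] = [
    ("volume", "total_walk_time_s", "whole_group", 196, 0.71, 0.65, 0.75, 2),
    ("volume", "total_walk_time_s", "dementia", 24, 0.63, 0.46, 0.77, 3),
    ("volume", "total_walk_time_s", "high", 68, 0.70, 0.61, 0.77, 2),
    ("volume", "total_walk_time_s", "intermediate", 104, 0.67, 0.59, 0.74, 2),
    ("volume", "total_steps", "whole_group", 196, 0.70, 0.65, 0.75, 2),
    ("volume", "total_steps", "dementia", 24, 0.65, 0.49, 0.79, 3),
    ("volume", "total_steps", "high", 68, 0.69, 0.60, 0.77, 2),
    ("volume", "total_steps", "intermediate", 104, 0.65, 0.57, 0.72, 3),
    ("volume", "total_bouts", "whole_group", 196, 0.77, 0.73, 0.81, 2),
    ("volume", "total_bouts", "dementia", 24, 0.67, 0.51, 0.80, 2),
    ("volume", "total_bouts", "high", 68, 0.74, 0.66, 0.81, 2),
    ("volume", "total_bouts", "intermediate", 104, 0.75, 0.68, 0.80, 2),
    ("pattern", "mean_bout_length_s", "whole_group", 196, 0.72, 0.68, 0.77, 2),
    ("pattern", "mean_bout_length_s", "dementia", 24, 0.76, 0.62, 0.86, 2),
    ("pattern", "mean_bout_length_s", "high", 68, 0.53, 0.43, 0.64, 4),
    ("pattern", "mean_bout_length_s", "intermediate", 104, 0.56, 0.48, 0.65, 4),
    ("pattern", "alpha", "whole_group", 196, 0.46, 0.40, 0.53, 5),
    ("pattern", "alpha", "dementia", 24, 0.75, 0.60, 0.85, 2),
    ("pattern", "alpha", "high", 68, 0.43, 0.32, 0.54, 6),
    ("pattern", "alpha", "intermediate", 104, 0.37, 0.29, 0.47, 7),
    ("variability", "variability_s", "whole_group", 196, 0.63, 0.57, 0.68, 3),
    ("variability", "variability_s", "dementia", 24, 0.80, 0.68, 0.89, 1),
    ("variability", "variability_s", "high", 68, 0.53, 0.42, 0.63, 4),
    ("variability", "variability_s", "intermediate", 104, 0.49, 0.40, 0.57, 5),
]


def published_icc_table() -> pd.DataFrame:
    """The reference table as a DataFrame in reporting order."""
    return pd.DataFrame(
        PUBLISHED_ICC_TABLE,
        columns=[
            "domain",
            "outcome",
            "stratum",
            "n_participants",
            "icc",
            "ci_low",
            "ci_high",
            "days_reported",
        ],
    )
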