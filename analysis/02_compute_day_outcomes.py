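"""Segment step events into ambulatory bouts and compute daily outcomes.

Applies the 2.5 s maximum-rest / 3-step minimum bout definition and the
3-full-days inclusion rule, then publishes per-care-level medians (IQR) of
the six walking outcomes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, SCRATCH, cohort

import pandas as pd

from arcgait.macrogait import OUTCOME_COLUMNS, build_day_table


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    days, _, _ = cohort()
    result = build_day_table(days)
    result.table.to_csv(SCRATCH / "day_outcomes.csv", index=False)

    n_inc = result.table["participant_id"].nunique()
    print(f"included participants : {n_inc}")
    print(f"excluded (<3 days)    : {len(result.excluded)}")
    print(f"analyzable days       : {len(result.table)}")

    rows = []
    for level, grp in result.table.groupby("care_level"):
        for outcome in OUTCOME_COLUMNS:
            q = grp[outcome].quantile([0.25, 0.5, 0.75])
            rows.append(
                {
                    "care_level": level,
                    "outcome": outcome,
                    "median": q.loc[0.5],
                    "iqr_low": q.loc[0.25],
                    "iqr_high": q.loc[0.75],
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "day_outcomes_summary.csv", index=False, float_format="%.3f")
    print(summary.pivot(index="outcome", columns="care_level", values="median").round(2))
    print(f"summary -> {RESULTS / 'day_outcomes_summary.csv'}")


if __name__ == "__main__":
    main()
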