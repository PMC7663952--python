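"""Test the impact of week structure on each walking outcome.

All 21 pairwise day-of-week contrasts (p < 0.01 threshold) plus the
weekday/weekend dummy model, per outcome.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, day_table_cached

import pandas as pd

from arcgait.macrogait import OUTCOME_COLUMNS
from arcgait.reliability import DEFAULT_TRANSFORMS, day_of_week_effects


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = day_table_cached()
    pair_frames, weekend_rows = [], []
    for outcome in OUTCOME_COLUMNS:
        res = day_of_week_effects(table, outcome, DEFAULT_TRANSFORMS[outcome])
        pw = res.pairwise.copy()
        pw.insert(0, "outcome", outcome)
        pair_frames.append(pw)
        weekend_rows.append({"outcome": outcome, **res.weekend_beta})
        n_sig = int(pw["significant"].sum())
        print(f"{outcome:<20} significant day pairs (p<0.01): {n_sig}/21")
    pairs = pd.concat(pair_frames, ignore_index=True)
    weekend = pd.DataFrame(weekend_rows)
    pairs.to_csv(RESULTS / "day_effects.csv", index=False, float_format="%.4g")
    weekend.to_csv(RESULTS / "weekend_effects.csv", index=False, float_format="%.4g")
    print("\nweekend betas (95% CI):")
    print(weekend.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
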