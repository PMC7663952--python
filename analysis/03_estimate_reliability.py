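"""Estimate single-day ICCs and days needed for reliability 0.8.

Fits the covariate-adjusted random-intercept model for each outcome, whole
group and per care level, with cluster-bootstrap CIs, and inverts the
Spearman-Brown prophecy formula for the day projection.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, SEED, day_table_cached

from arcgait.reliability import reliability_table


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = day_table_cached()
    rel = reliability_table(table, n_boot=200, seed=SEED)
    rel.to_csv(RESULTS / "reliability.csv", index=False, float_format="%.4g")
    show = rel[["outcome", "stratum", "n_participants", "icc", "ci_low", "ci_high", "days_needed"]]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(f"-> {RESULTS / 'reliability.csv'}")


if __name__ == "__main__":
    main()
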