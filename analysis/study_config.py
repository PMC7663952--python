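"""Shared study conditions for the analysis scripts.

One seeded configuration emulating the target aged-residential-care setting:
104 intermediate / 68 high / 24 dementia enrolled participants across 17
facilities, week-long wear with 44/44/12% full/partial/zero compliance.
Bulky intermediates (step events, truth record, full day table) live under
scratch/; the scripts publish small summary tables under results/.
"""

from pathlib import Path

import pandas as pd

from arcgait import CohortConfig, generate_cohort
from arcgait.macrogait import build_day_table

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_COHORT = CohortConfig(seed=SEED)


def cohort():
    return generate_cohort(STUDY_COHORT)


def day_table_cached() -> pd.DataFrame:
    """Segmented day-level outcomes for the study cohort (cached in scratch)."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / "day_outcomes.csv"
    if cache.exists():
        return pd.read_csv(cache)
    days, _, _ = cohort()
    table = build_day_table(days).table
    table.to_csv(cache, index=False)
    return table
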