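"""Simulate the study cohort: step events, wear log and truth record.

Writes the wear log to results/ (small) and the step events plus the full
generative truth record to scratch/ (large). Prints headline cohort facts.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, SCRATCH, cohort

from arcgait import write_step_events
from arcgait.cohort import write_wear_log


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    days, wear, truth = cohort()
    write_step_events(days, SCRATCH / "step_events.csv")
    write_wear_log(wear, RESULTS / "wear_log.csv")
    with open(SCRATCH / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    n_steps = sum(d.step_times.size for d in days)
    wearers = [e for e in wear if e.days_recorded > 0]
    print(f"enrolled participants : {len(wear)}")
    print(f"participant-days      : {len(days)}")
    print(f"step events           : {n_steps}")
    print(f"wearers (>0 days)     : {len(wearers)}")
    print(
        "mean days among wearers: "
        f"{sum(e.days_recorded for e in wearers) / len(wearers):.2f}"
    )
    print(f"step events -> {SCRATCH / 'step_events.csv'}")
    print(f"wear log    -> {RESULTS / 'wear_log.csv'}")


if __name__ == "__main__":
    main()
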