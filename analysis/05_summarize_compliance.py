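"""Summarize wear compliance: full/partial/zero weeks and loss reasons."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import RESULTS, cohort

from arcgait import summarize_compliance


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    _, wear, _ = cohort()
    s = summarize_compliance(wear)
    with open(RESULTS / "compliance.json", "w") as fh:
        json.dump(s.to_dict(), fh, indent=1)
    print(f"participants            : {s.n_total}")
    print(f"full week               : {s.pct_full_week:.1f}%")
    print(f"partial data            : {s.pct_partial:.1f}%")
    print(f"complete loss           : {s.pct_zero:.1f}%")
    print(f"mean days among wearers : {s.mean_days_among_wearers:.2f}")
    print("loss reasons (% of explained losses):")
    for reason, pct in sorted(s.reason_distribution.items(), key=lambda kv: -kv[1]):
        print(f"  {reason:<18} {pct:.1f}%")
    print(f"-> {RESULTS / 'compliance.json'}")


if __name__ == "__main__":
    main()
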