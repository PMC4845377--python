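#!/usr/bin/env python
"""Find incident depression cases and pair them 1:1 with matched controls.

Applies the four-criterion case-finding algorithm (two MDD codes on distinct
days, antidepressant prescription, note mention, PHQ-9 >= 15; any two
criteria define a case, dated at the second criterion), screens exclusion
diagnoses, then matches each incident case to a control on birth year (+/-2),
sex and an outpatient visit in the index year.
"""

from collections import Counter
from datetime import date
from pathlib import Path

import pandas as pd

from mdd_comorbidity import classify_cohort, match_cohort, read_tables, validate_pairs

SEED = 43  # matching tie-break seed
WINDOW = (date(2000, 1, 1), date(2013, 12, 31))
TABLES = Path("scratch/study/tables")
OUT = Path("scratch/study")


def main() -> None:
    records, _ = read_tables(TABLES)
    lookup = {r.patient_id: r for r in records}
    calls = classify_cohort(records, WINDOW)
    counts = Counter(c.status for c in calls)
    print("cohort classification:", dict(counts))

    cases = [c for c in calls if c.status == "incident_case"]
    pool = [lookup[c.patient_id] for c in calls if c.status == "control_eligible"]
    pairs, unmatched = match_cohort(cases, pool, lookup, seed=SEED)
    assert validate_pairs(pairs, lookup) == []
    print(f"matched {len(pairs)}/{len(cases)} incident cases "
          f"({len(unmatched)} unmatched)")
    print("pairs per stratum:", dict(Counter(p.stratum for p in pairs)))

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(p.case_id, p.control_id, p.case_index, p.control_index, p.stratum) for p in pairs],
        columns=["case_id", "control_id", "case_index", "control_index", "stratum"],
    ).to_csv(OUT / "pairs.csv", index=False)
    pd.DataFrame({"case_id": unmatched}).to_csv(OUT / "unmatched.csv", index=False)


if __name__ == "__main__":
    main()
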