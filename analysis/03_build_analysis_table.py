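#!/usr/bin/env python
"""Ascertain chronic conditions and build the per-subject analysis table.

Each subject's 24 condition flags use the two-code/30-day rule over the
5 years before their own index date; obesity is a single-code flag.  Writes
the analysis table (scratch) and the descriptive summaries (results/):
cohort characteristics and per-condition case/control frequencies.
"""

from datetime import date
from pathlib import Path

import pandas as pd

from mdd_comorbidity import build_analysis_table, load_catalog, read_tables
from mdd_comorbidity.ascertainment import rows_to_frame
from mdd_comorbidity.matching import MatchedPair
from mdd_comorbidity.pipeline import _build_fig1, _build_table1

TABLES = Path("scratch/study/tables")
SCRATCH = Path("scratch/study")
RESULTS = Path("results/study")


def main() -> None:
    records, _ = read_tables(TABLES)
    lookup = {r.patient_id: r for r in records}
    pairs = [
        MatchedPair(r.case_id, r.control_id, date.fromisoformat(r.case_index),
                    date.fromisoformat(r.control_index), r.stratum)
        for r in pd.read_csv(SCRATCH / "pairs.csv", dtype=str).itertuples(index=False)
    ]
    catalog = load_catalog()
    rows = build_analysis_table(pairs, lookup, catalog)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows_to_frame(rows).to_csv(SCRATCH / "analysis_table.csv", index=False)
    _build_table1(rows, lookup).to_csv(RESULTS / "table1.csv", index=False)
    fig1 = _build_fig1(rows, catalog)
    fig1.to_csv(RESULTS / "fig1_frequencies.csv", index=False)

    cases = [r for r in rows if r.outcome == 1]
    controls = [r for r in rows if r.outcome == 0]
    pct = lambda rs: 100 * sum(r.burden >= 1 for r in rs) / len(rs)
    print(f"{len(rows)} analysis rows ({len(cases)} cases)")
    print(f">=1 chronic condition: cases {pct(cases):.1f}% vs controls {pct(controls):.1f}%")
    top = fig1.sort_values("case_pct", ascending=False).head(3)
    print("most frequent conditions in cases:")
    for r in top.itertuples(index=False):
        print(f"  {r.condition}: {r.case_pct}% vs {r.control_pct}% in controls")


if __name__ == "__main__":
    main()
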