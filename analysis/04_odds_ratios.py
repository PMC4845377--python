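#!/usr/bin/env python
"""Per-condition adjusted odds ratios by age stratum (conditional logistic).

For each age stratum (<=45, 46-60, >60), every condition present in at
least 1% of stratum subjects gets a conditional-logistic model on the
matched pairs, adjusted for educational attainment and obesity.
"""

from pathlib import Path

import pandas as pd

from mdd_comorbidity import load_catalog
from mdd_comorbidity.ascertainment import AnalysisRow
from mdd_comorbidity.stats_clogit import per_condition_analysis

SCRATCH = Path("scratch/study")
RESULTS = Path("results/study")


def load_rows() -> list[AnalysisRow]:
    catalog = load_catalog()
    df = pd.read_csv(SCRATCH / "analysis_table.csv")
    return [
        AnalysisRow(
            patient_id=str(r["patient_id"]), pair_id=str(r["pair_id"]),
            outcome=int(r["outcome"]), stratum=str(r["stratum"]),
            conditions={c: bool(r[c]) for c in catalog.condition_ids},
            obesity=bool(r["obesity"]), education=str(r["education"]), sex=str(r["sex"]),
        )
        for _, r in df.iterrows()
    ]


def main() -> None:
    catalog = load_catalog()
    rows = load_rows()
    all_results, all_skipped = [], []
    for stratum in ("le45", "46to60", "gt60"):
        results, skipped = per_condition_analysis(rows, stratum, catalog)
        all_results.extend(results)
        all_skipped.extend({"stratum": stratum, **s} for s in skipped)
        n_sig = sum(r["converged"] and r["ci_low"] > 1.0 for r in results)
        print(f"{stratum}: {len(results)} conditions >=1% prevalence, "
              f"{n_sig} significantly associated (CI excludes 1)")
    RESULTS.mkdir(parents=True, exist_ok=True)
    ors = pd.DataFrame(all_results)
    ors.to_csv(RESULTS / "or_results.csv", index=False)
    pd.DataFrame(all_skipped).to_csv(RESULTS / "or_not_analyzed.csv", index=False)
    strongest = ors[ors.converged].sort_values("or", ascending=False).head(3)
    print("strongest adjusted associations:")
    for r in strongest.itertuples(index=False):
        print(f"  {r.stratum} {r.condition_id}: OR {r[2]:.2f} "
              f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")


if __name__ == "__main__":
    main()
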