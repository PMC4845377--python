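#!/usr/bin/env python
"""Simulate the synthetic primary-care cohort and write its EHR tables.

Generates 20,000 patients observed 1994-2013 with the default planted
effect structure (diabetes and cardiovascular conditions carry the largest
conditional log-odds for depression onset; eye conditions are null) and
writes the flat event tables that the rest of the analysis consumes.
"""

from pathlib import Path

from mdd_comorbidity import SimulationConfig, generate_population, write_tables

SEED = 42
OUT = Path("scratch/study/tables")


def main() -> None:
    cfg = SimulationConfig(n_patients=20000, seed=SEED)
    records, truth = generate_population(cfg)
    manifest = write_tables(records, truth, OUT)
    n_mdd = sum(t.true_mdd_onset is not None for t in truth)
    n_events = sum(len(r.diagnosis_events) + len(r.visit_events) for r in records)
    print(f"simulated {len(records)} patients ({n_events} coded events)")
    print(f"true depression onsets: {n_mdd} ({100 * n_mdd / len(records):.1f}%)")
    print(f"wrote {len(manifest)} tables to {OUT}")


if __name__ == "__main__":
    main()
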