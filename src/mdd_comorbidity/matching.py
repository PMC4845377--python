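"""1:1 case-control matching on birth year (+/-2), sex and index-year visit.

Matching is greedy and sequential: cases are processed in ascending
index-date order (ties broken by patient id), and each case takes the
still-unused control candidate with the smallest absolute birth-year
difference; remaining ties are broken by a seeded random priority assigned
to every candidate up front, so the pairing is fully reproducible.  The
control's index date is the first outpatient visit in the calendar year of
the case's index date.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from .phenotyping import CaseCall
from .synthetic_ehr import PatientRecord

STRATA = ("le45", "46to60", "gt60")


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    case_index: date
    control_index: date
    stratum: str


def assign_stratum(birth_year: int, index_date: date) -> str:
    """Age stratum at index: <=45, 46-60, >60 (age = index year - birth year)."""
    age = index_date.year - birth_year
    if age < 0:
        raise ValueError(f"negative age: born {birth_year}, index {index_date}")
    if age <= 45:
        return "le45"
    if age <= 60:
        return "46to60"
    return "gt60"


def _first_outpatient_visit_by_year(record: PatientRecord) -> dict[int, date]:
    first: dict[int, date] = {}
    for d, vtype in record.visit_events:  # visits are date-sorted
        if vtype == "outpatient" and d.year not in first:
            first[d.year] = d
    return first


def match_cohort(
    cases: list[CaseCall],
    pool: list[PatientRecord],
    records: dict[str, PatientRecord],
    seed: int,
) -> tuple[list[MatchedPair], list[str]]:
    """Greedily pair each incident case with one control, without replacement.

    ``pool`` holds the control-eligible patients (disjoint from the cases);
    ``records`` maps patient id -> record for the cases.  Returns the matched
    pairs and the ids of cases left unmatched (reported, never dropped
    silently).
    """
    case_ids = {c.patient_id for c in cases}
    if any(p.patient_id in case_ids for p in pool):
        raise ValueError("control pool must be disjoint from the cases")

    rng = np.random.default_rng(seed)
    priority = {p.patient_id: int(r) for p, r in zip(pool, rng.permutation(len(pool)))}

    # Index candidates by (sex, birth_year); precompute visit years.
    by_key: dict[tuple[str, int], list[PatientRecord]] = {}
    visit_years: dict[str, dict[int, date]] = {}
    for p in pool:
        by_key.setdefault((p.sex, p.birth_year), []).append(p)
        visit_years[p.patient_id] = _first_outpatient_visit_by_year(p)

    used: set[str] = set()
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    ordered = sorted(
        (c for c in cases if c.status == "incident_case"),
        key=lambda c: (c.index_date, c.patient_id),
    )
    for case in ordered:
        rec = records[case.patient_id]
        year = case.index_date.year
        best = None  # (|dy|, priority, candidate)
        for dy in (-2, -1, 0, 1, 2):
            for cand in by_key.get((rec.sex, rec.birth_year + dy), ()):
                if cand.patient_id in used:
                    continue
                if year not in visit_years[cand.patient_id]:
                    continue
                key = (abs(dy), priority[cand.patient_id])
                if best is None or key < best[0]:
                    best = (key, cand)
        if best is None:
            unmatched.append(case.patient_id)
            continue
        cand = best[1]
        used.add(cand.patient_id)
        pairs.append(
            MatchedPair(
                case_id=case.patient_id,
                control_id=cand.patient_id,
                case_index=case.index_date,
                control_index=visit_years[cand.patient_id][year],
                stratum=assign_stratum(rec.birth_year, case.index_date),
            )
        )
    return pairs, unmatched


def validate_pairs(
    pairs: list[MatchedPair],
    records: dict[str, PatientRecord],
) -> list[str]:
    """Independent post-hoc validator; returns a list of violation messages."""
    problems = []
    seen_cases: set[str] = set()
    seen_controls: set[str] = set()
    for pair in pairs:
        case, ctrl = records[pair.case_id], records[pair.control_id]
        if pair.case_id in seen_cases:
            problems.append(f"case {pair.case_id} matched twice")
        if pair.control_id in seen_controls:
            problems.append(f"control {pair.control_id} matched twice")
        seen_cases.add(pair.case_id)
        seen_controls.add(pair.control_id)
        if abs(case.birth_year - ctrl.birth_year) > 2:
            problems.append(f"pair {pair.case_id}: birth-year gap > 2")
        if case.sex != ctrl.sex:
            problems.append(f"pair {pair.case_id}: sex mismatch")
        year_visits = [
            d for d, t in ctrl.visit_events if t == "outpatient" and d.year == pair.case_index.year
        ]
        if not year_visits:
            problems.append(f"pair {pair.case_id}: control has no index-year outpatient visit")
        elif pair.control_index != min(year_visits):
            problems.append(f"pair {pair.case_id}: control index is not the first visit")
        if pair.stratum != assign_stratum(case.birth_year, pair.case_index):
            problems.append(f"pair {pair.case_id}: wrong stratum")
    return problems
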