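"""Rule-based EHR phenotyping of incident major depressive disorder.

A patient is a case when at least two of four criteria are met:

* ``ICD2``  — two MDD diagnosis codes (prefixes 296.2/296.3) on distinct days;
* ``RX``    — an antidepressant prescription (NDF-RT classes C8870/C8872/C8874/C8876);
* ``NOTE``  — a clinical-note mention of an MDD diagnosis;
* ``PHQ9``  — a PHQ-9 score of 15 or higher.

The index date is the first day on which two criteria are simultaneously
satisfied, i.e. the second-smallest of the per-criterion first-satisfied
dates.  Patients ever coded for bipolar disorder (296.1x, 296.4x-296.9x),
dementia/delirium (290.x) or psychotic disorders (295.x, 298.x) are excluded.
Control-eligible patients additionally carry no MDD-related record of any of
the four criterion event types.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .catalog import PhenotypeCodes, code_matches
from .synthetic_ehr import PatientRecord

CRITERIA = ("ICD2", "RX", "NOTE", "PHQ9")
STATUSES = ("incident_case", "prevalent_case", "excluded", "control_eligible", "ineligible")


@dataclass(frozen=True)
class CriterionProfile:
    """First date each phenotype criterion is satisfied (None if never)."""

    first_satisfied: dict  # criterion -> date | None

    def dates(self) -> list[date]:
        return sorted(d for d in self.first_satisfied.values() if d is not None)


@dataclass(frozen=True)
class CaseCall:
    patient_id: str
    status: str
    index_date: date | None = None
    criteria_met: frozenset = frozenset()
    exclusion_reason: str | None = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "excluded" and not self.exclusion_reason:
            raise ValueError("excluded status requires an exclusion_reason")


def evaluate_criteria(patient: PatientRecord, codes: PhenotypeCodes | None = None) -> CriterionProfile:
    """Compute first-satisfied dates for the four MDD phenotype criteria.

    ICD2 is dated at the second qualifying code on a *distinct* day
    (same-day duplicate billing rows count once); the other criteria at
    their first qualifying event.
    """
    codes = codes or PhenotypeCodes()
    first: dict[str, date | None] = dict.fromkeys(CRITERIA)

    mdd_days: list[date] = []
    seen: set[date] = set()
    for d, icd, _setting in patient.diagnosis_events:
        if d not in seen and code_matches(icd, codes.mdd_icd9_prefixes):
            seen.add(d)
            mdd_days.append(d)
            if len(mdd_days) == 2:
                first["ICD2"] = d
                break

    for d, cls in patient.med_events:
        if cls.strip().upper() in codes.antidepressant_classes:
            first["RX"] = d
            break
    for d, mention in patient.note_events:
        if mention:
            first["NOTE"] = d
            break
    for d, score in patient.phq9_events:
        if score >= codes.phq9_threshold:
            first["PHQ9"] = d
            break
    return CriterionProfile(first_satisfied=first)


def find_index_date(profile: CriterionProfile) -> date | None:
    """First day on which >=2 criteria are satisfied: the 2nd order statistic."""
    dates = profile.dates()
    return dates[1] if len(dates) >= 2 else None


def screen_exclusions(
    patient: PatientRecord,
    role: str,
    codes: PhenotypeCodes | None = None,
    strict_control_screen: bool = True,
) -> tuple[bool, str | None]:
    """Apply the diagnostic exclusion screen (cases) or the full control screen.

    Cases are excluded for any bipolar/dementia/psychotic code at any time.
    Control candidates are additionally excluded when *any* MDD-related
    record exists — a single event of any of the four criterion types
    (``strict_control_screen=False`` relaxes that to requiring a full
    phenotype match).
    """
    if role not in ("case", "control"):
        raise ValueError(f"unknown role {role!r}")
    codes = codes or PhenotypeCodes()

    for group, prefixes in codes.exclusion_prefixes.items():
        for _d, icd, _setting in patient.diagnosis_events:
            if code_matches(icd, prefixes):
                return True, group

    if role == "control":
        profile = evaluate_criteria(patient, codes)
        if strict_control_screen:
            has_mdd_code = any(
                code_matches(icd, codes.mdd_icd9_prefixes)
                for _d, icd, _s in patient.diagnosis_events
            )
            if (
                has_mdd_code
                or profile.first_satisfied["RX"] is not None
                or profile.first_satisfied["NOTE"] is not None
                or profile.first_satisfied["PHQ9"] is not None
            ):
                return True, "mdd_related_record"
        elif find_index_date(profile) is not None:
            return True, "mdd_related_record"
    return False, None


def _earliest_mdd_record(patient: PatientRecord, codes: PhenotypeCodes,
                         profile: CriterionProfile) -> date:
    """Earliest MDD-related event of any criterion type (single events count)."""
    candidates = [d for d in profile.first_satisfied.values() if d is not None]
    candidates += [
        d for d, icd, _s in patient.diagnosis_events
        if code_matches(icd, codes.mdd_icd9_prefixes)
    ]
    return min(candidates)


def classify_cohort(
    records: list[PatientRecord],
    study_window: tuple[date, date],
    codes: PhenotypeCodes | None = None,
    strict_control_screen: bool = True,
    strict_prevalent_screen: bool = False,
) -> list[CaseCall]:
    """Assign each patient exactly one cohort status.

    * ``excluded``         — carries a diagnostic exclusion code;
    * ``incident_case``    — index date inside the study window;
    * ``prevalent_case``   — index date before the window start;
    * ``control_eligible`` — passes the control screen and has >=1 outpatient visit;
    * ``ineligible``       — everything else (e.g. a lone MDD-related record,
      an index date after the window, or no outpatient visits).

    By default a case is prevalent only when its index date (first full
    algorithm satisfaction) precedes the window; ``strict_prevalent_screen``
    additionally demotes cases with *any* single MDD-related record before
    the window start.
    """
    codes = codes or PhenotypeCodes()
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_ids")
    w0, w1 = study_window

    calls = []
    for rec in records:
        excluded, reason = screen_exclusions(rec, "case", codes)
        if excluded:
            calls.append(CaseCall(rec.patient_id, "excluded", exclusion_reason=reason))
            continue
        profile = evaluate_criteria(rec, codes)
        index = find_index_date(profile)
        met = frozenset(
            c for c, d in profile.first_satisfied.items() if d is not None and index is not None and d <= index
        )
        if index is not None and w0 <= index <= w1:
            if strict_prevalent_screen and _earliest_mdd_record(rec, codes, profile) < w0:
                calls.append(CaseCall(rec.patient_id, "prevalent_case", index_date=index,
                                      criteria_met=met))
                continue
            calls.append(CaseCall(rec.patient_id, "incident_case", index_date=index, criteria_met=met))
            continue
        if index is not None and index < w0:
            calls.append(CaseCall(rec.patient_id, "prevalent_case", index_date=index, criteria_met=met))
            continue
        ctrl_excluded, _ = screen_exclusions(rec, "control", codes, strict_control_screen)
        has_outpatient = any(t == "outpatient" for _d, t in rec.visit_events)
        if not ctrl_excluded and has_outpatient:
            calls.append(CaseCall(rec.patient_id, "control_eligible"))
        else:
            calls.append(CaseCall(rec.patient_id, "ineligible"))
    return calls
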