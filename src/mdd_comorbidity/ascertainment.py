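"""Comorbidity ascertainment and the per-subject analysis table.

A chronic condition is present when the subject has at least two diagnosis
codes mapping to it within the 5-year lookback window, with the earliest and
latest such codes more than 30 days apart.  The lookback window is half-open,
``[index - 5 years, index)``: codes on the index date itself do not count,
because the conditions must precede the depression diagnosis.  Obesity is a
single-code flag over the same window (the two-code rule applies to the 24
chronic-condition categories).  Inpatient and outpatient codes both count.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .catalog import ConditionCatalog, PhenotypeCodes, code_matches, load_catalog
from .matching import MatchedPair
from .synthetic_ehr import EDUCATION_LEVELS, PatientRecord


@dataclass(frozen=True)
class AnalysisRow:
    patient_id: str
    pair_id: str
    outcome: int          # 1 case, 0 control
    stratum: str
    conditions: dict      # condition_id -> bool (after sex-restriction masking)
    obesity: bool
    education: str
    sex: str

    @property
    def burden(self) -> int:
        return sum(self.conditions.values())


def years_before(d: date, years: int) -> date:
    """Calendar-years-earlier date (Feb 29 maps to Feb 28)."""
    try:
        return d.replace(year=d.year - years)
    except ValueError:
        return d.replace(year=d.year - years, day=28)


def ascertain_condition(
    events,
    prefixes,
    index_date: date,
    lookback_years: int = 5,
) -> bool:
    """Two codes, >30 days apart, inside [index - lookback, index)."""
    lo = years_before(index_date, lookback_years)
    dates = [d for d, code, _setting in events if lo <= d < index_date and code_matches(code, prefixes)]
    if len(dates) < 2:
        return False
    return (max(dates) - min(dates)).days > 30


def ascertain_obesity(
    events,
    index_date: date,
    codes: PhenotypeCodes | None = None,
    lookback_years: int = 5,
    two_code_rule: bool = False,
) -> bool:
    """Obesity flag: >=1 listed code in the lookback window (single-code rule)."""
    codes = codes or PhenotypeCodes()
    if two_code_rule:
        return ascertain_condition(events, codes.obesity_codes, index_date, lookback_years)
    lo = years_before(index_date, lookback_years)
    return any(
        lo <= d < index_date and code_matches(icd, codes.obesity_codes)
        for d, icd, _setting in events
    )


def subject_flags(
    record: PatientRecord,
    index_date: date,
    catalog: ConditionCatalog,
    lookback_years: int = 5,
) -> dict[str, bool]:
    """All 24 condition flags for one subject, sex-restriction masked."""
    return {
        entry.condition_id: (
            entry.applies_to(record.sex)
            and ascertain_condition(record.diagnosis_events, entry.icd9_prefixes, index_date, lookback_years)
        )
        for entry in catalog
    }


def build_analysis_table(
    pairs: list[MatchedPair],
    records: dict[str, PatientRecord],
    catalog: ConditionCatalog | None = None,
    codes: PhenotypeCodes | None = None,
    lookback_years: int = 5,
) -> list[AnalysisRow]:
    """Two rows per matched pair; each subject ascertained at their OWN index date."""
    catalog = catalog or load_catalog()
    codes = codes or PhenotypeCodes()
    rows: list[AnalysisRow] = []
    for pair in pairs:
        for pid, index, outcome in (
            (pair.case_id, pair.case_index, 1),
            (pair.control_id, pair.control_index, 0),
        ):
            if pid not in records:
                raise KeyError(f"patient {pid} missing from records")
            rec = records[pid]
            rows.append(
                AnalysisRow(
                    patient_id=pid,
                    pair_id=pair.case_id,
                    outcome=outcome,
                    stratum=pair.stratum,
                    conditions=subject_flags(rec, index, catalog, lookback_years),
                    obesity=ascertain_obesity(rec.diagnosis_events, index, codes, lookback_years),
                    education=rec.education,
                    sex=rec.sex,
                )
            )
    return rows


def prevalence_filter(
    rows: list[AnalysisRow],
    condition_ids: list[str],
    threshold: float = 0.01,
) -> list[str]:
    """Condition ids flagged in at least ``threshold`` of subjects (cases+controls).

    ``rows`` should already be restricted to a single age stratum.
    """
    if not rows:
        raise ValueError("empty stratum")
    n = len(rows)
    return [
        cid
        for cid in condition_ids
        if sum(r.conditions[cid] for r in rows) / n >= threshold
    ]


def rows_to_frame(rows: list[AnalysisRow]) -> pd.DataFrame:
    """Flatten analysis rows into a DataFrame (one column per condition flag)."""
    if not rows:
        return pd.DataFrame()
    condition_ids = list(rows[0].conditions)
    data = {
        "patient_id": [r.patient_id for r in rows],
        "pair_id": [r.pair_id for r in rows],
        "outcome": [r.outcome for r in rows],
        "stratum": [r.stratum for r in rows],
        "sex": [r.sex for r in rows],
        "education": [r.education for r in rows],
        "obesity": [int(r.obesity) for r in rows],
        "burden": [r.burden for r in rows],
    }
    for cid in condition_ids:
        data[cid] = [int(r.conditions[cid]) for r in rows]
    df = pd.DataFrame(data)
    assert set(df["education"]) <= set(EDUCATION_LEVELS)
    return df
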