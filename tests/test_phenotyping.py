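"""Case-finding algorithm: criterion dates, index minimality, exclusions."""

from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from mdd_comorbidity import (
    CriterionProfile,
    PatientRecord,
    classify_cohort,
    evaluate_criteria,
    find_index_date,
    screen_exclusions,
)
from mdd_comorbidity.catalog import PhenotypeCodes, code_matches


def _patient(pid="P1", **streams):
    rec = PatientRecord(pid, 1960, "F", "White", "college")
    for name, events in streams.items():
        getattr(rec, name).extend(sorted(events))
    return rec


# ---------------------------------------------------------------------------
# evaluate_criteria
# ---------------------------------------------------------------------------

def test_criterion_first_satisfied_dates():
    rec = _patient(
        diagnosis_events=[
            (date(2005, 3, 1), "296.21", "outpatient"),
            (date(2005, 6, 15), "296.30", "outpatient"),
        ],
        med_events=[(date(2005, 4, 1), "C8870")],
    )
    prof = evaluate_criteria(rec)
    assert prof.first_satisfied == {
        "ICD2": date(2005, 6, 15),
        "RX": date(2005, 4, 1),
        "NOTE": None,
        "PHQ9": None,
    }


def test_single_mdd_code_leaves_icd2_unsatisfied():
    rec = _patient(diagnosis_events=[(date(2005, 3, 1), "296.2", "outpatient")])
    assert evaluate_criteria(rec).first_satisfied["ICD2"] is None


def test_same_day_duplicate_codes_count_once():
    rec = _patient(
        diagnosis_events=[
            (date(2005, 3, 1), "296.21", "outpatient"),
            (date(2005, 3, 1), "296.22", "inpatient"),
        ]
    )
    assert evaluate_criteria(rec).first_satisfied["ICD2"] is None


def test_phq9_threshold_boundary():
    below = _patient(phq9_events=[(date(2005, 1, 1), 14)])
    at = _patient(phq9_events=[(date(2005, 1, 1), 15)])
    assert evaluate_criteria(below).first_satisfied["PHQ9"] is None
    assert evaluate_criteria(at).first_satisfied["PHQ9"] == date(2005, 1, 1)


# ---------------------------------------------------------------------------
# find_index_date
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dates, expected",
    [
        ({"ICD2": date(2005, 6, 15), "RX": date(2005, 4, 1), "NOTE": None, "PHQ9": None},
         date(2005, 6, 15)),
        ({"ICD2": None, "RX": date(2005, 4, 1), "NOTE": None, "PHQ9": None}, None),
        ({"ICD2": date(2005, 4, 1), "RX": date(2005, 4, 1), "NOTE": None, "PHQ9": None},
         date(2005, 4, 1)),
        ({"ICD2": None, "RX": None, "NOTE": None, "PHQ9": None}, None),
    ],
)
def test_index_is_second_order_statistic(dates, expected):
    assert find_index_date(CriterionProfile(first_satisfied=dates)) == expected


@given(
    st.lists(
        st.one_of(st.none(), st.dates(date(2000, 1, 1), date(2013, 12, 31))),
        min_size=4, max_size=4,
    )
)
def test_index_matches_daily_scan(dates):
    """Brute-force day-by-day scan agrees with the order-statistic shortcut."""
    profile = CriterionProfile(first_satisfied=dict(zip(("ICD2", "RX", "NOTE", "PHQ9"), dates)))
    known = sorted(d for d in dates if d is not None)
    scan = None
    for day in known:  # criteria counts only change on criterion dates
        if sum(1 for d in known if d <= day) >= 2:
            scan = day
            break
    assert find_index_date(profile) == scan


# ---------------------------------------------------------------------------
# screen_exclusions
# ---------------------------------------------------------------------------

def test_bipolar_code_excludes_case_at_any_time():
    rec = _patient(diagnosis_events=[(date(1997, 2, 1), "296.40", "inpatient")])
    assert screen_exclusions(rec, "case") == (True, "bipolar")


def test_mdd_code_is_not_an_exclusion_code():
    rec = _patient(diagnosis_events=[(date(2005, 1, 1), "296.30", "outpatient")])
    assert screen_exclusions(rec, "case") == (False, None)


def test_lone_antidepressant_excludes_control_candidate():
    rec = _patient(med_events=[(date(2003, 5, 1), "C8876")])
    assert screen_exclusions(rec, "control") == (True, "mdd_related_record")
    # the strict screen is configurable off
    assert screen_exclusions(rec, "control", strict_control_screen=False) == (False, None)


def test_unknown_role_rejected():
    with pytest.raises(ValueError):
        screen_exclusions(_patient(), "bystander")


# ---------------------------------------------------------------------------
# classify_cohort
# ---------------------------------------------------------------------------

WINDOW = (date(2000, 1, 1), date(2013, 12, 31))


def _case_events(d0):
    return dict(
        diagnosis_events=[(d0, "296.21", "outpatient"),
                          (d0 + timedelta(days=30), "296.30", "outpatient")],
        med_events=[(d0 + timedelta(days=10), "C8870")],
        visit_events=[(d0, "outpatient")],
    )


def test_index_before_window_is_prevalent():
    rec = _patient(**_case_events(date(1998, 4, 1)))
    (call,) = classify_cohort([rec], WINDOW)
    assert call.status == "prevalent_case"
    # RX first (Apr 11), second criterion is the 2nd ICD code (Apr 1 + 30d)
    assert call.index_date == date(1998, 5, 1)


def test_clean_patient_with_visit_is_control_eligible():
    rec = _patient(visit_events=[(date(2004, 3, 3), "outpatient")])
    (call,) = classify_cohort([rec], WINDOW)
    assert call.status == "control_eligible"


def test_case_with_psychotic_code_is_excluded():
    rec = _patient(**_case_events(date(2004, 4, 1)))
    rec.diagnosis_events.append((date(2010, 1, 1), "295.3", "inpatient"))
    rec.diagnosis_events.sort()
    (call,) = classify_cohort([rec], WINDOW)
    assert call.status == "excluded"
    assert call.exclusion_reason == "psychotic"


def test_duplicate_patient_ids_rejected():
    with pytest.raises(ValueError):
        classify_cohort([_patient(), _patient()], WINDOW)


def test_statuses_partition_cohort(small_cohort):
    cfg, records, _ = small_cohort
    calls = classify_cohort(records, cfg.study_window)
    assert len(calls) == len(records)
    assert {c.patient_id for c in calls} == {r.patient_id for r in records}
    for c in calls:
        if c.status == "incident_case":
            assert cfg.study_window[0] <= c.index_date <= cfg.study_window[1]
            assert len(c.criteria_met) >= 2


def _brute_force_index(rec, codes):
    """Day-by-day scan over the raw event history (independent of the module path)."""
    days = sorted(
        {d for d, *_ in rec.diagnosis_events}
        | {d for d, _ in rec.med_events}
        | {d for d, _ in rec.phq9_events}
        | {d for d, _ in rec.note_events}
    )
    for day in days:
        n = 0
        mdd_days = {d for d, icd, _s in rec.diagnosis_events
                    if d <= day and code_matches(icd, codes.mdd_icd9_prefixes)}
        n += len(mdd_days) >= 2
        n += any(d <= day and c.upper() in codes.antidepressant_classes for d, c in rec.med_events)
        n += any(d <= day and m for d, m in rec.note_events)
        n += any(d <= day and s >= codes.phq9_threshold for d, s in rec.phq9_events)
        if n >= 2:
            return day
    return None


def test_index_dates_match_brute_force_scan(small_cohort):
    """Oracle equivalence on 500 synthetic patients."""
    _, records, _ = small_cohort
    codes = PhenotypeCodes()
    checked = 0
    for rec in records:
        expected = _brute_force_index(rec, codes)
        got = find_index_date(evaluate_criteria(rec, codes))
        assert got == expected, rec.patient_id
        checked += expected is not None
    assert checked > 20  # the cohort must actually exercise the algorithm


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_adding_events_never_delays_index(data):
    """Monotonicity: extra events can only move the index date earlier."""
    d0 = data.draw(st.dates(date(2001, 1, 1), date(2012, 1, 1)))
    rec = _patient(**_case_events(d0))
    base_index = find_index_date(evaluate_criteria(rec))
    extra_day = data.draw(st.dates(date(2000, 1, 1), date(2013, 12, 31)))
    kind = data.draw(st.sampled_from(["icd", "rx", "note", "phq9"]))
    if kind == "icd":
        rec.diagnosis_events.append((extra_day, "296.25", "outpatient"))
        rec.diagnosis_events.sort()
    elif kind == "rx":
        rec.med_events.append((extra_day, "C8872"))
        rec.med_events.sort()
    elif kind == "note":
        rec.note_events.append((extra_day, True))
        rec.note_events.sort()
    else:
        rec.phq9_events.append((extra_day, 20))
        rec.phq9_events.sort()
    new_index = find_index_date(evaluate_criteria(rec))
    assert new_index is not None and new_index <= base_index


def test_full_sensitivity_recovers_every_true_onset_in_window(catalog):
    """With no under-coding, every in-window true onset is called incident
    unless the record carries exclusion codes."""
    from mdd_comorbidity import SimulationConfig, generate_population

    cfg = SimulationConfig(n_patients=800, seed=99, undercoding_prob=0.0)
    records, truth = generate_population(cfg, catalog)
    calls = {c.patient_id: c for c in classify_cohort(records, cfg.study_window)}
    w0, w1 = cfg.study_window
    missed = []
    for t in truth:
        if t.true_mdd_onset is None or not (w0 <= t.true_mdd_onset <= w1):
            continue
        call = calls[t.patient_id]
        if call.status not in ("incident_case", "excluded", "prevalent_case"):
            missed.append(t.patient_id)
    assert missed == []


def test_strict_prevalent_screen_demotes_pre_window_evidence():
    """A single pre-window MDD record makes an in-window case prevalent
    under the strict mode, but not under the default index-based rule."""
    rec = _patient(**_case_events(date(2004, 4, 1)))
    rec.med_events.insert(0, (date(1999, 6, 1), "C8870"))
    (default_call,) = classify_cohort([rec], WINDOW)
    (strict_call,) = classify_cohort([rec], WINDOW, strict_prevalent_screen=True)
    assert default_call.status == "incident_case"
    assert strict_call.status == "prevalent_case"
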