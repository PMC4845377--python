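"""Synthetic longitudinal EHR generator with known ground truth.

No real patient data can accompany this package, so every downstream stage
(phenotyping, matching, ascertainment, regression, boosting) is exercised on
synthetic event streams generated here.  The generator emulates a primary-care
cohort observed over a calendar horizon:

* chronic-condition onsets follow per-year (optionally age-banded) incidence
  rates and are absorbing — once a condition starts, coded encounters for it
  recur at a configurable rate, so the two-code/30-day ascertainment rule is
  exercisable;
* incident depression follows a discrete-time (per-year) hazard on the
  log-odds scale: logit(p_t) = logit(base) + sum_k beta_k * active_k(t)
  + covariate terms, where active_k(t) indicates condition k started in an
  earlier year, so planted conditional effects are recoverable from the
  ground-truth table;
* on a true depression onset the record receives the evidence the
  case-finding algorithm looks for (two 296.2x/296.3x codes 1-180 days apart,
  an antidepressant prescription, and with probability 0.5 each a clinical
  note mention and a PHQ-9 score >= 15), unless the patient is "under-coded",
  emulating depression that never reaches the record.

All randomness flows from a single integer seed through per-patient
``numpy.random.SeedSequence`` children, so output is byte-for-byte
reproducible and independent of patient count changes elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import ConditionCatalog, PhenotypeCodes, load_catalog

EDUCATION_LEVELS = (
    "high_school_or_less",
    "some_college",
    "college",
    "post_graduate",
    "unknown",
)

RACE_LEVELS = ("White", "Black", "Asian", "Other")
_RACE_PROBS = (0.90, 0.03, 0.04, 0.03)

# Annual incidence of a first coded encounter per condition.  Values are
# either a scalar per-year probability or age bands [age_lo, age_hi, rate].
DEFAULT_CONDITION_RATES: dict[str, object] = {
    "hypothyroidism": 0.0015,
    "acute_mi": [[18, 45, 0.0001], [46, 60, 0.0006], [61, 120, 0.0015]],
    "anemia": 0.0018,
    "asthma": 0.0022,
    "atrial_fibrillation": [[18, 45, 0.0001], [46, 60, 0.0008], [61, 120, 0.003]],
    "bph": [[18, 45, 0.0002], [46, 60, 0.002], [61, 120, 0.006]],
    "breast_cancer": [[18, 45, 0.0002], [46, 120, 0.0012]],
    "cataract": [[18, 45, 0.0002], [46, 60, 0.0015], [61, 120, 0.007]],
    "chronic_kidney_disease": [[18, 45, 0.0002], [46, 120, 0.001]],
    "copd": [[18, 45, 0.0002], [46, 120, 0.002]],
    "colorectal_cancer": [[18, 45, 0.0001], [46, 120, 0.0007]],
    "diabetes": [[18, 45, 0.0009], [46, 60, 0.003], [61, 120, 0.004]],
    "endometrial_cancer": [[18, 45, 0.0001], [46, 120, 0.0005]],
    "glaucoma": [[18, 45, 0.0002], [46, 120, 0.0018]],
    "heart_failure": [[18, 45, 0.0001], [46, 60, 0.0008], [61, 120, 0.004]],
    "hip_fracture": [[18, 60, 0.0001], [61, 120, 0.0012]],
    "hyperlipidemia": [[18, 45, 0.0018], [46, 60, 0.006], [61, 120, 0.007]],
    "hypertension": [[18, 45, 0.0015], [46, 60, 0.0055], [61, 120, 0.008]],
    "ischemic_heart_disease": [[18, 45, 0.0002], [46, 60, 0.0025], [61, 120, 0.005]],
    "lung_cancer": [[18, 45, 0.00005], [46, 120, 0.0005]],
    "osteoporosis": [[18, 45, 0.0001], [46, 60, 0.001], [61, 120, 0.004]],
    "prostate_cancer": [[18, 45, 0.0001], [46, 60, 0.001], [61, 120, 0.004]],
    "ra_oa": [[18, 45, 0.0012], [46, 60, 0.006], [61, 120, 0.012]],
    "stroke_tia": [[18, 45, 0.0001], [46, 60, 0.001], [61, 120, 0.004]],
}

# Planted per-condition conditional log-odds effects on depression onset.
# Magnitudes follow the pattern reported for primary-care cohorts: strong
# effects for diabetes and cardiovascular disease, moderate for most somatic
# conditions, null for the eye conditions.
DEFAULT_CONDITION_LOG_OR: dict[str, float] = {
    "hypothyroidism": 0.2,
    "acute_mi": 0.5,
    "anemia": 0.3,
    "asthma": 0.4,
    "atrial_fibrillation": 0.3,
    "bph": 0.15,
    "breast_cancer": 0.3,
    "cataract": 0.0,
    "chronic_kidney_disease": 0.4,
    "copd": 0.4,
    "colorectal_cancer": 0.3,
    "diabetes": 0.75,
    "endometrial_cancer": 0.3,
    "glaucoma": 0.0,
    "heart_failure": 0.75,
    "hip_fracture": 0.3,
    "hyperlipidemia": 0.2,
    "hypertension": 0.4,
    "ischemic_heart_disease": 0.65,
    "lung_cancer": 0.5,
    "osteoporosis": 0.25,
    "prostate_cancer": 0.2,
    "ra_oa": 0.45,
    "stroke_tia": 0.65,
}

# Log-odds terms for education (aligned with EDUCATION_LEVELS): a gradient
# with lower attainment carrying higher depression risk, "unknown" neutral.
DEFAULT_EDUCATION_LOG_ODDS = (0.30, 0.15, 0.0, -0.15, 0.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults define the study conditions."""

    n_patients: int = 20000
    horizon: tuple[date, date] = (date(1994, 1, 1), date(2013, 12, 31))
    study_window: tuple[date, date] = (date(2000, 1, 1), date(2013, 12, 31))
    condition_base_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_RATES)
    )
    condition_log_or: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_LOG_OR)
    )
    mdd_base_hazard: float = 0.004
    education_probs: tuple = (0.31, 0.31, 0.15, 0.15, 0.08)
    obesity_prob: float = 0.08
    obesity_log_or: float = 0.4
    education_log_odds: tuple = DEFAULT_EDUCATION_LOG_ODDS
    sex_prob_female: float = 0.55
    birth_year_range: tuple[int, int] = (1930, 1985)
    visit_rate: float = 1.8
    condition_code_rate: float = 1.5
    obesity_code_rate: float = 0.3
    mdd_followup_code_rate: float = 0.8
    exclusion_code_rate: float = 0.0015
    background_antidepressant_rate: float = 0.004
    background_phq9_rate: float = 0.05
    background_note_rate: float = 0.10
    undercoding_prob: float = 0.10
    note_mention_prob: float = 0.5
    phq9_high_prob: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.seed is None:
            raise ValueError("seed is required: reproducibility is mandatory")
        for name in (
            "mdd_base_hazard", "obesity_prob", "sex_prob_female",
            "undercoding_prob", "note_mention_prob", "phq9_high_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education_probs must sum to 1")
        if len(self.education_probs) != 5 or len(self.education_log_odds) != 5:
            raise ValueError("education vectors must have 5 entries")
        h0, h1 = self.horizon
        w0, w1 = self.study_window
        if not h0 < h1:
            raise ValueError("horizon start must precede end")
        if not (h0 <= w0 and w1 <= h1):
            raise ValueError("study_window must lie within horizon")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("invalid birth_year_range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("horizon", "study_window"):
            if key in raw:
                raw[key] = tuple(date.fromisoformat(str(d)) for d in raw[key])
        for key in ("education_probs", "education_log_odds", "birth_year_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PatientRecord:
    """Demographics plus date-sorted event streams for one patient."""

    patient_id: str
    birth_year: int
    sex: str
    race: str
    education: str
    diagnosis_events: list = field(default_factory=list)   # (date, icd9, setting)
    med_events: list = field(default_factory=list)         # (date, ndf_rt_class)
    phq9_events: list = field(default_factory=list)        # (date, score)
    note_events: list = field(default_factory=list)        # (date, mdd_mention)
    visit_events: list = field(default_factory=list)       # (date, type)


@dataclass
class GroundTruth:
    patient_id: str
    true_mdd_onset: date | None
    true_conditions: dict  # condition_id -> onset date


def _rate_for_ages(rate_spec, ages: np.ndarray) -> np.ndarray:
    if isinstance(rate_spec, (int, float)):
        return np.full(ages.shape, float(rate_spec))
    out = np.zeros(ages.shape)
    for lo, hi, r in rate_spec:
        out[(ages >= lo) & (ages <= hi)] = float(r)
    return out


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def _random_day_in_year(rng, year: int, lo: date, hi: date) -> date:
    start = max(date(year, 1, 1), lo)
    end = min(date(year, 12, 31), hi)
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _subcoded(rng, prefix: str) -> str:
    # Emit a plausible child code of the prefix (prefix matching makes any
    # trailing digits equivalent for ascertainment).
    if "." not in prefix:
        return f"{prefix}.{rng.integers(0, 10)}"
    if len(prefix.split(".")[1]) < 2:
        return f"{prefix}{rng.integers(0, 10)}"
    return prefix


def _generate_patient(
    child_seed: np.random.SeedSequence,
    pid: str,
    config: SimulationConfig,
    catalog: ConditionCatalog,
    exclusion_prefixes: tuple[str, ...],
) -> tuple[PatientRecord, GroundTruth]:
    rng = np.random.default_rng(child_seed)
    h0, h1 = config.horizon

    birth_year = int(rng.integers(config.birth_year_range[0], config.birth_year_range[1] + 1))
    sex = "F" if rng.random() < config.sex_prob_female else "M"
    race = RACE_LEVELS[rng.choice(len(RACE_LEVELS), p=_RACE_PROBS)]
    edu_idx = int(rng.choice(5, p=np.asarray(config.education_probs, dtype=float)))
    education = EDUCATION_LEVELS[edu_idx]
    obese = rng.random() < config.obesity_prob

    record = PatientRecord(pid, birth_year, sex, race, education)
    truth = GroundTruth(pid, None, {})

    start_year = max(h0.year, birth_year + 18)
    end_year = h1.year
    if start_year > end_year:  # never an adult inside the horizon
        return record, truth
    years = np.arange(start_year, end_year + 1)
    ages = years - birth_year
    n_years = len(years)

    # --- condition onsets (absorbing) -------------------------------------
    onset_year: dict[str, int] = {}
    for entry in catalog:
        if not entry.applies_to(sex):
            continue
        rates = _rate_for_ages(config.condition_base_rates.get(entry.condition_id, 0.0), ages)
        hits = np.nonzero(rng.random(n_years) < rates)[0]
        if hits.size:
            y = int(years[hits[0]])
            onset_year[entry.condition_id] = y
            truth.true_conditions[entry.condition_id] = _random_day_in_year(rng, y, h0, h1)

    # --- depression onset: per-year log-odds hazard -----------------------
    eta0 = (
        _logit(config.mdd_base_hazard)
        + (config.obesity_log_or if obese else 0.0)
        + config.education_log_odds[edu_idx]
    )
    eta = np.full(n_years, eta0)
    for cond, oy in onset_year.items():
        beta = float(config.condition_log_or.get(cond, 0.0))
        if beta:
            eta[years > oy] += beta
    p_year = 1.0 / (1.0 + np.exp(-eta))
    mdd_hits = np.nonzero(rng.random(n_years) < p_year)[0]
    mdd_onset = None
    if mdd_hits.size:
        mdd_onset = _random_day_in_year(rng, int(years[mdd_hits[0]]), h0, h1)
        truth.true_mdd_onset = mdd_onset
    undercoded = rng.random() < config.undercoding_prob

    # --- coded encounters --------------------------------------------------
    diagnoses = record.diagnosis_events
    for cond, oy in onset_year.items():
        entry = catalog.get(cond)
        d0 = truth.true_conditions[cond]
        diagnoses.append((d0, _subcoded(rng, entry.icd9_prefixes[int(rng.integers(0, len(entry.icd9_prefixes)))]),
                          "inpatient" if rng.random() < 0.15 else "outpatient"))
        for y in range(oy, end_year + 1):
            for _ in range(rng.poisson(config.condition_code_rate)):
                d = _random_day_in_year(rng, y, h0, h1)
                if d < d0:
                    continue
                prefix = entry.icd9_prefixes[int(rng.integers(0, len(entry.icd9_prefixes)))]
                setting = "inpatient" if rng.random() < 0.15 else "outpatient"
                diagnoses.append((d, _subcoded(rng, prefix), setting))

    if obese:
        obesity_codes = ("278.0", "V85.3", "V85.4", "278.00", "278.01")
        for y in years:
            for _ in range(rng.poisson(config.obesity_code_rate)):
                diagnoses.append((_random_day_in_year(rng, int(y), h0, h1),
                                  obesity_codes[int(rng.integers(0, len(obesity_codes)))],
                                  "outpatient"))

    for y in years:
        if rng.random() < config.exclusion_code_rate:
            prefix = exclusion_prefixes[int(rng.integers(0, len(exclusion_prefixes)))]
            diagnoses.append((_random_day_in_year(rng, int(y), h0, h1),
                              _subcoded(rng, prefix), "outpatient"))

    # --- depression evidence ----------------------------------------------
    if mdd_onset is not None and not undercoded:
        def mdd_code() -> str:
            return f"296.{rng.integers(2, 4)}{rng.integers(0, 7)}"

        diagnoses.append((mdd_onset, mdd_code(), "outpatient"))
        second = min(mdd_onset + timedelta(days=int(rng.integers(1, 181))), h1)
        if second != mdd_onset:
            diagnoses.append((second, mdd_code(), "outpatient"))
        for y in range(mdd_onset.year + 1, end_year + 1):
            for _ in range(rng.poisson(config.mdd_followup_code_rate)):
                diagnoses.append((_random_day_in_year(rng, y, mdd_onset, h1),
                                  mdd_code(), "outpatient"))
        rx_class = ("C8870", "C8872", "C8874", "C8876")[int(rng.integers(0, 4))]
        record.med_events.append((min(mdd_onset + timedelta(days=int(rng.integers(0, 61))), h1), rx_class))
        if rng.random() < config.note_mention_prob:
            record.note_events.append((min(mdd_onset + timedelta(days=int(rng.integers(0, 31))), h1), True))
        if rng.random() < config.phq9_high_prob:
            record.phq9_events.append((min(mdd_onset + timedelta(days=int(rng.integers(0, 31))), h1),
                                       int(rng.integers(15, 28))))

    # --- background noise streams ------------------------------------------
    for y in years:
        y = int(y)
        if rng.random() < config.background_antidepressant_rate:
            record.med_events.append((_random_day_in_year(rng, y, h0, h1), "C8876"))
        if rng.random() < config.background_phq9_rate:
            score = int(rng.integers(0, 15)) if rng.random() < 0.95 else int(rng.integers(15, 28))
            record.phq9_events.append((_random_day_in_year(rng, y, h0, h1), score))
        if rng.random() < config.background_note_rate:
            record.note_events.append((_random_day_in_year(rng, y, h0, h1), False))
        for _ in range(rng.poisson(config.visit_rate)):
            vtype = "outpatient" if rng.random() < 0.9 else "inpatient"
            record.visit_events.append((_random_day_in_year(rng, y, h0, h1), vtype))

    record.diagnosis_events.sort()
    record.med_events.sort()
    record.phq9_events.sort()
    record.note_events.sort()
    record.visit_events.sort()
    return record, truth


def generate_population(
    config: SimulationConfig,
    catalog: ConditionCatalog | None = None,
) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Generate the synthetic cohort.

    Returns one :class:`PatientRecord` and one :class:`GroundTruth` per
    patient, in patient-id order.  Identical ``config`` (including seed)
    yields identical output.
    """
    catalog = catalog or load_catalog()
    exclusion_prefixes = tuple(
        p for group in PhenotypeCodes().exclusion_prefixes.values() for p in group
    )
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    width = max(6, len(str(config.n_patients)))
    records, truths = [], []
    for i, child in enumerate(children):
        pid = f"P{i + 1:0{width}d}"
        rec, tr = _generate_patient(child, pid, config, catalog, exclusion_prefixes)
        records.append(rec)
        truths.append(tr)
    return records, truths


# ---------------------------------------------------------------------------
# Flat-table round trip
# ---------------------------------------------------------------------------

TABLE_NAMES = ("patients", "diagnoses", "prescriptions", "phq9", "notes", "visits", "truth")


def write_tables(records, truths, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as flat CSV tables (ISO-8601 dates); returns a manifest."""
    if not records:
        raise ValueError("records must be non-empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    patients = pd.DataFrame(
        [(r.patient_id, r.birth_year, r.sex, r.race, r.education) for r in records],
        columns=["patient_id", "birth_year", "sex", "race", "education"],
    )
    diagnoses = pd.DataFrame(
        [(r.patient_id, d.isoformat(), c, s) for r in records for (d, c, s) in r.diagnosis_events],
        columns=["patient_id", "date", "icd9", "setting"],
    )
    prescriptions = pd.DataFrame(
        [(r.patient_id, d.isoformat(), c) for r in records for (d, c) in r.med_events],
        columns=["patient_id", "date", "ndf_rt_class"],
    )
    phq9 = pd.DataFrame(
        [(r.patient_id, d.isoformat(), s) for r in records for (d, s) in r.phq9_events],
        columns=["patient_id", "date", "score"],
    )
    notes = pd.DataFrame(
        [(r.patient_id, d.isoformat(), int(m)) for r in records for (d, m) in r.note_events],
        columns=["patient_id", "date", "mdd_mention"],
    )
    visits = pd.DataFrame(
        [(r.patient_id, d.isoformat(), t) for r in records for (d, t) in r.visit_events],
        columns=["patient_id", "date", "type"],
    )
    truth = pd.DataFrame(
        [
            (
                t.patient_id,
                t.true_mdd_onset.isoformat() if t.true_mdd_onset else "",
                ";".join(f"{k}:{v.isoformat()}" for k, v in sorted(t.true_conditions.items())),
            )
            for t in truths
        ],
        columns=["patient_id", "true_mdd_onset", "true_conditions"],
    )

    frames = dict(zip(TABLE_NAMES, (patients, diagnoses, prescriptions, phq9, notes, visits, truth)))
    manifest = {}
    for name, frame in frames.items():
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest[name] = path
    return manifest


def read_tables(directory: str | Path) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Read tables written by :func:`write_tables` back into records (exact round trip)."""
    directory = Path(directory)

    def load(name, **kw):
        return pd.read_csv(directory / f"{name}.csv", dtype=str, keep_default_na=False, **kw)

    patients = load("patients")
    streams = {name: load(name) for name in TABLE_NAMES if name not in ("patients", "truth")}
    truth_df = load("truth")

    by_patient: dict[str, dict[str, list]] = {}
    for name, df in streams.items():
        groups: dict[str, list] = {}
        for row in df.itertuples(index=False):
            groups.setdefault(row.patient_id, []).append(row)
        by_patient[name] = groups

    records = []
    for row in patients.itertuples(index=False):
        pid = row.patient_id
        rec = PatientRecord(pid, int(row.birth_year), row.sex, row.race, row.education)
        rec.diagnosis_events = [
            (date.fromisoformat(e.date), e.icd9, e.setting)
            for e in by_patient["diagnoses"].get(pid, [])
        ]
        rec.med_events = [
            (date.fromisoformat(e.date), e.ndf_rt_class)
            for e in by_patient["prescriptions"].get(pid, [])
        ]
        rec.phq9_events = [
            (date.fromisoformat(e.date), int(e.score)) for e in by_patient["phq9"].get(pid, [])
        ]
        rec.note_events = [
            (date.fromisoformat(e.date), bool(int(e.mdd_mention)))
            for e in by_patient["notes"].get(pid, [])
        ]
        rec.visit_events = [
            (date.fromisoformat(e.date), e.type) for e in by_patient["visits"].get(pid, [])
        ]
        records.append(rec)

    truths = []
    for row in truth_df.itertuples(index=False):
        onset = date.fromisoformat(row.true_mdd_onset) if row.true_mdd_onset else None
        conditions = {}
        if row.true_conditions:
            for item in row.true_conditions.split(";"):
                k, v = item.split(":")
                conditions[k] = date.fromisoformat(v)
        truths.append(GroundTruth(row.patient_id, onset, conditions))
    return records, truths


# ---------------------------------------------------------------------------
# Direct simulators for analysis-stage studies (matched pairs, flat strata)
# ---------------------------------------------------------------------------

def simulate_matched_pairs(
    n_pairs: int,
    log_odds: np.ndarray | list[float],
    exposure_probs: np.ndarray | list[float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate 1:1 matched pairs with planted conditional log-odds effects.

    Each pair receives two members with independent Bernoulli covariate
    vectors; which member is the case is drawn from the conditional
    likelihood P(member 1 is the case) = expit(beta . (x1 - x2)), so the
    planted ``log_odds`` are exactly the conditional (within-pair) effects.

    Returns ``(x_case, x_control)`` arrays of shape (n_pairs, p).
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(log_odds, dtype=float)
    probs = np.asarray(exposure_probs, dtype=float)
    x1 = (rng.random((n_pairs, beta.size)) < probs).astype(float)
    x2 = (rng.random((n_pairs, beta.size)) < probs).astype(float)
    eta = (x1 - x2) @ beta
    first_is_case = rng.random(n_pairs) < 1.0 / (1.0 + np.exp(-eta))
    x_case = np.where(first_is_case[:, None], x1, x2)
    x_control = np.where(first_is_case[:, None], x2, x1)
    return x_case, x_control


def simulate_stratum_features(
    n: int,
    log_odds: dict[str, float],
    prevalence: dict[str, float],
    intercept: float,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a flat analysis stratum: Bernoulli features, logistic outcome.

    ``log_odds`` maps feature name -> planted effect; ``prevalence`` maps
    feature name -> Bernoulli probability.  Returns (features, labels).
    """
    rng = np.random.default_rng(seed)
    names = list(prevalence)
    X = pd.DataFrame(
        {name: (rng.random(n) < prevalence[name]).astype(float) for name in names}
    )
    eta = intercept + sum(log_odds.get(name, 0.0) * X[name].to_numpy() for name in names)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y
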