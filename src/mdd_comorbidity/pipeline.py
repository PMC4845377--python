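"""End-to-end orchestration: simulate -> phenotype -> match -> ascertain -> analyze.

Produces the study's result tables on synthetic data:

* ``table1.csv``            — cohort characteristics of cases vs matched controls;
* ``fig1_frequencies.csv``  — per-condition frequencies by case/control status
  (sex-restricted denominators for prostate cancer, BPH, endometrial cancer);
* ``or_results.csv``        — per-stratum adjusted conditional-logistic odds ratios;
* ``ri_results.csv``        — per-stratum relative influences, with and without
  the total-disease-burden covariate;
* ``run_report.json``       — stage counts, seeds and config echo.

The master seed spawns per-stage seeds by fixed offsets (simulate: +0,
match: +1, boosting: +100 + 10*stratum + variant), all recorded in the run
report, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from .ascertainment import build_analysis_table, rows_to_frame
from .catalog import ConditionCatalog, PhenotypeCodes, load_catalog, load_phenotype_codes
from .gbm_ri import GbmConfig, ri_analysis
from .matching import match_cohort, validate_pairs
from .phenotyping import classify_cohort
from .stats_clogit import per_condition_analysis
from .synthetic_ehr import (
    EDUCATION_LEVELS,
    SimulationConfig,
    generate_population,
    read_tables,
    write_tables,
)

SEX_RESTRICTED_DENOMS = {"prostate_cancer": "M", "bph": "M", "endometrial_cancer": "F"}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs; simulation config or input tables."""

    seed: int = 42
    out_dir: str | Path = "results/run"
    simulation: SimulationConfig | None = None
    tables_dir: str | Path | None = None
    study_window: tuple[date, date] = (date(2000, 1, 1), date(2013, 12, 31))
    lookback_years: int = 5
    catalog_path: str | Path | None = None
    phenotype_codes_path: str | Path | None = None
    prevalence_threshold: float = 0.01
    strict_control_screen: bool = True
    gbm: GbmConfig | None = None
    write_input_tables: bool = False

    def __post_init__(self):
        if self.simulation is None and self.tables_dir is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.simulation is not None and self.tables_dir is not None:
            raise ValueError("give either a simulation config or input tables, not both")


@dataclass
class RunReport:
    seed: int
    version: str
    counts: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:  # preserve the failing stage name
                raise StageError(name, err) from err
        return wrapper
    return deco


def _pct(k: int, n: int) -> float:
    return round(100.0 * k / n, 1) if n else float("nan")


def _build_table1(rows, records) -> pd.DataFrame:
    """Cohort characteristics table (counts and percentages, cases vs controls)."""
    out = []
    groups = {"case": [r for r in rows if r.outcome == 1],
              "control": [r for r in rows if r.outcome == 0]}

    def add(section, level, fn):
        rec = {"section": section, "level": level}
        for g, rs in groups.items():
            k, n = fn(rs)
            rec[f"{g}_n"] = k
            rec[f"{g}_pct"] = _pct(k, n)
        out.append(rec)

    for stratum in ("le45", "46to60", "gt60"):
        add("age_at_index", stratum, lambda rs, s=stratum: (sum(r.stratum == s for r in rs), len(rs)))
    add("sex", "female", lambda rs: (sum(r.sex == "F" for r in rs), len(rs)))
    add("race", "white", lambda rs: (sum(records[r.patient_id].race == "White" for r in rs), len(rs)))
    for lvl in EDUCATION_LEVELS:
        add("education", lvl, lambda rs, l=lvl: (sum(r.education == l for r in rs), len(rs)))
    add("obesity", "diagnosed", lambda rs: (sum(r.obesity for r in rs), len(rs)))
    add("n_conditions_1plus", "overall", lambda rs: (sum(r.burden >= 1 for r in rs), len(rs)))
    for stratum in ("le45", "46to60", "gt60"):
        add(
            "n_conditions_1plus",
            stratum,
            lambda rs, s=stratum: (
                sum(r.burden >= 1 for r in rs if r.stratum == s),
                sum(r.stratum == s for r in rs),
            ),
        )
    return pd.DataFrame(out)


def _build_fig1(rows, catalog: ConditionCatalog) -> pd.DataFrame:
    """Per-condition frequencies; sex-restricted conditions use sex-specific denominators."""
    out = []
    for entry in catalog:
        sex = SEX_RESTRICTED_DENOMS.get(entry.condition_id)
        rec = {"condition_id": entry.condition_id, "condition": entry.display_name,
               "denominator": "all" if sex is None else {"M": "men", "F": "women"}[sex]}
        for g, outcome in (("case", 1), ("control", 0)):
            rs = [r for r in rows if r.outcome == outcome and (sex is None or r.sex == sex)]
            k = sum(r.conditions[entry.condition_id] for r in rs)
            rec[f"{g}_n"] = k
            rec[f"{g}_pct"] = _pct(k, len(rs))
        out.append(rec)
    return pd.DataFrame(out)


def run_pipeline(config: RunConfig) -> RunReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(config.catalog_path)
    codes = load_phenotype_codes(config.phenotype_codes_path) if config.phenotype_codes_path else PhenotypeCodes()

    stage_seeds = {"simulate": config.seed, "match": config.seed + 1}
    report = RunReport(seed=config.seed, version=__version__, stage_seeds=stage_seeds)

    # --- inputs -----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        if config.tables_dir is not None:
            return read_tables(config.tables_dir)
        records, truth = generate_population(config.simulation, catalog)
        if config.write_input_tables:
            write_tables(records, truth, out_dir / "tables")
        return records, truth

    records, _truth = simulate()
    lookup = {r.patient_id: r for r in records}

    # --- phenotype --------------------------------------------------------
    @_stage("phenotype")
    def phenotype():
        return classify_cohort(records, config.study_window, codes, config.strict_control_screen)

    calls = phenotype()
    by_status: dict[str, list] = {}
    for c in calls:
        by_status.setdefault(c.status, []).append(c)
    exclusion_reasons: dict[str, int] = {}
    for c in by_status.get("excluded", []):
        exclusion_reasons[c.exclusion_reason] = exclusion_reasons.get(c.exclusion_reason, 0) + 1

    # --- match ------------------------------------------------------------
    @_stage("match")
    def match():
        cases = by_status.get("incident_case", [])
        pool = [lookup[c.patient_id] for c in by_status.get("control_eligible", [])]
        pairs, unmatched = match_cohort(cases, pool, lookup, seed=stage_seeds["match"])
        problems = validate_pairs(pairs, lookup)
        if problems:
            raise RuntimeError(f"matching validator found violations: {problems[:5]}")
        return pairs, unmatched

    pairs, unmatched = match()
    pd.DataFrame(
        [(p.case_id, p.control_id, p.case_index, p.control_index, p.stratum) for p in pairs],
        columns=["case_id", "control_id", "case_index", "control_index", "stratum"],
    ).to_csv(out_dir / "pairs.csv", index=False)
    pd.DataFrame({"case_id": unmatched}).to_csv(out_dir / "unmatched.csv", index=False)

    # --- ascertain --------------------------------------------------------
    @_stage("ascertain")
    def ascertain():
        return build_analysis_table(pairs, lookup, catalog, codes, config.lookback_years)

    rows = ascertain()
    rows_to_frame(rows).to_csv(out_dir / "analysis_table.csv", index=False)
    _build_table1(rows, lookup).to_csv(out_dir / "table1.csv", index=False)
    _build_fig1(rows, catalog).to_csv(out_dir / "fig1_frequencies.csv", index=False)

    strata_present = sorted({r.stratum for r in rows})

    # --- analyze: conditional logistic ------------------------------------
    @_stage("analyze_clogit")
    def analyze_clogit():
        all_results, all_skipped = [], []
        for stratum in strata_present:
            results, skipped = per_condition_analysis(
                rows, stratum, catalog, config.prevalence_threshold
            )
            all_results.extend(results)
            for s in skipped:
                all_skipped.append({"stratum": stratum, **s})
        return all_results, all_skipped

    or_results, not_analyzed = analyze_clogit()
    pd.DataFrame(
        or_results,
        columns=["stratum", "condition_id", "or", "ci_low", "ci_high", "n_informative", "converged"],
    ).to_csv(out_dir / "or_results.csv", index=False)
    pd.DataFrame(not_analyzed, columns=["stratum", "condition_id", "reason"]).to_csv(
        out_dir / "not_analyzed.csv", index=False
    )

    # --- analyze: boosting relative influence -----------------------------
    @_stage("analyze_gbm")
    def analyze_gbm():
        base = config.gbm or GbmConfig()
        ri_rows = []
        for si, stratum in enumerate(strata_present):
            seed = config.seed + 100 + 10 * si
            stage_seeds[f"gbm_{stratum}"] = seed
            cfg = dataclasses.replace(base, seed=seed)
            no_burden, with_burden = ri_analysis(
                rows, stratum, catalog, cfg, config.prevalence_threshold
            )
            for ri in (no_burden, with_burden):
                for var, pct in ri.relative_influence.items():
                    ri_rows.append(
                        {"stratum": stratum, "variant": ri.variant, "variable": var,
                         "ri_percent": round(float(pct), 4)}
                    )
        return ri_rows

    ri_rows = analyze_gbm()
    pd.DataFrame(ri_rows, columns=["stratum", "variant", "variable", "ri_percent"]).to_csv(
        out_dir / "ri_results.csv", index=False
    )

    # --- report -----------------------------------------------------------
    n_cases = len(by_status.get("incident_case", []))
    report.counts = {
        "patients": len(records),
        "incident_cases": n_cases,
        "prevalent_cases": len(by_status.get("prevalent_case", [])),
        "excluded": len(by_status.get("excluded", [])),
        "exclusions_by_reason": exclusion_reasons,
        "control_eligible": len(by_status.get("control_eligible", [])),
        "ineligible": len(by_status.get("ineligible", [])),
        "matched_pairs": len(pairs),
        "unmatched_cases": len(unmatched),
        "per_stratum_pairs": {s: sum(p.stratum == s for p in pairs) for s in strata_present},
    }
    assert n_cases == len(pairs) + len(unmatched)
    report.config_echo = {
        "study_window": [d.isoformat() for d in config.study_window],
        "lookback_years": config.lookback_years,
        "prevalence_threshold": config.prevalence_threshold,
        "strict_control_screen": config.strict_control_screen,
        "gbm": dataclasses.asdict(config.gbm or GbmConfig()),
        "simulation": dataclasses.asdict(config.simulation) if config.simulation else None,
        "tables_dir": str(config.tables_dir) if config.tables_dir else None,
        "seed_rule": "simulate=seed, match=seed+1, gbm=seed+100+10*stratum_index",
    }
    (out_dir / "run_report.json").write_text(report.to_json())
    return report
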