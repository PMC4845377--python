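"""Chronic-condition catalog and phenotype code sets.

The condition catalog holds the 24 CCW-style chronic-condition categories
(the Chronic Conditions Data Warehouse set after removing the
dementia/Alzheimer's and depression categories) together with the ICD-9-CM
prefixes that ascertain each one and the sex restriction applied when the
flag is computed.  Both the catalog and the phenotype code sets are loaded
from editable YAML so users can substitute their own code lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

SEX_RESTRICTIONS = ("none", "male_only", "female_only")


@dataclass(frozen=True)
class ConditionEntry:
    condition_id: str
    display_name: str
    icd9_prefixes: tuple[str, ...]
    sex_restriction: str = "none"

    def __post_init__(self) -> None:
        if self.sex_restriction not in SEX_RESTRICTIONS:
            raise ValueError(f"unknown sex_restriction {self.sex_restriction!r}")
        if not self.icd9_prefixes:
            raise ValueError(f"condition {self.condition_id!r} has no ICD-9 prefixes")

    def applies_to(self, sex: str) -> bool:
        """Whether this condition can be flagged for a subject of the given sex."""
        if self.sex_restriction == "male_only":
            return sex == "M"
        if self.sex_restriction == "female_only":
            return sex == "F"
        return True


@dataclass(frozen=True)
class ConditionCatalog:
    entries: tuple[ConditionEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.condition_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate condition ids in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def condition_ids(self) -> list[str]:
        return [e.condition_id for e in self.entries]

    def get(self, condition_id: str) -> ConditionEntry:
        for e in self.entries:
            if e.condition_id == condition_id:
                return e
        raise KeyError(condition_id)


@dataclass(frozen=True)
class PhenotypeCodes:
    """Code sets driving the rule-based MDD case-finding algorithm."""

    mdd_icd9_prefixes: tuple[str, ...] = ("296.2", "296.3")
    antidepressant_classes: tuple[str, ...] = ("C8870", "C8872", "C8874", "C8876")
    phq9_threshold: int = 15
    exclusion_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "bipolar": ("296.1", "296.4", "296.5", "296.6", "296.7", "296.8", "296.9"),
            "dementia_delirium": ("290",),
            "psychotic": ("295", "298"),
        }
    )
    obesity_codes: tuple[str, ...] = (
        "278.0", "564.2", "V45.3", "V45.86", "649.1", "649.2", "V85.3", "V85.4", "V77.8",
    )


def normalize_code(code: str) -> str:
    """Normalize an ICD code for prefix matching: strip whitespace, uppercase."""
    return code.strip().upper()


def code_matches(code: str, prefixes) -> bool:
    """String-prefix match after normalization (standard ICD-9-CM hierarchy semantics)."""
    norm = normalize_code(code)
    return any(norm.startswith(normalize_code(p)) for p in prefixes)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mdd_comorbidity").joinpath("data", name)))


def load_catalog(path: str | Path | None = None) -> ConditionCatalog:
    """Load a condition catalog from YAML; the packaged default has 24 entries."""
    path = _data_path("ccw_catalog.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    entries = tuple(
        ConditionEntry(
            condition_id=item["id"],
            display_name=item.get("name", item["id"]),
            icd9_prefixes=tuple(str(p) for p in item["icd9_prefixes"]),
            sex_restriction=item.get("sex_restriction", "none"),
        )
        for item in raw["conditions"]
    )
    return ConditionCatalog(entries=entries)


def load_phenotype_codes(path: str | Path | None = None) -> PhenotypeCodes:
    path = _data_path("phenotype_codes.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    return PhenotypeCodes(
        mdd_icd9_prefixes=tuple(raw["mdd_icd9_prefixes"]),
        antidepressant_classes=tuple(raw["antidepressant_ndfrt_classes"]),
        phq9_threshold=int(raw["phq9_threshold"]),
        exclusion_prefixes={k: tuple(v) for k, v in raw["exclusion_icd9_prefixes"].items()},
        obesity_codes=tuple(raw["obesity_icd9_codes"]),
    )
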