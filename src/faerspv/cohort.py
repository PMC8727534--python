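"""Cohort selection and contingency-table construction.

Given a deduplicated report universe, select the reports in which a target
drug (matched through a configurable brand/generic synonym list, primary
suspect role only) co-occurs with a target set of MedDRA Preferred Terms,
optionally split off suicide-related use, and build the 2x2 contingency
table

    =============  ===========  ===============
                   target event  other events
    =============  ===========  ===============
    target drug         a             c
    other drugs         b             d
    =============  ===========  ===============

whose cells feed every disproportionality statistic: ``a`` counts reports
containing both the suspect drug and the suspect reaction, ``b`` the
reaction with other medications, ``c`` the suspect drug with other
reactions, and ``d`` neither.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, field_validator

from .io import CaseReport, PartialDate

logger = logging.getLogger("faerspv")

# --------------------------------------------------------------------------
# Default target configuration: drug-induced kidney injury
# --------------------------------------------------------------------------

#: MedDRA Preferred Terms (name, code) commonly used to capture drug-induced
#: kidney injury in spontaneous-report screening.  "Dialysis" names a
#: procedure rather than an injury but is retained by default; drop it with
#: ``CohortConfig.without_pt("dialysis")``.
KIDNEY_INJURY_PTS: tuple[tuple[str, int], ...] = (
    ("Acute kidney injury", 10069339),
    ("Subacute kidney injury", 10081980),
    ("Acute prerenal failure", 10001017),
    ("Renal failure acute ischaemic", 10038439),
    ("Blood creatinine increased", 10005483),
    ("Blood urea abnormal", 10005846),
    ("Glomerular filtration rate decreased", 10018358),
    ("Renal impairment", 10062237),
    ("Oliguria", 10030302),
    ("Anuria", 10002847),
    ("Dialysis", 10061105),
    ("Proteinuria", 10037032),
    ("Nephrosis osmotic", 10029163),
    ("Renal tubular injury", 10078933),
    ("Nephropathy toxic", 10029155),
    ("Nephritis allergic", 10029120),
    ("Tubulointerstitial nephritis", 10048302),
)

IBUPROFEN_SYNONYMS = (
    "ibuprofen", "advil", "motrin", "nurofen", "brufen", "caldolor",
    "neoprofen", "midol ib", "ibuprofen lysine", "dexibuprofen",
)

ACETAMINOPHEN_SYNONYMS = (
    "acetaminophen", "paracetamol", "apap", "tylenol", "panadol", "calpol",
    "perfalgan", "ofirmev", "tempra", "anacin aspirin free",
)

#: Indication terms that mark intentional self-harm / deliberate overdose.
SUICIDE_INDICATION_TERMS = (
    "intentional overdose", "poisoning deliberate", "suicidal ideation",
    "suicide attempt", "intentional product misuse", "overdose", "poisoning",
)


class DateWindow(BaseModel):
    """Inclusive study window applied to the FDA receipt date."""

    start: str = "2004-01-01"
    end: str = "2021-03-31"

    def contains(self, d: PartialDate | None) -> bool:
        # reports with unknown receipt date are retained
        if d is None:
            return True
        lo = PartialDate.from_isoformat(self.start).sort_key()
        hi = PartialDate.from_isoformat(self.end).sort_key()
        return lo <= d.sort_key() <= hi


class CohortConfig(BaseModel):
    """Target definition for one drug-event screening question."""

    drug_name: str = "drug"
    drug_synonyms: list[str]
    target_pts: list[tuple[str, int]]
    window: DateWindow = Field(default_factory=DateWindow)
    required_role: str = "PS"
    suicide_indication_terms: list[str] = list(SUICIDE_INDICATION_TERMS)
    suicide_dose_threshold_grams: float = 12.0

    @field_validator("drug_synonyms", "target_pts")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("must be non-empty")
        return v

    @field_validator("suicide_dose_threshold_grams")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("threshold must be > 0")
        return v

    def without_pt(self, name: str) -> "CohortConfig":
        keep = [(n, c) for n, c in self.target_pts if n.lower() != name.lower()]
        return self.model_copy(update={"target_pts": keep})

    @property
    def target_pt_codes(self) -> frozenset[int]:
        return frozenset(c for _, c in self.target_pts)

    @property
    def target_pt_names(self) -> frozenset[str]:
        return frozenset(n.upper() for n, _ in self.target_pts)


def ibuprofen_config(**overrides) -> CohortConfig:
    return CohortConfig(drug_name="ibuprofen",
                        drug_synonyms=list(IBUPROFEN_SYNONYMS),
                        target_pts=list(KIDNEY_INJURY_PTS), **overrides)


def acetaminophen_config(**overrides) -> CohortConfig:
    return CohortConfig(drug_name="acetaminophen",
                        drug_synonyms=list(ACETAMINOPHEN_SYNONYMS),
                        target_pts=list(KIDNEY_INJURY_PTS), **overrides)


# --------------------------------------------------------------------------
# Drug-name normalization and matching
# --------------------------------------------------------------------------

_FORM_TOKENS = frozenset({
    "TABLET", "TABLETS", "TAB", "CAPSULE", "CAPSULES", "CAP", "CAPLET",
    "CAPLETS", "ORAL", "SUSPENSION", "SOLUTION", "SYRUP", "INJECTION",
    "GEL", "CREAM", "SUPPOSITORY", "ER", "XR", "SR", "IV", "LIQUID",
    "CHEWABLE", "DROPS", "FILM", "COATED", "EXTENDED", "RELEASE",
})
_UNIT_RE = re.compile(r"^(\d+(\.\d+)?)?(MG|G|GM|MCG|UG|ML|MG/ML|%)?$")


def normalize_drug_name(name: str) -> str:
    """Uppercase, strip punctuation, drop trailing dose/form tokens."""
    s = re.sub(r"[^\w\s/%.]", " ", name.upper())
    tokens = s.split()
    # strip dose / formulation tokens from the tail
    while tokens and (tokens[-1] in _FORM_TOKENS or _UNIT_RE.match(tokens[-1])):
        tokens.pop()
    return " ".join(tokens)


def match_target_drug(report: CaseReport, config: CohortConfig) -> bool:
    """True iff a primary-suspect drug entry matches a configured synonym."""
    synonyms = {normalize_drug_name(s) for s in config.drug_synonyms}
    for d in report.drugs:
        if d.role != config.required_role:
            continue
        if normalize_drug_name(d.name) in synonyms:
            return True
    return False


def match_target_event(report: CaseReport, config: CohortConfig) -> bool:
    """True iff any reaction PT matches the target set (code preferred)."""
    codes = config.target_pt_codes
    names = config.target_pt_names
    for r in report.reactions:
        if r.code is not None:
            if r.code in codes:
                return True
        elif r.name.upper() in names:
            return True
    return False


def _target_entries(report: CaseReport, config: CohortConfig) -> list:
    synonyms = {normalize_drug_name(s) for s in config.drug_synonyms}
    return [d for d in report.drugs
            if d.role == config.required_role
            and normalize_drug_name(d.name) in synonyms]


def flag_suicide(report: CaseReport, config: CohortConfig) -> bool:
    """True iff the report looks like intentional self-harm with the drug.

    Either an indication term (report- or drug-level) contains one of the
    configured suicide terms, or the summed reported dose of the target
    drug exceeds the configured gram threshold.
    """
    terms = [t.lower() for t in config.suicide_indication_terms]
    indications = list(report.indications) + [
        d.indication for d in report.drugs if d.indication
    ]
    for ind in indications:
        low = ind.lower()
        if any(t in low for t in terms):
            return True
    doses = [d.dose_grams for d in _target_entries(report, config)
             if d.dose_grams is not None]
    return bool(doses) and sum(doses) > config.suicide_dose_threshold_grams


# --------------------------------------------------------------------------
# Cohorts and the 2x2 table
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Counts underlying the disproportionality statistics."""

    a: int  # target drug & target event
    b: int  # other drugs & target event
    c: int  # target drug & other events
    d: int  # other drugs & other events

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def with_continuity_correction(self, delta: float = 0.5):
        """Haldane-style corrected cells (floats), for zero-cell tables."""
        return (self.a + delta, self.b + delta, self.c + delta, self.d + delta)


@dataclass(slots=True)
class CohortResult:
    """Per-drug case selection with CONSORT-style flow counts."""

    drug_name: str
    cases: list[CaseReport]
    non_suicide_cases: list[CaseReport]
    suicide_cases: list[CaseReport]
    flow: dict[str, int]


def build_cohorts(reports: Sequence[CaseReport],
                  configs: Iterable[CohortConfig]) -> dict[str, CohortResult]:
    """Select per-drug kidney-injury cohorts and their suicide split.

    A report matching several drug configs appears in each matching cohort.
    ``flow`` records counts after each successive filter (universe, study
    window, drug match, event match, suicide exclusion).
    """
    out: dict[str, CohortResult] = {}
    for config in configs:
        in_window = [r for r in reports if config.window.contains(r.version_date)]
        drug_matched = [r for r in in_window if match_target_drug(r, config)]
        cases = [r for r in drug_matched if match_target_event(r, config)]
        suicide = [r for r in cases if flag_suicide(r, config)]
        non_suicide = [r for r in cases if not flag_suicide(r, config)]
        out[config.drug_name] = CohortResult(
            drug_name=config.drug_name,
            cases=cases,
            non_suicide_cases=non_suicide,
            suicide_cases=suicide,
            flow={
                "universe": len(reports),
                "in_window": len(in_window),
                "drug_matched": len(drug_matched),
                "drug_and_event": len(cases),
                "suicide_excluded": len(non_suicide),
                "suicide_only": len(suicide),
            },
        )
    return out


def build_contingency(reports: Sequence[CaseReport],
                      config: CohortConfig) -> ContingencyTable:
    """Partition the universe into the 2x2 cells for one drug-event pair.

    Every report falls in exactly one cell; only a primary-suspect match
    counts as drug exposure.
    """
    if not reports:
        raise ValueError("empty report universe: no statistics computable")
    a = b = c = d = 0
    for r in reports:
        drug = match_target_drug(r, config)
        event = match_target_event(r, config)
        if drug and event:
            a += 1
        elif event:
            b += 1
        elif drug:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)
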