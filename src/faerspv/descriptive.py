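"""Clinical-characteristics tables, rate comparisons and dose summaries.

Summarizes a selected cohort the way pharmacovigilance case series are
reported: demographic breakdowns (age bands, sex, world region, reporter
occupation), outcome frequencies (a report may carry several outcome codes,
so outcome counts do not sum to the cohort size), two-group rate
comparisons (Fisher exact / Pearson chi-square), overdose-dose summaries
and co-reported-event ("complication") rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortConfig, _target_entries
from .io import CaseReport
from .signals import round_half_up

logger = logging.getLogger("faerspv")

# --------------------------------------------------------------------------
# Category vocabularies
# --------------------------------------------------------------------------

AGE_BANDS = ("<18", "18-44", "45-64", "65-74", ">74", "Unknown")

_AGE_UNIT_TO_YEARS = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12, "WK": 1 / 52.18,
                      "DY": 1 / 365.25, "HR": 1 / 8766}

SEX_LABELS = {"F": "Female", "M": "Male"}

OUTCOME_LABELS = {
    "DE": "Death",
    "HO": "Hospitalization",
    "LT": "Life-Threatening",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention",
    "OT": "Other Serious",
}

REPORTER_LABELS = {
    "CN": "Consumer",
    "LW": "Lawyer",
    "PH": "Pharmacist",
    "MD": "Physician",
    "OT": "Other health-professional",
    "HP": "Other health-professional",
}

REGIONS = ("Africa", "Asia", "Europe", "Oceania", "North America",
           "South America", "Unknown")

#: ISO-3166 alpha-2 country -> continent, covering the reporter countries
#: that dominate spontaneous-report databases; unmapped codes -> Unknown.
COUNTRY_TO_REGION: dict[str, str] = {
    # North America
    "US": "North America", "CA": "North America", "MX": "North America",
    "PR": "North America", "CR": "North America", "PA": "North America",
    "GT": "North America", "DO": "North America", "CU": "North America",
    # South America
    "BR": "South America", "AR": "South America", "CO": "South America",
    "CL": "South America", "PE": "South America", "VE": "South America",
    "EC": "South America", "UY": "South America",
    # Europe
    "GB": "Europe", "DE": "Europe", "FR": "Europe", "IT": "Europe",
    "ES": "Europe", "NL": "Europe", "BE": "Europe", "CH": "Europe",
    "AT": "Europe", "SE": "Europe", "NO": "Europe", "DK": "Europe",
    "FI": "Europe", "IE": "Europe", "PT": "Europe", "PL": "Europe",
    "CZ": "Europe", "HU": "Europe", "GR": "Europe", "RO": "Europe",
    "RU": "Europe", "UA": "Europe", "HR": "Europe", "RS": "Europe",
    "SK": "Europe", "SI": "Europe", "BG": "Europe", "LT": "Europe",
    "LV": "Europe", "EE": "Europe", "IS": "Europe", "LU": "Europe",
    # Asia
    "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia", "TW": "Asia",
    "TH": "Asia", "SG": "Asia", "MY": "Asia", "PH": "Asia", "ID": "Asia",
    "VN": "Asia", "IL": "Asia", "SA": "Asia", "AE": "Asia", "TR": "Asia",
    "PK": "Asia", "BD": "Asia", "HK": "Asia", "IR": "Asia", "IQ": "Asia",
    # Oceania
    "AU": "Oceania", "NZ": "Oceania", "FJ": "Oceania", "PG": "Oceania",
    # Africa
    "ZA": "Africa", "EG": "Africa", "NG": "Africa", "KE": "Africa",
    "MA": "Africa", "TN": "Africa", "DZ": "Africa", "GH": "Africa",
    "ET": "Africa", "TZ": "Africa",
}


# --------------------------------------------------------------------------
# Age handling
# --------------------------------------------------------------------------


def age_in_years(age_value: float | None, age_unit: str | None) -> float | None:
    """Convert a (value, unit-code) age to years; None when not convertible."""
    if age_value is None:
        return None
    if age_value < 0:
        logger.warning("negative age %s ignored", age_value)
        return None
    factor = _AGE_UNIT_TO_YEARS.get((age_unit or "YR").strip().upper())
    if factor is None:
        return None
    return age_value * factor


def assign_age_band(age_value: float | None, age_unit: str | None) -> str:
    """Band an age into ``<18, 18-44, 45-64, 65-74, >74, Unknown``."""
    years = age_in_years(age_value, age_unit)
    if years is None:
        return "Unknown"
    if years < 18:
        return "<18"
    if years < 45:
        return "18-44"
    if years < 65:
        return "45-64"
    if years < 75:
        return "65-74"
    return ">74"


# --------------------------------------------------------------------------
# Demographics table
# --------------------------------------------------------------------------


def _pct(k: int, n: int) -> float:
    return 0.0 if n == 0 else round_half_up(100.0 * k / n)


@dataclass(slots=True)
class DemographicsTable:
    """Counts and percentages per characteristic for one cohort.

    ``table`` has one row per (characteristic, category) with the count,
    the percentage over the whole cohort, and — for age and sex — the
    percentage over reports with the characteristic known.  ``aggregates``
    carries derived rows (the 65+ age group) kept out of the closure-checked
    categories.
    """

    n: int
    table: pd.DataFrame
    aggregates: pd.DataFrame


def demographics_table(cohort: Sequence[CaseReport]) -> DemographicsTable:
    n = len(cohort)
    rows = []

    def _emit(characteristic, counts: dict[str, int], known_denominator=None):
        for category, k in counts.items():
            known_pct = None
            if known_denominator is not None and category != "Unknown":
                known_pct = _pct(k, known_denominator)
            rows.append({"characteristic": characteristic, "category": category,
                         "count": k, "pct": _pct(k, n), "pct_known": known_pct})

    age_counts = {band: 0 for band in AGE_BANDS}
    for r in cohort:
        age_counts[assign_age_band(r.age_value, r.age_unit)] += 1
    known_age = n - age_counts["Unknown"]
    _emit("age", age_counts, known_age)

    sex_counts = {"Female": 0, "Male": 0, "Unknown": 0}
    for r in cohort:
        sex_counts[SEX_LABELS.get((r.sex or "").upper(), "Unknown")] += 1
    known_sex = n - sex_counts["Unknown"]
    _emit("sex", sex_counts, known_sex)

    region_counts = {region: 0 for region in REGIONS}
    for r in cohort:
        region_counts[COUNTRY_TO_REGION.get((r.country or "").upper(), "Unknown")] += 1
    _emit("region", region_counts)

    reporter_counts = {label: 0 for label in
                       ("Consumer", "Lawyer", "Pharmacist", "Physician",
                        "Other health-professional", "Unknown")}
    for r in cohort:
        reporter_counts[REPORTER_LABELS.get((r.reporter or "").upper(), "Unknown")] += 1
    _emit("reporter", reporter_counts)

    outcome_counts = {label: 0 for label in OUTCOME_LABELS.values()}
    for r in cohort:
        for code in r.outcomes:
            label = OUTCOME_LABELS.get(code)
            if label:
                outcome_counts[label] += 1
    _emit("outcome", outcome_counts)

    k65 = age_counts["65-74"] + age_counts[">74"]
    aggregates = pd.DataFrame([{
        "characteristic": "age_aggregate", "category": "65+",
        "count": k65, "pct": _pct(k65, n),
        "pct_known": _pct(k65, known_age) if known_age else None,
    }])
    return DemographicsTable(n=n, table=pd.DataFrame(rows), aggregates=aggregates)


# --------------------------------------------------------------------------
# Outcome rates and rate comparisons
# --------------------------------------------------------------------------


@dataclass(slots=True)
class OutcomeRates:
    n: int
    n_with_outcome: int
    counts: dict[str, int]  # per outcome code
    rate_all: dict[str, float]  # denominator: all cases
    rate_with_outcome: dict[str, float | None]  # denominator: cases w/ >=1 outcome
    note: str | None = None


def outcome_rates(cohort: Sequence[CaseReport]) -> OutcomeRates:
    """Outcome frequencies with both denominators reported."""
    n = len(cohort)
    n_with = sum(1 for r in cohort if r.outcomes)
    counts = {code: 0 for code in OUTCOME_LABELS}
    for r in cohort:
        for code in r.outcomes:
            if code in counts:
                counts[code] += 1
    rate_all = {c: (k / n if n else 0.0) for c, k in counts.items()}
    if n_with:
        rate_with = {c: k / n_with for c, k in counts.items()}
        note = None
    else:
        rate_with = {c: None for c in counts}
        note = "no case carries a recorded outcome; with-outcome rates undefined"
        logger.warning(note)
    return OutcomeRates(n, n_with, counts, rate_all, rate_with, note)


@dataclass(slots=True)
class RateComparison:
    rate1: float
    rate2: float
    test_name: str  # fisher_exact | pearson_chi2
    statistic: float | None
    p_value: float
    note: str | None = None


def compare_rates(k1: int, n1: int, k2: int, n2: int,
                  method: str = "fisher_exact") -> RateComparison:
    """Two-sided comparison of two proportions.

    Fisher's exact test by default; Pearson's chi-square when requested and
    all expected counts are >= 5 (otherwise it falls back to Fisher with a
    note).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("event counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    note = None
    if method == "pearson_chi2":
        expected = stats.contingency.expected_freq(table)
        if (expected >= 5).all():
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            return RateComparison(k1 / n1, k2 / n2, "pearson_chi2",
                                  float(chi2), float(p))
        note = "expected count < 5; fell back to Fisher's exact test"
    elif method != "fisher_exact":
        raise ValueError(f"unknown method {method!r}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return RateComparison(k1 / n1, k2 / n2, "fisher_exact", None, float(p), note)


# --------------------------------------------------------------------------
# Dose summaries (suicide subset)
# --------------------------------------------------------------------------


@dataclass(slots=True)
class DoseSummary:
    n: int  # cases with a usable dose
    n_missing: int  # cases excluded for missing dose
    median_grams: float | None
    iqr: tuple[float, float] | None
    count_at_or_above_threshold: int
    threshold_grams: float
    note: str | None = None


def dose_summary(doses_grams: Sequence[float | None],
                 threshold_grams: float) -> DoseSummary:
    """Median / IQR (linear-interpolation quartiles) and threshold count.

    Missing doses are excluded and counted; the threshold comparison is
    inclusive (``>=``).
    """
    usable = sorted(float(x) for x in doses_grams if x is not None)
    n_missing = len(doses_grams) - len(usable)
    if not usable:
        return DoseSummary(0, n_missing, None, None, 0, threshold_grams,
                           note="no case reports a usable dose")
    arr = np.asarray(usable)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear (type 7)
    k = int((arr >= threshold_grams).sum())
    return DoseSummary(len(usable), n_missing, float(med),
                       (float(q1), float(q3)), k, threshold_grams)


def extract_target_doses(cases: Sequence[CaseReport],
                         config: CohortConfig) -> list[float | None]:
    """Per-case total reported dose (grams) of the target drug."""
    out: list[float | None] = []
    for r in cases:
        doses = [d.dose_grams for d in _target_entries(r, config)
                 if d.dose_grams is not None]
        out.append(sum(doses) if doses else None)
    return out


# --------------------------------------------------------------------------
# Complications
# --------------------------------------------------------------------------


def complication_ranking(cohort: Sequence[CaseReport],
                         target_pts: Sequence[tuple[str, int]],
                         top_k: int | None = 10) -> pd.DataFrame:
    """Rank non-target reaction PTs co-reported with the target events.

    Counts the number of cohort reports mentioning each PT outside the
    target set; descending by count, ties alphabetical.  ``top_k=None``
    returns the full ranking.
    """
    target_codes = {c for _, c in target_pts}
    target_names = {n.upper() for n, _ in target_pts}
    counts: dict[str, int] = {}
    for r in cohort:
        seen: set[str] = set()
        for reaction in r.reactions:
            if reaction.code is not None and reaction.code in target_codes:
                continue
            if reaction.name.upper() in target_names:
                continue
            key = reaction.name
            if key.upper() not in seen:
                seen.add(key.upper())
                counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].upper()))
    if top_k is not None:
        ranked = ranked[:top_k]
    return pd.DataFrame(ranked, columns=["pt", "count"])


def plot_complications(ranking: pd.DataFrame, path: str,
                       title: str = "Top co-reported events") -> None:
    """Horizontal bar chart of a complication ranking."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(ranking), 4) + 1.5))
    ax.barh(ranking["pt"][::-1], ranking["count"][::-1], color="#4878a8")
    ax.set_xlabel("reports")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
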