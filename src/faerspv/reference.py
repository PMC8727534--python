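"""Published reference inputs for the worked kidney-injury example.

Post-marketing surveillance work on ibuprofen- and acetaminophen-associated
kidney injury reports its case series as printed tables: clinical
characteristic counts, suicide-subset dose listings, and the four
disproportionality statistics per drug.  Those printed values are *inputs*
here — the package recomputes percentages, dose summaries and criteria
decisions from them, which makes the arithmetic independently checkable.

All dose values are grams; counts are deduplicated report counts.
"""

from __future__ import annotations

from .signals import SignalCriteria, SignalScores, evaluate_criteria

# --------------------------------------------------------------------------
# Cohort sizes (deduplicated) and raw retrieval counts
# --------------------------------------------------------------------------

RAW_REPORTS = {"ibuprofen": 3673, "acetaminophen": 2296}
DEDUP_REPORTS = {"ibuprofen": 2453, "acetaminophen": 1288}

# --------------------------------------------------------------------------
# Clinical-characteristics counts (per drug)
# --------------------------------------------------------------------------

AGE_COUNTS = {
    "ibuprofen": {"<18": 431, "18-44": 459, "45-64": 571, "65-74": 340,
                  ">74": 256, "Unknown": 396},
    "acetaminophen": {"<18": 125, "18-44": 485, "45-64": 312, "65-74": 68,
                      ">74": 82, "Unknown": 216},
}

SEX_COUNTS = {
    "ibuprofen": {"Female": 1073, "Male": 1072, "Unknown": 308},
    "acetaminophen": {"Female": 635, "Male": 501, "Unknown": 152},
}

REGION_COUNTS = {
    "ibuprofen": {"Africa": 2, "Asia": 60, "Europe": 1500, "Oceania": 36,
                  "North America": 794, "South America": 10, "Unknown": 51},
    "acetaminophen": {"Africa": 1, "Asia": 93, "Europe": 474, "Oceania": 17,
                      "North America": 611, "South America": 1, "Unknown": 91},
}

REPORTER_COUNTS = {
    "ibuprofen": {"Consumer": 152, "Lawyer": 4, "Pharmacist": 364,
                  "Physician": 690, "Other health-professional": 799,
                  "Unknown": 444},
    "acetaminophen": {"Consumer": 55, "Lawyer": 2, "Pharmacist": 91,
                      "Physician": 372, "Other health-professional": 509,
                      "Unknown": 259},
}

OUTCOME_COUNTS = {
    "ibuprofen": {"Death": 178, "Hospitalization": 1778, "Disability": 37,
                  "Life-Threatening": 323, "Other Serious": 1327,
                  "Required Intervention": 28, "Congenital Anomaly": 2},
    "acetaminophen": {"Death": 570, "Hospitalization": 838, "Disability": 13,
                      "Life-Threatening": 205, "Other Serious": 652,
                      "Required Intervention": 17, "Congenital Anomaly": 1},
}

# --------------------------------------------------------------------------
# Suicide-subset dose listings (grams per case)
# --------------------------------------------------------------------------

IBUPROFEN_SUICIDE_DOSES_G = (
    2.4, 9.6, 9.6, 9.6, 9.6, 6.4, 6.4, 12, 12, 23,
    23, 8, 8, 12.4, 28.8, 95.4, 12, 105, 24, 100,
)

ACETAMINOPHEN_SUICIDE_DOSES_G = (
    50, 40, 30, 15, 40, 40, 40, 16, 16, 16, 16,
    8, 8, 28, 28, 40, 40, 90, 3, 3, 16,
    30, 30, 3, 2, 8, 8, 20, 7, 50, 27, 50, 28,
)

SUICIDE_DOSE_THRESHOLDS_G = {"ibuprofen": 12.0, "acetaminophen": 16.0}

# --------------------------------------------------------------------------
# Published disproportionality statistics per drug
# --------------------------------------------------------------------------

#: As printed: co-occurrence count N, ROR with 95% CI, PRR with chi-square,
#: IC with its 95% lower bound, EBGM with its one-sided lower bound.
PUBLISHED_SIGNALS: dict[str, dict] = {
    "ibuprofen": {"n": 1287, "ror": 1.34, "ror_ci95": (1.27, 1.41),
                  "prr": 1.33, "chi2": 106.38, "ic": 0.41, "ic025": 0.39,
                  "ebgm": 1.33, "eb05": 1.27},
    "acetaminophen": {"n": 2451, "ror": 2.45, "ror_ci95": (2.36, 2.56),
                      "prr": 2.39, "chi2": 2002.94, "ic": 1.25, "ic025": 1.20,
                      "ebgm": 2.38, "eb05": 2.30},
}


def published_scores(drug: str) -> SignalScores:
    """The published statistics for one drug as a :class:`SignalScores`."""
    v = PUBLISHED_SIGNALS[drug]
    return SignalScores(n_cooccurrence=v["n"], ror=v["ror"],
                        ror_ci95=v["ror_ci95"], prr=v["prr"], chi2=v["chi2"],
                        ic=v["ic"], ic025=v["ic025"], ebgm=v["ebgm"],
                        eb05=v["eb05"])


def published_criteria(drug: str) -> SignalCriteria:
    """Criteria decisions recomputed from the published statistics."""
    return evaluate_criteria(published_scores(drug))
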