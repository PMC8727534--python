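"""Synthetic FAERS-like quarterly tables with planted structure.

Every stage of the pipeline is testable without external data: the
generator emits the six quarterly tables (DEMO, DRUG, REAC, OUTC, INDI,
THER) in either accepted dialect together with a per-case ground-truth
ledger, so that cohort selection, deduplication, disproportionality
statistics, dose screening and time-to-onset each have a known correct
answer.

The planting model is a two-way Bernoulli scheme per target drug: a report
is exposed with probability ``exposure_prob`` (exposure writes a
primary-suspect drug entry), and develops a target event with probability
``baseline_event_prob`` when unexposed and ``baseline_event_prob *
planted_rr`` when exposed.  Exposed cases with the event receive a true
onset drawn from a log-normal (configurable median and log-scale sigma)
which links the drug start date to the event date before any date
degradation (missing / truncated dates) is applied.  Duplicate case
versions share a CASEID with earlier FDA receipt dates, so
keep-latest-version deduplication has a well-defined correct answer.

Reproducibility: the same :class:`SyntheticParams` (including ``seed``)
produce byte-identical output files.  Independent RNG streams are spawned
per concern (structure, demographics, dates, reactions, outcomes, doses,
duplicates) so extending one table does not perturb the others.
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort import KIDNEY_INJURY_PTS, ContingencyTable
from .io import RawTables

# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

BACKGROUND_DRUGS = (
    "LISINOPRIL", "METFORMIN", "ATORVASTATIN", "OMEPRAZOLE", "AMOXICILLIN",
    "SERTRALINE", "AMLODIPINE", "LEVOTHYROXINE", "GABAPENTIN", "WARFARIN",
    "FUROSEMIDE", "PREDNISONE", "INSULIN GLARGINE", "SALBUTAMOL",
    "CLOPIDOGREL", "RAMIPRIL",
)

#: (PT name, invented non-MedDRA code, sampling weight); weights are skewed
#: so complication rankings have a stable, non-trivial order.
BACKGROUND_PTS = (
    ("Vomiting", 20000001, 10.0),
    ("Metabolic acidosis", 20000002, 6.0),
    ("Hypotension", 20000003, 5.0),
    ("Nausea", 20000004, 4.5),
    ("Hepatotoxicity", 20000005, 4.0),
    ("Diarrhoea", 20000006, 3.5),
    ("Pyrexia", 20000007, 3.0),
    ("Rash", 20000008, 2.5),
    ("Headache", 20000009, 2.0),
    ("Dizziness", 20000010, 1.8),
    ("Fatigue", 20000011, 1.5),
    ("Dyspnoea", 20000012, 1.2),
    ("Abdominal pain", 20000013, 1.0),
    ("Pruritus", 20000014, 0.8),
    ("Somnolence", 20000015, 0.6),
)

BENIGN_INDICATIONS = ("Pain", "Pyrexia", "Headache", "Arthralgia", "Influenza")
SUICIDE_INDICATIONS = ("Suicide attempt", "Intentional overdose",
                       "Poisoning deliberate", "Suicidal ideation")

#: Demographic category distributions loosely shaped like spontaneous-report
#: case series for OTC analgesics (heavy European/North-American reporting,
#: substantial unknowns).
AGE_BAND_PROBS = {"<18": 0.17, "18-44": 0.19, "45-64": 0.23, "65-74": 0.14,
                  ">74": 0.10, "Unknown": 0.17}
AGE_BAND_RANGES = {"<18": (0.5, 17.9), "18-44": (18.0, 44.9),
                   "45-64": (45.0, 64.9), "65-74": (65.0, 74.9),
                   ">74": (75.0, 95.0)}
SEX_PROBS = {"F": 0.44, "M": 0.44, "": 0.12}
COUNTRY_PROBS = {"GB": 0.22, "DE": 0.18, "FR": 0.18, "US": 0.28, "CA": 0.03,
                 "JP": 0.02, "AU": 0.015, "BR": 0.005, "ZA": 0.002, "": 0.048}
REPORTER_PROBS = {"CN": 0.06, "LW": 0.002, "PH": 0.15, "MD": 0.28, "OT": 0.33,
                  "": 0.178}
#: Outcome code probabilities, conditional on carrying a target event.
OUTCOME_PROBS_TARGET = {"DE": 0.07, "HO": 0.70, "LT": 0.13, "DS": 0.015,
                        "CA": 0.001, "RI": 0.011, "OT": 0.55}
OUTCOME_PROBS_OTHER = {"DE": 0.04, "HO": 0.30, "LT": 0.05, "DS": 0.01,
                       "CA": 0.001, "RI": 0.008, "OT": 0.40}

WINDOW_START = np.datetime64("2004-01-01")
WINDOW_END = np.datetime64("2021-03-31")


class TargetDrugParams(BaseModel):
    """Planting parameters for one target drug."""

    name: str
    exposure_prob: float = Field(gt=0, le=1)
    planted_rr: float = Field(gt=0)
    onset_median_days: float = Field(default=5.0, gt=0)
    onset_sigma: float = Field(default=1.5, gt=0)
    suicide_rate: float = Field(default=0.02, ge=0, le=1)
    suicide_dose_median_grams: float = Field(default=20.0, gt=0)


class SyntheticParams(BaseModel):
    """Full configuration of one synthetic report universe."""

    n_reports: int = Field(default=20000, gt=0)
    target_drugs: list[TargetDrugParams] = Field(
        default_factory=lambda: [
            TargetDrugParams(name="IBUPROFEN", exposure_prob=0.05,
                             planted_rr=1.33, onset_median_days=5.0),
            TargetDrugParams(name="PARACETAMOL", exposure_prob=0.05,
                             planted_rr=2.38, onset_median_days=2.0),
        ])
    target_pts: list[tuple[str, int]] = Field(
        default_factory=lambda: list(KIDNEY_INJURY_PTS))
    background_drugs: list[str] = Field(default_factory=lambda: list(BACKGROUND_DRUGS))
    baseline_event_prob: float = Field(default=0.02, gt=0, lt=1)
    duplicate_rate: float = Field(default=0.5, ge=0)  # expected extra versions/case
    missing_date_rate: float = Field(default=0.25, ge=0, le=1)
    partial_date_rate: float = Field(default=0.10, ge=0, le=1)
    dose_report_rate: float = Field(default=0.5, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self):
        for t in self.target_drugs:
            if self.baseline_event_prob * t.planted_rr > 1:
                raise ValueError(
                    f"target drug {t.name}: baseline_event_prob * planted_rr = "
                    f"{self.baseline_event_prob * t.planted_rr:.3f} > 1; "
                    "the planted event probability is not a probability")
        names = [t.name.upper() for t in self.target_drugs]
        if len(set(names)) != len(names):
            raise ValueError("target drug names must be distinct")
        return self


# --------------------------------------------------------------------------
# Cell-level planting (shared by the full generator and fast simulations)
# --------------------------------------------------------------------------


def cell_probabilities(exposure_prob: float, baseline_event_prob: float,
                       planted_rr: float) -> tuple[float, float, float, float]:
    """Per-report probabilities of the four contingency cells (a, b, c, d)."""
    p1 = min(1.0, baseline_event_prob * planted_rr)
    p0 = baseline_event_prob
    pe = exposure_prob
    return (pe * p1, (1 - pe) * p0, pe * (1 - p1), (1 - pe) * (1 - p0))


def simulate_cells(n_reports: int, exposure_prob: float,
                   baseline_event_prob: float, planted_rr: float,
                   rng: np.random.Generator) -> ContingencyTable:
    """Draw one universe's contingency cells directly (no table files).

    Uses the same per-report planting model as :func:`generate`; suitable
    for replicate-heavy calibration studies where writing and re-parsing
    quarterly tables would add nothing.
    """
    probs = cell_probabilities(exposure_prob, baseline_event_prob, planted_rr)
    a, b, c, d = rng.multinomial(n_reports, probs)
    return ContingencyTable(int(a), int(b), int(c), int(d))


# --------------------------------------------------------------------------
# Full table generation
# --------------------------------------------------------------------------


def _choice(rng: np.random.Generator, options: Sequence[str],
            probs: Sequence[float], size: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(options, dtype=object), size=size, p=p / p.sum())


def _fmt_dates(days: np.ndarray, missing: np.ndarray, partial: np.ndarray
               ) -> list[str]:
    """Render day offsets from the window start as (possibly degraded) FAERS dates."""
    dates = WINDOW_START + days.astype("timedelta64[D]")
    out = []
    for i, d in enumerate(dates):
        if missing[i]:
            out.append("")
            continue
        s = pd.Timestamp(d).strftime("%Y%m%d")
        out.append(s[:6] if partial[i] else s)
    return out


def generate(params: SyntheticParams, out_dir: str | Path | None = None,
             dialect: str = "csv") -> tuple[RawTables, pd.DataFrame, dict]:
    """Generate a synthetic universe.

    Returns ``(tables, ledger, ground_truth)``.  The ledger has one row per
    case (the latest version) with its true cell per target drug, suicide
    flag, true onset and duplicate count.  ``ground_truth`` carries derived
    bookkeeping (per-drug cell counts, complication counters, flow counts).
    When ``out_dir`` is given the six tables are also written there
    (``demo.csv`` ... or ``demo.txt`` "$"-delimited for ``faers_ascii``).
    """
    n = params.n_reports
    streams = np.random.SeedSequence(params.seed).spawn(7)
    rng_struct, rng_demo, rng_dates, rng_reac, rng_outc, rng_dose, rng_dup = (
        np.random.default_rng(s) for s in streams)

    drugs = params.target_drugs
    k = len(drugs)
    # exposure and event planting
    exposed = np.zeros((n, k), dtype=bool)
    for j, t in enumerate(drugs):
        exposed[:, j] = rng_struct.random(n) < t.exposure_prob
    p_event = np.full(n, params.baseline_event_prob)
    for j, t in enumerate(drugs):
        p_event = np.where(exposed[:, j], np.minimum(1.0, p_event * t.planted_rr),
                           p_event)
    event = rng_struct.random(n) < p_event
    suicide = np.zeros((n, k), dtype=bool)
    for j, t in enumerate(drugs):
        suicide[:, j] = exposed[:, j] & (rng_struct.random(n) < t.suicide_rate)

    # identifiers: CASEID and latest-version PRIMARYID (version 1 + extras)
    caseids = np.arange(10_000_001, 10_000_001 + n)
    n_dups = rng_dup.poisson(params.duplicate_rate, size=n)
    primaryids = caseids * 10 + 1 + n_dups  # final version number

    # demographics
    bands = _choice(rng_demo, list(AGE_BAND_PROBS), list(AGE_BAND_PROBS.values()), n)
    ages, age_units = [], []
    u = rng_demo.random(n)
    for i, band in enumerate(bands):
        if band == "Unknown":
            ages.append("")
            age_units.append("")
        else:
            lo, hi = AGE_BAND_RANGES[band]
            ages.append(f"{lo + u[i] * (hi - lo):.1f}")
            age_units.append("YR")
    sexes = _choice(rng_demo, list(SEX_PROBS), list(SEX_PROBS.values()), n)
    countries = _choice(rng_demo, list(COUNTRY_PROBS), list(COUNTRY_PROBS.values()), n)
    reporters = _choice(rng_demo, list(REPORTER_PROBS), list(REPORTER_PROBS.values()), n)

    # dates: receipt always day-precise; start/event degraded by configured rates
    window_days = int((WINDOW_END - WINDOW_START) / np.timedelta64(1, "D"))
    fda_days = rng_dates.integers(400, window_days + 1, size=n)
    start_days = fda_days - rng_dates.integers(10, 365, size=n)  # per-report anchor
    onset_true = np.full((n, k), np.nan)
    for j, t in enumerate(drugs):
        mask = exposed[:, j] & event
        m = int(mask.sum())
        if m:
            draw = rng_dates.lognormal(math.log(t.onset_median_days),
                                       t.onset_sigma, size=m)
            onset_true[mask, j] = np.round(draw)
    # the event date follows the earliest exposed drug's start + its onset
    event_days = fda_days - rng_dates.integers(0, 100, size=n)  # default anchor
    has_onset = ~np.isnan(onset_true).all(axis=1)
    first_j = np.argmax(~np.isnan(onset_true), axis=1)
    onset_first = np.where(has_onset, onset_true[np.arange(n), first_j], np.nan)
    # all exposed drugs share the report's start anchor, so the onset encoded
    # in the event date is the same for each of them
    for j in range(k):
        mask = ~np.isnan(onset_true[:, j]) & has_onset
        onset_true[mask, j] = onset_first[mask]
    event_days = np.where(has_onset, start_days + np.nan_to_num(onset_first),
                          event_days).astype(int)

    miss_ev = rng_dates.random(n) < params.missing_date_rate
    part_ev = rng_dates.random(n) < params.partial_date_rate
    miss_st = rng_dates.random(n) < params.missing_date_rate
    part_st = rng_dates.random(n) < params.partial_date_rate
    # reports without any target event rarely state an event date
    miss_ev |= ~event & (rng_dates.random(n) < 0.5)

    event_dt = _fmt_dates(event_days, miss_ev, part_ev)
    start_dt = _fmt_dates(start_days, miss_st, part_st)
    fda_dt = _fmt_dates(fda_days, np.zeros(n, bool), np.zeros(n, bool))

    # reactions
    pt_names = np.array([nm for nm, _ in params.target_pts], dtype=object)
    pt_codes = np.array([str(cd) for _, cd in params.target_pts], dtype=object)
    bg_names = np.array([nm for nm, _, _ in BACKGROUND_PTS], dtype=object)
    bg_codes = np.array([str(cd) for _, cd, _ in BACKGROUND_PTS], dtype=object)
    bg_w = np.array([w for _, _, w in BACKGROUND_PTS])
    bg_p = bg_w / bg_w.sum()

    reac_pid, reac_pt, reac_cd = [], [], []
    complications: list[Counter] = [Counter() for _ in range(k)]
    n_bg = rng_reac.poisson(1.0, size=n)
    n_bg[~event] = np.maximum(n_bg[~event], 1)  # reactions must be non-empty
    target_idx = rng_reac.integers(0, len(pt_names), size=n)
    for i in range(n):
        pid = primaryids[i]
        if event[i]:
            reac_pid.append(pid)
            reac_pt.append(pt_names[target_idx[i]])
            reac_cd.append(pt_codes[target_idx[i]])
        picks = rng_reac.choice(len(bg_names), size=n_bg[i], replace=False, p=bg_p) \
            if n_bg[i] else []
        for b in picks:
            reac_pid.append(pid)
            reac_pt.append(bg_names[b])
            reac_cd.append(bg_codes[b])
            if event[i]:
                for j in range(k):
                    if exposed[i, j]:
                        complications[j][str(bg_names[b])] += 1

    # outcomes
    outc_pid, outc_cod = [], []
    for code in OUTCOME_PROBS_TARGET:  # fixed code order for determinism
        p = np.where(event, OUTCOME_PROBS_TARGET[code], OUTCOME_PROBS_OTHER[code])
        hit = rng_outc.random(n) < p
        outc_pid.extend(primaryids[hit])
        outc_cod.extend([code] * int(hit.sum()))

    # drugs, therapy dates, indications
    drug_rows: list[tuple] = []   # (pid, seq, name, role, start, dose, unit)
    ther_rows: list[tuple] = []   # (pid, seq, start)
    indi_rows: list[tuple] = []   # (pid, seq, term)
    n_bg_drugs = 1 + rng_struct.poisson(1.0, size=n)
    bg_drug_pool = np.array(params.background_drugs, dtype=object)
    bg_roles = np.array(["C", "SS", "I"], dtype=object)
    suicide_term_idx = rng_dose.integers(0, len(SUICIDE_INDICATIONS), size=n)
    benign_idx = rng_dose.integers(0, len(BENIGN_INDICATIONS), size=n)
    benign_has = rng_dose.random(n) < 0.5
    dose_reported = rng_dose.random((n, k)) < params.dose_report_rate
    therapeutic = rng_dose.choice([200.0, 400.0, 600.0, 800.0, 1200.0], size=(n, k))
    for i in range(n):
        pid = primaryids[i]
        seq = 0
        any_suicide = suicide[i].any()
        for j, t in enumerate(drugs):
            if not exposed[i, j]:
                continue
            seq += 1
            if suicide[i, j]:
                grams = float(np.round(rng_dose.lognormal(
                    math.log(t.suicide_dose_median_grams), 0.6), 1))
                dose_amt, dose_unit = f"{grams:g}", "G"
            elif dose_reported[i, j]:
                dose_amt, dose_unit = f"{therapeutic[i, j]:g}", "MG"
            else:
                dose_amt, dose_unit = "", ""
            drug_rows.append((pid, seq, t.name, "PS", start_dt[i], dose_amt, dose_unit))
            if start_dt[i]:
                ther_rows.append((pid, seq, start_dt[i]))
            if suicide[i, j]:
                indi_rows.append((pid, seq, SUICIDE_INDICATIONS[suicide_term_idx[i]]))
            elif benign_has[i]:
                indi_rows.append((pid, seq, BENIGN_INDICATIONS[benign_idx[i]]))
        picks = rng_struct.choice(len(bg_drug_pool), size=n_bg_drugs[i], replace=False) \
            if n_bg_drugs[i] <= len(bg_drug_pool) else range(len(bg_drug_pool))
        for m, b in enumerate(picks):
            seq += 1
            role = "PS" if (seq == 1 and m == 0) else str(
                bg_roles[rng_struct.integers(0, len(bg_roles))])
            drug_rows.append((pid, seq, bg_drug_pool[b], role, "", "", ""))
        if not any_suicide and not benign_has[i] and seq:
            pass  # no indication row for this report

    demo = pd.DataFrame({
        "PRIMARYID": primaryids, "CASEID": caseids, "FDA_DT": fda_dt,
        "EVENT_DT": event_dt, "AGE": ages, "AGE_COD": age_units,
        "SEX": sexes, "REPORTER_COUNTRY": countries, "OCCP_COD": reporters,
    })
    drug = pd.DataFrame(drug_rows, columns=["PRIMARYID", "DRUG_SEQ", "DRUGNAME",
                                            "ROLE_COD", "START_DT", "DOSE_AMT",
                                            "DOSE_UNIT"])
    reac = pd.DataFrame({"PRIMARYID": reac_pid, "PT": reac_pt, "PT_CD": reac_cd})
    outc = pd.DataFrame({"PRIMARYID": outc_pid, "OUTC_COD": outc_cod})
    indi = pd.DataFrame(indi_rows, columns=["PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"])
    ther = pd.DataFrame(ther_rows, columns=["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"])

    # duplicate case versions: same content, earlier receipt, lower version no.
    dup_frames = {name: [df] for name, df in
                  (("demo", demo), ("drug", drug), ("reac", reac),
                   ("outc", outc), ("indi", indi), ("ther", ther))}
    dup_idx = np.nonzero(n_dups)[0]
    if dup_idx.size:
        dup_case_rows, dup_pids, dup_fda = [], [], []
        for i in dup_idx:
            back = int(rng_dup.integers(30, 400))
            for v in range(1, n_dups[i] + 1):
                dup_case_rows.append(i)
                dup_pids.append(caseids[i] * 10 + v)
                dup_fda.append(max(fda_days[i] - back * (n_dups[i] - v + 1), 0))
        dup_demo = demo.iloc[dup_case_rows].copy()
        dup_demo["PRIMARYID"] = dup_pids
        dup_demo["FDA_DT"] = _fmt_dates(np.array(dup_fda),
                                        np.zeros(len(dup_fda), bool),
                                        np.zeros(len(dup_fda), bool))
        dup_frames["demo"].append(dup_demo)
        orig_pid_of_dup = primaryids[dup_case_rows]
        for name, df in (("drug", drug), ("reac", reac), ("outc", outc),
                         ("indi", indi), ("ther", ther)):
            groups = df.groupby("PRIMARYID", sort=False).indices
            rows, new_pids = [], []
            for orig_pid, new_pid in zip(orig_pid_of_dup, dup_pids):
                idx = groups.get(orig_pid)
                if idx is None:
                    continue
                rows.extend(idx)
                new_pids.extend([new_pid] * len(idx))
            child = df.iloc[rows].copy()
            child["PRIMARYID"] = new_pids
            dup_frames[name].append(child)

    def _concat(name):
        df = pd.concat(dup_frames[name], ignore_index=True)
        return df.sort_values("PRIMARYID", kind="stable").reset_index(drop=True)

    tables = RawTables(**{name: _concat(name).astype(str) for name in
                          ("demo", "drug", "reac", "outc", "indi", "ther")})

    # ledger: per-case truth (refers to the latest version, the dedup answer)
    ledger_cols: dict[str, object] = {
        "caseid": caseids.astype(str), "primaryid": primaryids.astype(str),
        "event": event, "n_duplicates": n_dups,
    }
    for j, t in enumerate(drugs):
        cell = np.where(exposed[:, j] & event, "a",
                        np.where(event, "b", np.where(exposed[:, j], "c", "d")))
        ledger_cols[f"exposed_{t.name}"] = exposed[:, j]
        ledger_cols[f"cell_{t.name}"] = cell
        ledger_cols[f"suicide_{t.name}"] = suicide[:, j]
        ledger_cols[f"onset_days_{t.name}"] = onset_true[:, j]
    ledger = pd.DataFrame(ledger_cols)

    ground_truth = {
        "n_cases": n,
        "n_raw_reports": int(n + n_dups.sum()),
        "cells": {t.name: {c: int((ledger[f"cell_{t.name}"] == c).sum())
                           for c in "abcd"} for t in drugs},
        "suicide_counts": {t.name: int(suicide[:, j].sum())
                           for j, t in enumerate(drugs)},
        "complications": {t.name: dict(complications[j])
                          for j, t in enumerate(drugs)},
        "onset_true_median": {
            t.name: (float(np.nanmedian(onset_true[:, j]))
                     if np.isfinite(onset_true[:, j]).any() else None)
            for j, t in enumerate(drugs)},
    }

    if out_dir is not None:
        write_tables(tables, out_dir, dialect)
        ledger.to_csv(Path(out_dir) / "ledger.csv", index=False)
    return tables, ledger, ground_truth


def write_tables(tables: RawTables, out_dir: str | Path, dialect: str = "csv"
                 ) -> dict[str, Path]:
    """Write the six tables; returns the per-table paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep, ext = ("$", "txt") if dialect == "faers_ascii" else (",", "csv")
    paths = {}
    for name, df in tables:
        p = out_dir / f"{name}.{ext}"
        df.to_csv(p, sep=sep, index=False, lineterminator="\n")
        paths[name] = p
    return paths


# --------------------------------------------------------------------------
# Ledger-side estimates
# --------------------------------------------------------------------------


def empirical_rr(ledger: pd.DataFrame, drug_name: str) -> float:
    """Realized risk ratio of the target event given exposure, from the ledger.

    ``[a/(a+c)] / [b/(b+d)]`` over the true cell assignments; the yardstick
    recovery tests compare pipeline estimates against, net of sampling noise
    in the planting itself.
    """
    cells = ledger[f"cell_{drug_name}"].value_counts()
    a, b, c, d = (int(cells.get(x, 0)) for x in "abcd")
    if (a + c) == 0 or (b + d) == 0:
        # one margin is empty (e.g. every report exposed): the conditional
        # comparison is vacuous and the realized RR is 1 by construction
        return 1.0
    if b == 0:
        raise ValueError("no unexposed events: risk ratio undefined")
    return (a / (a + c)) / (b / (b + d))
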