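"""Reading, assembly and deduplication of FAERS-style quarterly tables.

The FDA Adverse Event Reporting System (FAERS) publishes quarterly snapshots
as seven "$"-delimited ASCII tables.  This module handles the six used here
(DEMO, DRUG, REAC, OUTC, INDI, THER), merges them by report identifier
(``PRIMARYID``) into :class:`CaseReport` records, and removes duplicate case
versions so that each ``CASEID`` contributes a single report.

Dates in FAERS are written ``YYYYMMDD`` but are frequently truncated to
``YYYYMM`` or ``YYYY``; :class:`PartialDate` keeps the stated precision
explicit so that downstream analyses (time-to-onset in particular) can
exclude imprecise dates instead of silently imputing a day.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("faerspv")

# --------------------------------------------------------------------------
# Partial calendar dates
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True, order=False)
class PartialDate:
    """A calendar date known to year, month or day precision."""

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @classmethod
    def parse(cls, text: str | None) -> "PartialDate | None":
        """Parse ``YYYY``, ``YYYYMM`` or ``YYYYMMDD``; ``None`` if unparseable."""
        if text is None:
            return None
        s = str(text).strip()
        if s.endswith(".0"):  # numeric passthrough from loosely typed sources
            s = s[:-2]
        if not s or not s.isdigit():
            return None
        try:
            if len(s) == 8:
                d = date(int(s[:4]), int(s[4:6]), int(s[6:8]))
                return cls(d.year, d.month, d.day)
            if len(s) == 6:
                y, m = int(s[:4]), int(s[4:6])
                if not 1 <= m <= 12:
                    return None
                return cls(y, m)
            if len(s) == 4:
                return cls(int(s))
        except ValueError:
            return None
        return None

    def to_date(self) -> date | None:
        """A :class:`datetime.date`, only when day precision is available."""
        if self.day is None:
            return None
        return date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    @classmethod
    def from_isoformat(cls, text: str | None) -> "PartialDate | None":
        if not text:
            return None
        parts = text.split("-")
        y = int(parts[0])
        m = int(parts[1]) if len(parts) > 1 else None
        d = int(parts[2]) if len(parts) > 2 else None
        return cls(y, m, d)


def _date_key(d: PartialDate | None) -> tuple[int, int, int]:
    # missing dates sort earliest (before any real year)
    return d.sort_key() if d is not None else (-1, 0, 0)


# --------------------------------------------------------------------------
# Report data model
# --------------------------------------------------------------------------

DRUG_ROLES = ("PS", "SS", "C", "I")  # primary suspect, secondary, concomitant, interacting
OUTCOME_CODES = ("DE", "HO", "LT", "DS", "CA", "RI", "OT")
AGE_UNITS = ("DEC", "YR", "MON", "WK", "DY", "HR")


@dataclass(slots=True)
class DrugEntry:
    """One drug line of a report."""

    name: str
    role: str  # PS / SS / C / I
    start_date: PartialDate | None = None
    dose_grams: float | None = None
    indication: str | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "role": self.role,
            "start_date": self.start_date.isoformat() if self.start_date else None,
            "dose_grams": self.dose_grams,
            "indication": self.indication,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugEntry":
        return cls(
            name=d["name"],
            role=d["role"],
            start_date=PartialDate.from_isoformat(d.get("start_date")),
            dose_grams=d.get("dose_grams"),
            indication=d.get("indication"),
        )


@dataclass(slots=True)
class Reaction:
    """A MedDRA Preferred Term, by name and (optionally) numeric code."""

    name: str
    code: int | None = None

    def to_dict(self) -> dict:
        return {"name": self.name, "code": self.code}

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        return cls(name=d["name"], code=d.get("code"))


@dataclass(slots=True)
class CaseReport:
    """One assembled spontaneous report (one FAERS case version)."""

    primaryid: str
    caseid: str
    version_date: PartialDate | None = None  # FDA receipt date of this version
    event_date: PartialDate | None = None
    age_value: float | None = None
    age_unit: str | None = None  # DEC / YR / MON / WK / DY / HR
    sex: str | None = None  # F / M
    country: str | None = None
    reporter: str | None = None  # CN / LW / PH / MD / OT
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    outcomes: set[str] = field(default_factory=set)
    indications: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "primaryid": self.primaryid,
            "caseid": self.caseid,
            "version_date": self.version_date.isoformat() if self.version_date else None,
            "event_date": self.event_date.isoformat() if self.event_date else None,
            "age_value": self.age_value,
            "age_unit": self.age_unit,
            "sex": self.sex,
            "country": self.country,
            "reporter": self.reporter,
            "drugs": [d.to_dict() for d in self.drugs],
            "reactions": [r.to_dict() for r in self.reactions],
            "outcomes": sorted(self.outcomes),
            "indications": list(self.indications),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        return cls(
            primaryid=d["primaryid"],
            caseid=d["caseid"],
            version_date=PartialDate.from_isoformat(d.get("version_date")),
            event_date=PartialDate.from_isoformat(d.get("event_date")),
            age_value=d.get("age_value"),
            age_unit=d.get("age_unit"),
            sex=d.get("sex"),
            country=d.get("country"),
            reporter=d.get("reporter"),
            drugs=[DrugEntry.from_dict(x) for x in d.get("drugs", [])],
            reactions=[Reaction.from_dict(x) for x in d.get("reactions", [])],
            outcomes=set(d.get("outcomes", [])),
            indications=list(d.get("indications", [])),
        )


@dataclass(slots=True)
class RawTables:
    """The six quarterly tables as normalized DataFrames (string cells)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame

    def __iter__(self):
        yield from (("demo", self.demo), ("drug", self.drug), ("reac", self.reac),
                    ("outc", self.outc), ("indi", self.indi), ("ther", self.ther))


# --------------------------------------------------------------------------
# Table schemas and reading
# --------------------------------------------------------------------------

TABLE_NAMES = ("demo", "drug", "reac", "outc", "indi", "ther")

#: Required columns per table; tuples denote "any one of these" alternatives.
REQUIRED_COLUMNS: dict[str, list] = {
    "demo": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
             ("SEX", "GNDR_COD"), ("OCCR_COUNTRY", "REPORTER_COUNTRY"), "OCCP_COD"],
    "drug": ["PRIMARYID", "DRUGNAME", "ROLE_COD"],
    "reac": ["PRIMARYID", "PT"],
    "outc": ["PRIMARYID", "OUTC_COD"],
    "indi": ["PRIMARYID", "INDI_PT"],
    "ther": ["PRIMARYID", "START_DT"],
}

OPTIONAL_COLUMNS: dict[str, list[str]] = {
    "demo": [],
    "drug": ["DRUG_SEQ", "PROD_AI", "START_DT", "DOSE_AMT", "DOSE_UNIT"],
    "reac": ["PT_CD"],
    "outc": [],
    "indi": ["INDI_DRUG_SEQ"],
    "ther": ["DSG_DRUG_SEQ"],
}


class SchemaError(ValueError):
    """A table is missing, or lacks required columns."""


def _read_one(path: Path, sep: str, table: str) -> pd.DataFrame:
    bad_rows: list = []

    def _on_bad(row):  # pragma: no cover - exercised only on malformed input
        bad_rows.append(row)
        return None

    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                         encoding="utf-8", engine="python", on_bad_lines=_on_bad)
    except UnicodeDecodeError:
        # historical FAERS quarters mix encodings; retry per-file as latin-1
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                         encoding="latin-1", engine="python", on_bad_lines=_on_bad)
    if bad_rows:
        logger.warning("%s: %d unparseable rows skipped", table.upper(), len(bad_rows))
    df.columns = [c.strip().upper() for c in df.columns]
    missing = []
    for req in REQUIRED_COLUMNS[table]:
        alts = req if isinstance(req, tuple) else (req,)
        if not any(a in df.columns for a in alts):
            missing.append("|".join(alts))
    if missing:
        raise SchemaError(
            f"table {table.upper()} at {path}: missing required column(s) "
            f"{missing}; expected schema: {REQUIRED_COLUMNS[table]} "
            f"(optional: {OPTIONAL_COLUMNS[table]})"
        )
    return df


def read_tables(paths: Mapping[str, str | Path], dialect: str = "auto") -> RawTables:
    """Read the six quarterly tables.

    Parameters
    ----------
    paths
        Mapping with keys ``demo, drug, reac, outc, indi, ther`` to file paths.
    dialect
        ``"faers_ascii"`` ("$"-delimited), ``"csv"``, or ``"auto"`` to sniff
        the delimiter from each file's header line.
    """
    if dialect not in ("auto", "faers_ascii", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frames = {}
    for table in TABLE_NAMES:
        if table not in paths:
            raise SchemaError(f"no path given for required table {table.upper()}")
        path = Path(paths[table])
        if not path.exists():
            raise SchemaError(f"table {table.upper()}: file not found: {path}")
        if dialect == "auto":
            with open(path, "rb") as fh:
                header = fh.readline().decode("latin-1")
            sep = "$" if "$" in header else ","
        else:
            sep = "$" if dialect == "faers_ascii" else ","
        frames[table] = _read_one(path, sep, table)
    return RawTables(**frames)


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

_DOSE_UNIT_TO_GRAMS = {"G": 1.0, "GM": 1.0, "GRAM": 1.0, "MG": 1e-3, "KG": 1e3,
                       "UG": 1e-6, "MCG": 1e-6}


def dose_to_grams(amount: str | float | None, unit: str | None) -> float | None:
    """Convert a reported dose to grams; unknown units count as missing."""
    if amount is None or str(amount).strip() == "":
        return None
    try:
        value = float(amount)
    except ValueError:
        return None
    u = (unit or "").strip().upper()
    if u not in _DOSE_UNIT_TO_GRAMS:
        if u:
            logger.warning("unknown dose unit %r treated as missing", u)
        return None
    return value * _DOSE_UNIT_TO_GRAMS[u]


def _clean(s: str | None) -> str | None:
    if s is None:
        return None
    s = str(s).strip()
    return s or None


def _group_rows(df: pd.DataFrame) -> dict[str, list[dict]]:
    if df.empty:
        return {}
    out: dict[str, list[dict]] = {}
    cols = list(df.columns)
    for row in df.itertuples(index=False):
        rec = dict(zip(cols, row))
        out.setdefault(str(rec["PRIMARYID"]).strip(), []).append(rec)
    return out


def assemble_reports(tables: RawTables) -> list[CaseReport]:
    """Merge the six tables into one :class:`CaseReport` per ``PRIMARYID``.

    Child rows whose ``PRIMARYID`` is absent from DEMO are logged and
    skipped.  Output is sorted by ``PRIMARYID`` for determinism.
    """
    demo = tables.demo
    sex_col = "SEX" if "SEX" in demo.columns else ("GNDR_COD" if "GNDR_COD" in demo.columns else None)
    country_col = ("OCCR_COUNTRY" if "OCCR_COUNTRY" in demo.columns
                   else ("REPORTER_COUNTRY" if "REPORTER_COUNTRY" in demo.columns else None))

    children = {name: _group_rows(getattr(tables, name))
                for name in ("drug", "reac", "outc", "indi", "ther")}
    known: set[str] = set()
    reports: list[CaseReport] = []
    for row in demo.itertuples(index=False):
        rec = dict(zip(demo.columns, row))
        pid = str(rec["PRIMARYID"]).strip()
        known.add(pid)
        age_value: float | None = None
        raw_age = _clean(rec.get("AGE"))
        if raw_age is not None:
            try:
                age_value = float(raw_age)
            except ValueError:
                age_value = None
            if age_value is not None and age_value < 0:
                logger.warning("report %s: negative age %s treated as missing", pid, raw_age)
                age_value = None
        report = CaseReport(
            primaryid=pid,
            caseid=str(rec["CASEID"]).strip(),
            version_date=PartialDate.parse(_clean(rec.get("FDA_DT"))),
            event_date=PartialDate.parse(_clean(rec.get("EVENT_DT"))),
            age_value=age_value,
            age_unit=_clean(rec.get("AGE_COD")),
            sex=_clean(rec.get(sex_col)) if sex_col else None,
            country=_clean(rec.get(country_col)) if country_col else None,
            reporter=_clean(rec.get("OCCP_COD")),
        )
        # therapy start dates, keyed by drug sequence number when available
        ther_by_seq: dict[str | None, PartialDate] = {}
        for t in children["ther"].get(pid, []):
            seq = _clean(t.get("DSG_DRUG_SEQ"))
            d = PartialDate.parse(_clean(t.get("START_DT")))
            if d is not None and seq not in ther_by_seq:
                ther_by_seq[seq] = d
        indi_by_seq: dict[str | None, str] = {}
        for i in children["indi"].get(pid, []):
            term = _clean(i.get("INDI_PT"))
            if term is None:
                continue
            report.indications.append(term)
            seq = _clean(i.get("INDI_DRUG_SEQ"))
            indi_by_seq.setdefault(seq, term)
        for d in children["drug"].get(pid, []):
            name = _clean(d.get("DRUGNAME")) or _clean(d.get("PROD_AI"))
            if name is None:
                continue
            seq = _clean(d.get("DRUG_SEQ"))
            start = PartialDate.parse(_clean(d.get("START_DT")))
            if start is None:
                start = ther_by_seq.get(seq)
            report.drugs.append(DrugEntry(
                name=name,
                role=(_clean(d.get("ROLE_COD")) or "C").upper(),
                start_date=start,
                dose_grams=dose_to_grams(_clean(d.get("DOSE_AMT")), _clean(d.get("DOSE_UNIT"))),
                indication=indi_by_seq.get(seq),
            ))
        seen_pts: set[tuple[str, int | None]] = set()
        for r in children["reac"].get(pid, []):
            name = _clean(r.get("PT"))
            if name is None:
                continue
            code_raw = _clean(r.get("PT_CD"))
            code = int(code_raw) if code_raw and code_raw.isdigit() else None
            key = (name.upper(), code)
            if key in seen_pts:
                continue
            seen_pts.add(key)
            report.reactions.append(Reaction(name=name, code=code))
        for o in children["outc"].get(pid, []):
            code = _clean(o.get("OUTC_COD"))
            if code:
                report.outcomes.add(code.upper())
        reports.append(report)

    orphans = sum(len(v) for name in ("drug", "reac", "outc", "indi", "ther")
                  for k, v in children[name].items() if k not in known)
    if orphans:
        logger.warning("%d child rows referenced a PRIMARYID absent from DEMO; skipped", orphans)
    reports.sort(key=lambda r: r.primaryid)
    return reports


# --------------------------------------------------------------------------
# Deduplication
# --------------------------------------------------------------------------


def deduplicate_cases(reports: Sequence[CaseReport]) -> list[CaseReport]:
    """Keep one report per ``CASEID``: the latest FDA receipt date.

    Ties on receipt date are broken by the numerically larger ``PRIMARYID``
    (later case version).  Missing receipt dates sort earliest.  Output is
    sorted by ``PRIMARYID``.
    """

    def _pid_key(pid: str) -> tuple[int, str]:
        return (int(pid), "") if pid.isdigit() else (0, pid)

    best: dict[str, CaseReport] = {}
    for r in reports:
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
            continue
        key_new = (_date_key(r.version_date), _pid_key(r.primaryid))
        key_cur = (_date_key(cur.version_date), _pid_key(cur.primaryid))
        if key_new > key_cur:
            best[r.caseid] = r
    kept = sorted(best.values(), key=lambda r: r.primaryid)
    removed = len(reports) - len(kept)
    if removed:
        logger.info("deduplication removed %d duplicate case versions (%d kept)",
                    removed, len(kept))
    return kept


# --------------------------------------------------------------------------
# Interchange format (line-delimited JSON)
# --------------------------------------------------------------------------


def write_reports(reports: Iterable[CaseReport], path: str | Path) -> None:
    """Write assembled reports as line-delimited JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(json.dumps(r.to_dict(), separators=(",", ":")) + "\n")


def read_reports(path: str | Path) -> list[CaseReport]:
    """Read reports written by :func:`write_reports`."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(CaseReport.from_dict(json.loads(line)))
    return out
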