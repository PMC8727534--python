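"""Disproportionality statistics and signal criteria.

Four statistics are screened per drug-event pair, all functions of the 2x2
cells ``a, b, c, d`` (``N = a+b+c+d``):

* **ROR** (reporting odds ratio) ``= (a/b)/(c/d)`` with the lognormal 95% CI
  ``exp(ln ROR +/- 1.96*s)``, ``s = sqrt(1/a + 1/b + 1/c + 1/d)``;
  positive when the CI lower bound exceeds 1 and ``a >= 2``.
* **PRR** (proportional reporting ratio) ``= [a/(a+c)] / [b/(b+d)]`` with the
  four-cell Pearson chi-square; positive when ``PRR >= 2``, ``chi2 >= 4`` and
  ``a >= 3``.
* **BCPNN information component** ``IC = log2( a*N / ((a+c)(a+b)) )``, the
  log2 observed-over-expected co-reporting ratio; positive when its 95%
  lower bound ``IC025`` exceeds 0.
* **MGPS** ``EBGM = a*N / ((a+c)(a+b)) = 2^IC`` with the one-sided 90% lower
  bound ``EB05 = EBGM * exp(-1.64*s)``; positive when ``EB05 >= 2`` and
  ``a > 0``.

A pair is a positive signal when at least one of the four criteria is met.

The IC lower bound is computed on the additive log2 scale by default,
``IC025 = IC - 1.96*s/ln 2``, which is null-calibrated (under independence
it exceeds 0 in well under 5% of universes).  Some published screens instead
print the multiplicative form ``IC * exp(-1.96*s)``; that variant is
available as ``ic025_method="multiplicative"`` for comparison with such
tables, but it is positive whenever IC > 0 and therefore cannot serve as a
decision rule (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .cohort import CohortConfig, ContingencyTable, build_contingency

Z95 = 1.96  # two-sided 95%
Z90_ONE_SIDED = 1.64  # one-sided 95% (lower 90% two-sided)
LN2 = math.log(2.0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as printed pharmacovigilance tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Scores
# --------------------------------------------------------------------------


@dataclass(slots=True)
class SignalScores:
    """Computed statistics for one drug-event pair.

    Members are ``None`` when undefined (zero cells, non-positive IC for the
    multiplicative bound); ``notes`` records why.
    """

    n_cooccurrence: int
    ror: float | None = None
    ror_ci95: tuple[float, float] | None = None
    prr: float | None = None
    chi2: float | None = None
    ic: float | None = None
    ic025: float | None = None
    ebgm: float | None = None
    eb05: float | None = None
    notes: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class SignalCriteria:
    """Per-algorithm decision flags; ``any_positive`` is their OR."""

    ror_positive: bool
    prr_positive: bool
    bcpnn_positive: bool
    mgps_positive: bool

    @property
    def any_positive(self) -> bool:
        return (self.ror_positive or self.prr_positive
                or self.bcpnn_positive or self.mgps_positive)


def _cells(t: ContingencyTable, continuity_correction: bool):
    """Cell values as floats, optionally Haldane-corrected; None if unusable."""
    if continuity_correction and min(t.a, t.b, t.c, t.d) == 0:
        return t.with_continuity_correction()
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    return (float(t.a), float(t.b), float(t.c), float(t.d))


def _se_log(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def compute_ror(t: ContingencyTable, continuity_correction: bool = False
                ) -> tuple[float | None, tuple[float, float] | None]:
    """Reporting odds ratio with its lognormal 95% CI."""
    cells = _cells(t, continuity_correction)
    if cells is None:
        return None, None
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    se = _se_log(a, b, c, d)
    ci = (ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))
    return ror, ci


def compute_prr(t: ContingencyTable, continuity_correction: bool = False,
                yates: bool = False) -> tuple[float | None, float | None]:
    """Proportional reporting ratio and the four-cell Pearson chi-square.

    The chi-square statistic sums ``(O-E)^2/E`` over all four cells with
    expectations from the row x column margins; ``yates`` applies the
    continuity-corrected ``(|O-E|-0.5)^2/E`` form.
    """
    cells = _cells(t, continuity_correction)
    if cells is None:
        return None, None
    a, b, c, d = cells
    n = a + b + c + d
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return None, None
    prr = (a / (a + c)) / (b / (b + d))
    chi2 = 0.0
    for obs, row, col in ((a, a + c, a + b), (b, b + d, a + b),
                          (c, a + c, c + d), (d, b + d, c + d)):
        expected = row * col / n
        dev = abs(obs - expected)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / expected
    return prr, chi2


def compute_bcpnn(t: ContingencyTable, continuity_correction: bool = False,
                  ic025_method: str = "log2"
                  ) -> tuple[float | None, float | None]:
    """Information component and its 95% lower bound.

    ``ic025_method="log2"`` (default): ``IC - 1.96*s/ln2`` on the additive
    log2 scale.  ``"multiplicative"``: ``IC * exp(-1.96*s)``, defined only
    for IC > 0.
    """
    if ic025_method not in ("log2", "multiplicative"):
        raise ValueError(f"unknown ic025_method {ic025_method!r}")
    cells = _cells(t, continuity_correction)
    if cells is None:
        return None, None
    a, b, c, d = cells
    n = a + b + c + d
    ic = math.log2(a * n / ((a + c) * (a + b)))
    se = _se_log(a, b, c, d)
    if ic025_method == "log2":
        ic025 = ic - Z95 * se / LN2
    else:
        ic025 = ic * math.exp(-Z95 * se) if ic > 0 else None
    return ic, ic025


def compute_mgps(t: ContingencyTable, continuity_correction: bool = False
                 ) -> tuple[float | None, float | None]:
    """Observed-over-expected ratio (EBGM form) and its one-sided lower bound."""
    cells = _cells(t, continuity_correction)
    if cells is None:
        return None, None
    a, b, c, d = cells
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    eb05 = ebgm * math.exp(-Z90_ONE_SIDED * _se_log(a, b, c, d))
    return ebgm, eb05


def score_table(t: ContingencyTable, continuity_correction: bool = False,
                ic025_method: str = "log2") -> SignalScores:
    """All four statistics for one contingency table."""
    s = SignalScores(n_cooccurrence=t.a)
    if min(t.a, t.b, t.c, t.d) == 0 and not continuity_correction:
        s.notes["zero_cell"] = (
            "one or more cells are zero and no continuity correction was "
            "requested; all statistics undefined")
        return s
    s.ror, s.ror_ci95 = compute_ror(t, continuity_correction)
    s.prr, s.chi2 = compute_prr(t, continuity_correction)
    s.ic, s.ic025 = compute_bcpnn(t, continuity_correction, ic025_method)
    if s.ic is not None and s.ic025 is None:
        s.notes["ic025"] = "multiplicative bound undefined for IC <= 0"
    s.ebgm, s.eb05 = compute_mgps(t, continuity_correction)
    return s


def evaluate_criteria(s: SignalScores) -> SignalCriteria:
    """Apply the four decision rules; undefined members never satisfy one."""
    n = s.n_cooccurrence
    ror_pos = (s.ror_ci95 is not None and s.ror_ci95[0] > 1.0 and n >= 2)
    prr_pos = (s.prr is not None and s.chi2 is not None
               and s.prr >= 2.0 and s.chi2 >= 4.0 and n >= 3)
    bcpnn_pos = s.ic025 is not None and s.ic025 > 0.0
    mgps_pos = s.eb05 is not None and s.eb05 >= 2.0 and n > 0
    return SignalCriteria(ror_pos, prr_pos, bcpnn_pos, mgps_pos)


# --------------------------------------------------------------------------
# Batch screening
# --------------------------------------------------------------------------

SIGNAL_TABLE_COLUMNS = [
    "pair", "drug", "event_set", "a", "b", "c", "d",
    "ROR", "ROR_low", "ROR_high", "PRR", "chi2", "IC", "IC025",
    "EBGM", "EB05", "ror_positive", "prr_positive", "bcpnn_positive",
    "mgps_positive", "any_positive", "notes",
]


def screen_pairs(reports: Sequence, drug_configs: Iterable[CohortConfig],
                 pt_sets: Sequence[tuple[str, list[tuple[str, int]]]] | None = None,
                 continuity_correction: bool = False,
                 ic025_method: str = "log2") -> pd.DataFrame:
    """Score every (drug config, PT set) pair over a deduplicated universe.

    When ``pt_sets`` is None each config is screened against its own target
    PT set.  Returns one row per pair in deterministic (input) order; rows
    with undefined statistics carry the reason in ``notes``.
    """
    rows = []
    for config in drug_configs:
        if pt_sets is None:
            pairs = [(config.drug_name + ":target", config.target_pts)]
        else:
            pairs = [(label, pts) for label, pts in pt_sets]
        for label, pts in pairs:
            cfg = config.model_copy(update={"target_pts": list(pts)})
            t = build_contingency(reports, cfg)
            s = score_table(t, continuity_correction, ic025_method)
            crit = evaluate_criteria(s)
            rows.append({
                "pair": f"{config.drug_name}|{label}",
                "drug": config.drug_name,
                "event_set": label,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ROR": s.ror,
                "ROR_low": s.ror_ci95[0] if s.ror_ci95 else None,
                "ROR_high": s.ror_ci95[1] if s.ror_ci95 else None,
                "PRR": s.prr, "chi2": s.chi2, "IC": s.ic, "IC025": s.ic025,
                "EBGM": s.ebgm, "EB05": s.eb05,
                "ror_positive": crit.ror_positive,
                "prr_positive": crit.prr_positive,
                "bcpnn_positive": crit.bcpnn_positive,
                "mgps_positive": crit.mgps_positive,
                "any_positive": crit.any_positive,
                "notes": "; ".join(f"{k}: {v}" for k, v in s.notes.items()),
            })
    return pd.DataFrame(rows, columns=SIGNAL_TABLE_COLUMNS)


def format_signal_table(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Presentation copy with statistics rounded half-up to ``ndigits``."""
    out = df.copy()
    for col in ("ROR", "ROR_low", "ROR_high", "PRR", "chi2", "IC", "IC025",
                "EBGM", "EB05"):
        out[col] = out[col].map(
            lambda x: round_half_up(x, ndigits) if x is not None and pd.notna(x) else x)
    return out
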