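"""Time-to-onset analysis.

Onset is the whole-day interval from the earliest primary-suspect start
date of the target drug to the adverse-event onset date.  Both dates must
be stated to day precision; reports with missing or truncated dates, or
with the event dated strictly before the drug start, are excluded with an
explicit reason rather than imputed.  Same-day start and event counts as
onset 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortConfig, _target_entries
from .io import CaseReport

EXCLUSION_REASONS = ("missing_date", "partial_date", "event_before_start", "none")

#: Default histogram bin edges (days), right-inclusive, last bin open.
DEFAULT_ONSET_BINS = (0, 30, 60, 90, 120)


@dataclass(frozen=True, slots=True)
class OnsetRecord:
    caseid: str
    onset_days: int | None
    included: bool
    exclusion_reason: str  # one of EXCLUSION_REASONS


@dataclass(frozen=True, slots=True)
class OnsetSummary:
    n_included: int
    median_days: float
    iqr: tuple[float, float]
    mean_days: float


def compute_onset(report: CaseReport, config: CohortConfig) -> OnsetRecord:
    """Onset for one drug-matched report, or the reason it is excluded."""
    entries = _target_entries(report, config)
    starts = [d.start_date for d in entries if d.start_date is not None]
    event = report.event_date
    if event is None or not starts:
        return OnsetRecord(report.caseid, None, False, "missing_date")
    start = min(starts, key=lambda d: d.sort_key())
    if event.precision != "day" or start.precision != "day":
        return OnsetRecord(report.caseid, None, False, "partial_date")
    delta = (event.to_date() - start.to_date()).days
    if delta < 0:
        return OnsetRecord(report.caseid, None, False, "event_before_start")
    return OnsetRecord(report.caseid, int(delta), True, "none")


def compute_onsets(cohort: Sequence[CaseReport],
                   config: CohortConfig) -> list[OnsetRecord]:
    return [compute_onset(r, config) for r in cohort]


def exclusion_counts(records: Sequence[OnsetRecord]) -> dict[str, int]:
    """Counts per exclusion reason; 'none' counts the included records."""
    out = {reason: 0 for reason in EXCLUSION_REASONS}
    for rec in records:
        out[rec.exclusion_reason] += 1
    return out


def onset_summary(records: Sequence[OnsetRecord]) -> OnsetSummary:
    """Median, IQR (linear-interpolation quartiles) and mean of included onsets."""
    days = np.array([r.onset_days for r in records if r.included], dtype=float)
    if days.size == 0:
        raise ValueError("no included onset records; summary undefined")
    q1, med, q3 = np.percentile(days, [25, 50, 75])
    return OnsetSummary(int(days.size), float(med), (float(q1), float(q3)),
                        float(days.mean()))


def compare_onset(records_1: Sequence[OnsetRecord],
                  records_2: Sequence[OnsetRecord]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (tie-corrected) between two onset groups.

    Returns ``(U1, p)`` where U1 is the statistic of the first group.
    """
    x = [r.onset_days for r in records_1 if r.included]
    y = [r.onset_days for r in records_2 if r.included]
    if not x or not y:
        raise ValueError("both groups need at least one included onset record")
    # exact null distribution for small tie-free groups, tie-corrected
    # normal approximation otherwise
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def onset_histogram(records: Sequence[OnsetRecord],
                    bins: Sequence[int] = DEFAULT_ONSET_BINS) -> pd.DataFrame:
    """Binned onset counts: (0-30, 31-60, ..., >last] by default."""
    days = [r.onset_days for r in records if r.included]
    edges = list(bins)
    labels = [f"{edges[i] + (1 if i else 0)}-{edges[i + 1]}"
              for i in range(len(edges) - 1)] + [f">{edges[-1]}"]
    counts = [0] * len(labels)
    for d in days:
        for i in range(len(edges) - 1):
            lo = edges[i] + (1 if i else 0)
            if lo <= d <= edges[i + 1]:
                counts[i] += 1
                break
        else:
            counts[-1] += 1
    return pd.DataFrame({"bin_days": labels, "count": counts})


def onset_table(records: Sequence[OnsetRecord]) -> pd.DataFrame:
    """Per-case onset CSV layout: caseid, onset_days, exclusion_reason."""
    return pd.DataFrame(
        [{"caseid": r.caseid, "onset_days": r.onset_days,
          "exclusion_reason": r.exclusion_reason} for r in records],
        columns=["caseid", "onset_days", "exclusion_reason"])


def plot_onset_histogram(records: Sequence[OnsetRecord], path: str,
                         bins: Sequence[int] = DEFAULT_ONSET_BINS,
                         title: str = "Time to onset") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = onset_histogram(records, bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist["bin_days"], hist["count"], color="#4878a8")
    ax.set_xlabel("days from drug start to event onset")
    ax.set_ylabel("reports")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
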