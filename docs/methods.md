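# Methods

## Data model and ingestion

FAERS quarterly snapshots arrive as "$"-delimited ASCII tables (DEMO, DRUG,
REAC, OUTC, INDI, THER) keyed by `PRIMARYID` (one report version) and
`CASEID` (one case, possibly several versions). The reader accepts that
dialect or CSV equivalents with the same column names (case-insensitive),
requires only the column subset the pipeline uses, and ignores extra
columns — real quarters carry many more. Files are read as UTF-8 with a
per-file latin-1 fallback, since historical quarters mix encodings.
Unparseable rows are counted and logged, never silently dropped.

Dates are kept as *partial dates* with explicit precision (`YYYY`,
`YYYYMM`, `YYYYMMDD`). Nothing in the pipeline imputes a missing month or
day; analyses that need day precision (time-to-onset) exclude imprecise
dates with an explicit reason instead. Start dates missing from DRUG are
back-filled from THER via the drug sequence number.

**Deduplication.** One report per `CASEID` is retained: the version with
the latest FDA receipt date, ties broken by the numerically larger
`PRIMARYID`, missing receipt dates sorting earliest. This is the standard
keep-latest-version rule for quarterly files; it is deterministic and
idempotent, and the retained count always equals the number of distinct
case identifiers.

## Cohort selection

A report belongs to a drug cohort when a drug entry with the
**primary-suspect (PS) role** matches the configured brand/generic synonym
list after normalization (uppercase, punctuation stripped, trailing
dose/form tokens such as `200MG TABLET` removed, then exact match —
substring matching is deliberately avoided because verbatim drug strings
embed each other). Event membership is matched by MedDRA PT code when a
code is present, by name otherwise. The default target set is 17
kidney-injury PTs (acute kidney injury, renal impairment, anuria, ...);
"Dialysis" names a procedure rather than an injury but is kept by default
and can be dropped with `CohortConfig.without_pt`.

Only PS-role matches count as exposure anywhere in the pipeline, including
cell `a` of the 2×2 table; non-PS mentions of the target drug fall in
`b`/`d` like any other report. The study window (default
2004-01-01..2021-03-31, configurable) filters on the FDA receipt date;
reports with unknown receipt dates are retained.

**Suicide subset.** A case is flagged as intentional-overdose use when any
indication term contains one of the configured self-harm terms
(case-insensitive substring: suicide attempt, intentional overdose,
poisoning deliberate, ...) or when the summed reported dose of the target
drug exceeds the configured threshold (default 12 g — ten times a typical
maximum daily ibuprofen dose). Dose amounts with unknown units are treated
as missing and logged. The *flag* uses a strict `>` on the threshold; the
descriptive threshold count in `dose_summary` is inclusive (`>=`), matching
how published listings count "no less than" a dose.

## Disproportionality statistics

All four statistics are closed forms of the cells `a, b, c, d`
(`N = a+b+c+d`, `s = sqrt(1/a+1/b+1/c+1/d)`): the reporting odds ratio with
lognormal 95% CI (z = 1.96 exactly, as screening tables print it), the
proportional reporting ratio with the four-cell Pearson χ² (expectations
from row×column margins; the printed one-cell `O = a` form extends to all
four cells, which is the universal PRR practice; Yates correction
available by flag, off by default), the information component
`IC = log2(a·N/((a+c)(a+b)))`, and `EBGM = 2^IC` with
`EB05 = EBGM·e^(−1.64·s)`.

**IC lower bound.** Some published screening tables print
`IC025 = IC·e^(−1.96·s)`, a multiplicative bound applied to a quantity that
already lives on a log scale. That form is positive whenever IC > 0, so the
BCPNN decision rule "IC025 > 0" degenerates to "observed > expected" and
fires in roughly half of all null universes — it cannot discriminate. The
default here is the additive bound on the log2 scale,
`IC025 = IC − 1.96·s/ln 2`, which is null-calibrated (well under 5% false
positives under independence) and coheres with the other bounds:
`2^IC025 = EBGM·e^(−1.96·s)`, the same shrink-down form as the ROR CI and
EB05. The multiplicative variant remains available
(`ic025_method="multiplicative"`) for comparing against tables that print
it; it is reported, never used as the default criterion. Neither form is
the canonical Bayesian BCPNN posterior or the gamma-Poisson MGPS fit —
those are out of scope by design; the closed forms above are what screening
tables actually print.

**Zero cells.** By default any zero cell renders the statistics undefined,
with the reason recorded; criteria treat undefined members as not met. An
optional Haldane-style +0.5 continuity correction to all four cells can be
enabled for small synthetic tables. Presentation tables round half-up to 2
decimals; internal values keep full precision.

## Descriptive analysis

Ages are converted to years (DEC×10, MON÷12, WK÷52.18, DY÷365.25, HR÷8766)
and banded `<18, 18–44, 45–64, 65–74, >74, Unknown`; negative or
unit-less ages are Unknown. Percentages are reported over the whole cohort
and, for age and sex, also over the known-only denominator, since published
series quote both; a derived 65+ aggregate row is emitted separately so
single-valued characteristics still sum to 100%. Countries map to seven
world regions through a bundled ISO-3166 table; unmapped codes are Unknown.
Outcome counts use both denominators (all cases; cases with ≥1 recorded
outcome) because a case may carry several outcome codes and published
outcome percentages are not always consistent with either denominator —
both are reported rather than forced to agree.

Two-group rate comparisons default to the two-sided Fisher exact test;
Pearson's χ² is used when requested and all expected counts are ≥ 5 (else
it falls back to Fisher with a note). Quartiles (dose and onset IQRs) use
linear interpolation between order statistics (NumPy's default, "type 7");
published IQRs rarely state a convention, so one is fixed and documented.
Complication rankings count cohort reports mentioning each non-target PT,
descending, ties alphabetical.

## Time to onset

Onset is `event_date − earliest PS-role start date` of the target drug, in
whole days. Both dates must have day precision; exclusion reasons are
`missing_date`, `partial_date`, and `event_before_start` (strictly negative
differences only — same-day onset is 0 and included, which is consistent
with published IQR lower bounds of 0). Included counts plus per-reason
exclusions always sum to the cohort size. Group comparison is the
two-sided Mann–Whitney U: exact (permutation) null distribution for small
tie-free groups, tie-corrected normal approximation otherwise.

## Synthetic report generator

The generator emulates per-report demographics, one-or-more drug entries
with roles/start dates/doses, reaction PTs, outcome codes, indications,
duplicate case versions, and partial/missing dates, with a configurable
planted drug–event association. Per report and target drug: exposure is
Bernoulli(`exposure_prob`) (writing a PS-role entry), and the target event
occurs with probability `baseline_event_prob` unexposed versus
`baseline_event_prob·planted_rr` exposed (validated ≤ 1). Exposed evented
cases draw a true onset from a log-normal — default medians 5 days
(ibuprofen-like) and 2 days (acetaminophen-like), log-scale σ = 1.5, a
long-right-tail shape typical of reported onsets — rounded to whole days
and linking start to event date *before* date degradation (missing- and
partial-date rates, defaults 0.25/0.10, roughly FAERS-like) is applied.
Duplicates add Poisson(`duplicate_rate`, default 0.5) earlier versions per
case with identical content, so keep-latest deduplication has a unique
correct answer; the default rate mirrors the ~3:2 raw-to-deduplicated ratio
seen in practice. Planted suicides (rate 2% of exposed) receive a
self-harm indication and a gram-scale overdose; other exposed entries get
therapeutic milligram doses or none. Demographic category distributions
default to values shaped like OTC-analgesic case series (heavy
European/North-American reporting, ~12–17% unknowns).

A per-case ledger records the true cell, suicide flag, true onset and
duplicate count; `ground_truth` adds per-drug cell totals and complication
counters. Identical parameters (including seed) yield byte-identical
files; independent RNG streams are spawned per concern so extending one
table never perturbs another.

**What the generator does not emulate:** real FAERS reporting volumes and
their secular trends, drug co-prescription structure, country-specific
reporting cultures, verbatim free-text drug strings, or duplicates with
*different* CASEIDs but overlapping content (the hard deduplication
problem). Passing tests therefore demonstrate correctness of the
machinery under a known data-generating process, not that real-data
screening results are unbiased — disproportionality on spontaneous
reports remains subject to reporting bias and confounding regardless of
implementation.

## Replicate studies and problem sizes

Calibration and recovery studies that need hundreds of universes use
`simulate_cells`, the generator's cell-level planting model (one
multinomial draw per universe over the four cell probabilities), rather
than writing and re-parsing full table sets; a file-level universe in the
test suite anchors the two paths by checking that pipeline recounts equal
the ledger exactly. Sizes used: null specificity at 50,000 reports × 200
replicates (flagged fraction ≤ 5%); χ² null calibration at 2,000
replicates against P(χ² ≥ 4) = 0.0455; planted-RR-2.4 recovery at
marginals sized for a ≈ 1,000 over 50 replicates (median EBGM/ROR within
10% — exposure 4% and baseline event rate 2% keep both the odds-ratio
and observed-over-expected estimands within a few percent of the planted
risk ratio); onset recovery on ~9,000-case file-level universes yielding
≥ 1,000 included onsets per group.

## Known limitations

* Drug matching is exact post-normalization against a static synonym list;
  misspelled verbatims and combination products are out of scope.
* The MedDRA hierarchy is not traversed; target sets are flat PT lists
  supplied by configuration.
* No shrinkage estimation (gamma-Poisson EM, Bayesian IC posterior): the
  printed closed forms only.
* Cross-CASEID duplicate detection (same patient, different case) is not
  attempted; only version-level deduplication is performed.
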