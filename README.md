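# faerspv

Pharmacovigilance signal screening for FAERS-style spontaneous adverse-event
reports, built around the worked example of ibuprofen- and
acetaminophen-associated kidney injury.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) hold millions of voluntary reports, each linking suspect drugs to
MedDRA-coded reactions. Because there is no denominator of drug use,
associations are screened by *disproportionality*: a drug–event pair is
compared against the rest of the database through the 2×2 table

|              | target event | other events |
|--------------|--------------|--------------|
| target drug  | a            | c            |
| other drugs  | b            | d            |

This package is aimed at pharmacoepidemiologists and pharmacovigilance
analysts who want that screening workflow as reusable, tested code rather
than ad-hoc spreadsheets: quarterly-table ingestion and case deduplication,
cohort selection by drug synonym (primary-suspect role only) and target PT
set, four disproportionality statistics with their decision criteria,
descriptive case-series tables, time-to-onset analysis, and a synthetic
report generator with planted ground truth for end-to-end validation.

## Statistics

With `N = a+b+c+d` and `s = sqrt(1/a + 1/b + 1/c + 1/d)`:

| Algorithm | Statistic | Positive signal when |
|-----------|-----------|----------------------|
| ROR | `(a/b)/(c/d)`, 95% CI `exp(ln ROR ± 1.96·s)` | CI low > 1 and `a ≥ 2` |
| PRR | `[a/(a+c)]/[b/(b+d)]`, four-cell Pearson χ² | PRR ≥ 2, χ² ≥ 4, `a ≥ 3` |
| BCPNN | `IC = log2(a·N/((a+c)(a+b)))`, `IC025 = IC − 1.96·s/ln 2` | IC025 > 0 |
| MGPS | `EBGM = a·N/((a+c)(a+b)) = 2^IC`, `EB05 = EBGM·e^(−1.64·s)` | EB05 ≥ 2, `a > 0` |

A pair is reported as a signal when **any** of the four criteria is met.
See `docs/methods.md` for the variant IC lower bound some published tables
print and why it is not used as the decision rule.

## Worked example

Generate a synthetic 20,000-case universe with two target drugs planted at
relative risks 1.33 (ibuprofen-like) and 2.38 (acetaminophen-like), then run
the full pipeline:

```python
import faerspv as fp

params = fp.SyntheticParams(n_reports=20_000, seed=0)
tables, ledger, truth = fp.generate(params)
reports = fp.deduplicate_cases(fp.assemble_reports(tables))

df = fp.screen_pairs(reports, [fp.ibuprofen_config(), fp.acetaminophen_config()])
print(fp.format_signal_table(df)[["drug", "a", "b", "c", "d", "ROR",
                                  "ROR_low", "EBGM", "IC025", "any_positive"]])
```

which prints (seed 0):

```
         drug  a   b   c     d  ROR  ROR_low  EBGM  IC025  any_positive
    ibuprofen 30 370 981 18619 1.54     1.05  1.48   0.02          True
acetaminophen 40 360 955 18645 2.17     1.55  2.01   0.53          True
```

The generator planted 29,951 raw report versions that deduplicate back to
exactly 20,000 cases, and the 2×2 cells recomputed by the pipeline equal
the generator's ledger exactly. Both planted signals are flagged; the
stronger acetaminophen-like signal shows the larger ROR/EBGM, with
estimates scattered around the planted values as expected at `a ≈ 30–40`
co-occurrences.

Time-to-onset for the acetaminophen-like cohort in the same universe
(onset planted log-normal with median 2 days):

```
APAP onset: n=22 median=2.0 IQR=(1.0, 4.75) mean=6.2
exclusions: {'missing_date': 12, 'partial_date': 6, 'event_before_start': 0, 'none': 22}
```

Every case is accounted for: included onsets plus the per-reason exclusion
counts sum to the cohort size, and truncated (month- or year-precision)
dates are excluded, never imputed.

The same stages are available from the shell:

```bash
faerspv synth --out data/ --n-reports 20000 --seed 0
faerspv assemble --data-dir data/ --out reports.jsonl
faerspv screen --reports reports.jsonl --out signals.csv
faerspv describe --reports reports.jsonl --drug ibuprofen --out-dir tables/
faerspv onset --reports reports.jsonl --drug acetaminophen --out-dir tables/
```

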