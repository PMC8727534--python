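"""Demographics, outcome rates, rate comparisons, doses, complications."""

from collections import Counter
from math import comb

import pytest

from faerspv import (assign_age_band, compare_rates, complication_ranking,
                     demographics_table, dose_summary, extract_target_doses,
                     ibuprofen_config, outcome_rates, round_half_up)
from faerspv.descriptive import COUNTRY_TO_REGION, age_in_years
from faerspv.reference import (ACETAMINOPHEN_SUICIDE_DOSES_G, AGE_COUNTS,
                               IBUPROFEN_SUICIDE_DOSES_G)

from conftest import make_report

IBU = ibuprofen_config()


# --------------------------------------------------------------------------
# Age banding
# --------------------------------------------------------------------------


@pytest.mark.parametrize("value, unit, band", [
    (17.9, "YR", "<18"),
    (18.0, "YR", "18-44"),
    (216, "MON", "18-44"),     # 216 months = 18 years
    (2, "DEC", "18-44"),       # 2 decades = 20 years
    (100, "WK", "<18"),
    (700, "DY", "<18"),
    (64.9, "YR", "45-64"),
    (74.9, "YR", "65-74"),
    (75, "YR", ">74"),
    (None, None, "Unknown"),
    (-5, "YR", "Unknown"),
    (40, "XX", "Unknown"),     # unknown unit code
])
def test_assign_age_band(value, unit, band):
    assert assign_age_band(value, unit) == band


def test_age_unit_conversion_factors():
    assert age_in_years(8766, "HR") == pytest.approx(1.0)
    assert age_in_years(52.18, "WK") == pytest.approx(1.0)
    assert age_in_years(365.25, "DY") == pytest.approx(1.0)


# --------------------------------------------------------------------------
# Demographics table
# --------------------------------------------------------------------------


def test_demographics_counts_match_manual_recount(universe):
    cohort = universe["reports"][:1500]
    table = demographics_table(cohort)
    bands = Counter(assign_age_band(r.age_value, r.age_unit) for r in cohort)
    age_rows = table.table[table.table["characteristic"] == "age"]
    assert dict(zip(age_rows["category"], age_rows["count"])) == \
        {b: bands.get(b, 0) for b in age_rows["category"]}
    regions = Counter(COUNTRY_TO_REGION.get((r.country or "").upper(), "Unknown")
                      for r in cohort)
    region_rows = table.table[table.table["characteristic"] == "region"]
    assert dict(zip(region_rows["category"], region_rows["count"])) == \
        {c: regions.get(c, 0) for c in region_rows["category"]}


def test_demographics_percentage_closure(universe):
    table = demographics_table(universe["reports"][:1500]).table
    for char in ("age", "sex", "region", "reporter"):
        rows = table[table["characteristic"] == char]
        assert rows["count"].sum() == 1500
        assert abs(rows["pct"].sum() - 100.0) <= 0.05 * len(rows)


def test_demographics_known_only_denominator(universe):
    table = demographics_table(universe["reports"][:1500]).table
    known = table[(table["characteristic"].isin(["age", "sex"]))
                  & (table["category"] != "Unknown")]
    assert (known["pct_known"] >= known["pct"]).all()


def test_demographics_published_count_percentages():
    """The printed <18 ibuprofen count over the cohort size gives 17.57%."""
    n = sum(AGE_COUNTS["ibuprofen"].values())
    assert n == 2453
    assert round_half_up(100 * AGE_COUNTS["ibuprofen"]["<18"] / n) == 17.57
    known = n - AGE_COUNTS["ibuprofen"]["Unknown"]
    assert round_half_up(100 * AGE_COUNTS["ibuprofen"]["45-64"] / known) == 27.76


def test_demographics_empty_cohort():
    table = demographics_table([])
    assert (table.table["count"] == 0).all()
    assert (table.table["pct"] == 0.0).all()


def test_demographics_age_aggregate_row(universe):
    t = demographics_table(universe["reports"][:1500])
    age = t.table[t.table["characteristic"] == "age"].set_index("category")
    agg = t.aggregates.iloc[0]
    assert agg["category"] == "65+"
    assert agg["count"] == age.loc["65-74", "count"] + age.loc[">74", "count"]


# --------------------------------------------------------------------------
# Outcome rates
# --------------------------------------------------------------------------


def test_outcome_rates_enumeration():
    cohort = [make_report(primaryid=str(i), caseid=str(i), reactions=["x"],
                          outcomes=o)
              for i, o in enumerate([{"DE"}, {"HO"}, {"DE", "HO"}, set()])]
    rates = outcome_rates(cohort)
    assert rates.counts["DE"] == 2 and rates.counts["HO"] == 2
    assert rates.rate_all["DE"] == pytest.approx(2 / 4)
    assert rates.rate_with_outcome["DE"] == pytest.approx(2 / 3)


def test_outcome_rates_no_outcomes_flagged():
    cohort = [make_report(reactions=["x"])]
    rates = outcome_rates(cohort)
    assert rates.n_with_outcome == 0
    assert rates.rate_with_outcome["DE"] is None
    assert rates.note is not None


# --------------------------------------------------------------------------
# Rate comparisons
# --------------------------------------------------------------------------


def fisher_p_by_enumeration(k1, n1, k2, n2):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    m = k1 + k2  # successes total, fixed margins
    n = n1 + n2

    def pmf(k):
        if k < 0 or k > n1 or m - k > n2:
            return 0.0
        return comb(n1, k) * comb(n2, m - k) / comb(n, m)

    p_obs = pmf(k1)
    return min(1.0, sum(pmf(k) for k in range(0, m + 1)
                        if pmf(k) <= p_obs * (1 + 1e-12)))


def test_identical_groups_p_is_one():
    assert compare_rates(5, 10, 5, 10).p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    res = compare_rates(9, 10, 1, 10)
    assert res.test_name == "fisher_exact"
    assert res.p_value == pytest.approx(fisher_p_by_enumeration(9, 10, 1, 10),
                                        rel=1e-9)


def test_fisher_oracle_sweep_small_tables():
    for (k1, n1, k2, n2) in [(0, 5, 5, 5), (3, 8, 1, 12), (7, 15, 7, 15),
                             (2, 4, 9, 11), (0, 12, 0, 14), (6, 6, 0, 9)]:
        res = compare_rates(k1, n1, k2, n2)
        assert res.p_value == pytest.approx(
            fisher_p_by_enumeration(k1, n1, k2, n2), rel=1e-9), (k1, n1, k2, n2)


def test_published_fatality_rates_differ():
    res = compare_rates(178, 2453, 570, 1288)
    assert res.p_value < 1e-4
    assert res.rate1 == pytest.approx(178 / 2453)


def test_pearson_chi2_and_small_count_fallback():
    res = compare_rates(100, 400, 150, 400, method="pearson_chi2")
    assert res.test_name == "pearson_chi2" and res.statistic > 0
    res2 = compare_rates(1, 5, 4, 5, method="pearson_chi2")
    assert res2.test_name == "fisher_exact" and res2.note is not None


def test_compare_rates_input_validation():
    with pytest.raises(ValueError):
        compare_rates(1, 0, 1, 5)
    with pytest.raises(ValueError):
        compare_rates(6, 5, 1, 5)


# --------------------------------------------------------------------------
# Dose summaries
# --------------------------------------------------------------------------


def test_published_ibuprofen_dose_listing():
    s = dose_summary(IBUPROFEN_SUICIDE_DOSES_G, threshold_grams=12)
    assert s.n == 20
    assert s.median_grams == pytest.approx(12.0)
    assert s.count_at_or_above_threshold == 11


def test_published_acetaminophen_dose_listing():
    s = dose_summary(ACETAMINOPHEN_SUICIDE_DOSES_G, threshold_grams=16)
    assert s.n == 33
    assert s.count_at_or_above_threshold == 23
    # computed median of the listed doses (27 g)
    assert s.median_grams == pytest.approx(27.0)


def test_dose_summary_single_and_missing():
    s = dose_summary([5.0, None, None], threshold_grams=12)
    assert (s.n, s.n_missing) == (1, 2)
    assert s.median_grams == 5.0 and s.iqr == (5.0, 5.0)
    empty = dose_summary([None], threshold_grams=12)
    assert empty.median_grams is None and empty.note is not None


def test_extract_target_doses_sums_target_entries_only():
    r = make_report(drugs=[("IBUPROFEN", "PS", None, 9.0),
                           ("IBUPROFEN", "PS", None, 4.0),
                           ("WARFARIN", "C", None, 50.0)],
                    reactions=["x"])
    assert extract_target_doses([r], IBU) == [13.0]
    r2 = make_report(drugs=[("IBUPROFEN", "PS")], reactions=["x"])
    assert extract_target_doses([r2], IBU) == [None]


# --------------------------------------------------------------------------
# Complications
# --------------------------------------------------------------------------


def test_complication_vomiting_ranks_first():
    cohort = []
    for i in range(174):
        cohort.append(make_report(
            primaryid=str(i), caseid=str(i),
            reactions=[("Acute kidney injury", 10069339), "Vomiting"]))
    for i in range(174, 174 + 127):
        cohort.append(make_report(
            primaryid=str(i), caseid=str(i),
            reactions=[("Acute kidney injury", 10069339), "Hypotension"]))
    ranked = complication_ranking(cohort, IBU.target_pts)
    assert ranked.iloc[0]["pt"] == "Vomiting"
    assert ranked.iloc[0]["count"] == 174
    assert ranked.iloc[1]["pt"] == "Hypotension"


def test_complication_ties_alphabetical_and_topk():
    cohort = [make_report(primaryid=str(i), caseid=str(i),
                          reactions=[("Anuria", 10002847), "Zoster", "Ague"])
              for i in range(3)]
    ranked = complication_ranking(cohort, IBU.target_pts, top_k=1)
    assert list(ranked["pt"]) == ["Ague"]


def test_complication_none_outside_target():
    cohort = [make_report(reactions=[("Anuria", 10002847)])]
    assert complication_ranking(cohort, IBU.target_pts).empty


def test_complication_ranking_matches_generator_truth(universe):
    from faerspv import build_cohorts
    cases = build_cohorts(universe["reports"], [IBU])["ibuprofen"].cases
    ranked = complication_ranking(cases, IBU.target_pts, top_k=None)
    truth = universe["truth"]["complications"]["IBUPROFEN"]
    assert dict(zip(ranked["pt"], ranked["count"])) == truth
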