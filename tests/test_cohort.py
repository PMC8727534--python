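"""Cohort selection, suicide flagging and 2x2 table construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv import (CohortConfig, acetaminophen_config, assemble_reports,
                     build_cohorts, build_contingency, deduplicate_cases,
                     flag_suicide, ibuprofen_config, match_target_drug,
                     match_target_event, normalize_drug_name)

from conftest import make_report

IBU = ibuprofen_config()
APAP = acetaminophen_config()


# --------------------------------------------------------------------------
# Drug matching
# --------------------------------------------------------------------------


@pytest.mark.parametrize("name, role, expected", [
    ("IBUPROFEN", "PS", True),
    ("ibuprofen 200mg tablet", "PS", True),   # dose/form tokens stripped
    ("Advil", "PS", True),
    ("Advil", "C", False),                    # concomitant role never matches
    ("NUROFEN 400 MG CAPSULE", "PS", True),
    ("NAPROXEN", "PS", False),
    ("IBUPROFEN LYSINE", "PS", True),
])
def test_match_target_drug(name, role, expected):
    report = make_report(drugs=[(name, role)], reactions=["Nausea"])
    assert match_target_drug(report, IBU) is expected


def test_normalization_strips_trailing_tokens_only():
    assert normalize_drug_name("Ibuprofen 200mg Tablet") == "IBUPROFEN"
    assert normalize_drug_name("advil") == "ADVIL"
    # an embedded word is not a match: normalization is not substring search
    report = make_report(drugs=[("IBUPROFENOL COMPOUND", "PS")],
                         reactions=["Nausea"])
    assert not match_target_drug(report, IBU)


# --------------------------------------------------------------------------
# Event matching
# --------------------------------------------------------------------------


@pytest.mark.parametrize("reactions, expected", [
    ([("Some coded term", 10069339)], True),          # acute kidney injury code
    (["Nausea"], False),
    (["Tubulointerstitial nephritis"], True),          # name match, no code
    ([("Tubulointerstitial nephritis", 99999999)], False),  # code wins over name
    (["acute KIDNEY injury"], True),                   # case-insensitive name
])
def test_match_target_event(reactions, expected):
    report = make_report(reactions=reactions)
    assert match_target_event(report, IBU) is expected


def test_dialysis_pt_can_be_dropped():
    cfg = IBU.without_pt("Dialysis")
    assert len(cfg.target_pts) == len(IBU.target_pts) - 1
    report = make_report(reactions=[("Dialysis", 10061105)])
    assert match_target_event(report, IBU)
    assert not match_target_event(report, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(drug_synonyms=[], target_pts=[("x", 1)])
    with pytest.raises(ValueError):
        CohortConfig(drug_synonyms=["x"], target_pts=[("x", 1)],
                     suicide_dose_threshold_grams=0)


# --------------------------------------------------------------------------
# Suicide flag
# --------------------------------------------------------------------------


@pytest.mark.parametrize("indications, dose, expected", [
    (["Suicide attempt"], None, True),
    (["Pyrexia"], 0.6, False),
    ([], 15.0, True),            # dose above the 12 g threshold
    ([], 12.0, False),           # threshold is strict for the flag
    (["INTENTIONAL OVERDOSE"], None, True),  # case-insensitive substring
])
def test_flag_suicide(indications, dose, expected):
    report = make_report(drugs=[("PARACETAMOL", "PS", None, dose)],
                         reactions=["Nausea"], indications=indications)
    assert flag_suicide(report, APAP) is expected


def test_flag_suicide_ignores_non_target_drug_dose():
    report = make_report(drugs=[("WARFARIN", "PS", None, 99.0),
                                ("PARACETAMOL", "PS", None, 1.0)],
                         reactions=["Nausea"])
    assert not flag_suicide(report, APAP)


# --------------------------------------------------------------------------
# Contingency tables
# --------------------------------------------------------------------------


def _four_cell_universe():
    return [
        make_report(primaryid="1", caseid="1", drugs=[("IBUPROFEN", "PS")],
                    reactions=[("Acute kidney injury", 10069339)]),
        make_report(primaryid="2", caseid="2", drugs=[("WARFARIN", "PS")],
                    reactions=[("Acute kidney injury", 10069339)]),
        make_report(primaryid="3", caseid="3", drugs=[("IBUPROFEN", "PS")],
                    reactions=["Nausea"]),
        make_report(primaryid="4", caseid="4", drugs=[("WARFARIN", "PS")],
                    reactions=["Nausea"]),
    ]


def test_contingency_one_report_per_cell():
    t = build_contingency(_four_cell_universe(), IBU)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    assert t.n == 4


def test_contingency_empty_universe_raises():
    with pytest.raises(ValueError):
        build_contingency([], IBU)


def test_contingency_partition_and_monotonicity():
    universe = _four_cell_universe()
    t0 = build_contingency(universe, IBU)
    universe.append(make_report(primaryid="5", caseid="5",
                                drugs=[("IBUPROFEN", "PS")],
                                reactions=[("Oliguria", 10030302)]))
    t1 = build_contingency(universe, IBU)
    assert (t1.a, t1.b, t1.c, t1.d) == (t0.a + 1, t0.b, t0.c, t0.d)
    assert t1.n == t0.n + 1


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
def test_contingency_matches_brute_force(memberships):
    """Cells equal a brute-force recount of planted (drug, event) flags."""
    reports = []
    for i, (drug, event) in enumerate(memberships):
        reports.append(make_report(
            primaryid=str(i), caseid=str(i),
            drugs=[("IBUPROFEN", "PS") if drug else ("WARFARIN", "PS")],
            reactions=[("Acute kidney injury", 10069339) if event else "Nausea"]))
    t = build_contingency(reports, IBU)
    expected = (
        sum(1 for d, e in memberships if d and e),
        sum(1 for d, e in memberships if not d and e),
        sum(1 for d, e in memberships if d and not e),
        sum(1 for d, e in memberships if not d and not e),
    )
    assert (t.a, t.b, t.c, t.d) == expected
    assert t.n == len(memberships)


def test_contingency_matches_generator_ledger(universe):
    """Pipeline recount over generated files equals the planted truth."""
    for drug, cfg in (("IBUPROFEN", IBU), ("PARACETAMOL", APAP)):
        t = build_contingency(universe["reports"], cfg)
        assert {"a": t.a, "b": t.b, "c": t.c, "d": t.d} == \
            universe["truth"]["cells"][drug]


def test_suicide_exclusion_changes_only_their_cells(universe):
    reports = universe["reports"]
    full = build_contingency(reports, IBU)
    kept = [r for r in reports if not flag_suicide(r, IBU)]
    sub = build_contingency(kept, IBU)
    removed = [r for r in reports if flag_suicide(r, IBU)]
    delta = {"a": 0, "b": 0, "c": 0, "d": 0}
    for r in removed:
        drug = match_target_drug(r, IBU)
        event = match_target_event(r, IBU)
        delta["a" if drug and event else "b" if event else "c" if drug else "d"] += 1
    assert (full.a - sub.a, full.b - sub.b, full.c - sub.c, full.d - sub.d) == \
        (delta["a"], delta["b"], delta["c"], delta["d"])


# --------------------------------------------------------------------------
# Cohort building
# --------------------------------------------------------------------------


def test_cohort_flow_matches_ledger(universe):
    truth = universe["truth"]
    cohorts = build_cohorts(universe["reports"], [IBU, APAP])
    for drug, key in (("IBUPROFEN", "ibuprofen"), ("PARACETAMOL", "acetaminophen")):
        flow = cohorts[key].flow
        cells = truth["cells"][drug]
        assert flow["drug_matched"] == cells["a"] + cells["c"]
        assert flow["drug_and_event"] == cells["a"]
        assert flow["suicide_only"] + flow["suicide_excluded"] == cells["a"]


def test_empty_event_universe_flow():
    reports = [make_report(primaryid=str(i), caseid=str(i),
                           drugs=[("IBUPROFEN", "PS")], reactions=["Nausea"])
               for i in range(5)]
    result = build_cohorts(reports, [IBU])["ibuprofen"]
    assert result.cases == []
    assert result.flow["drug_matched"] == 5
    assert result.flow["drug_and_event"] == 0


def test_report_matching_both_drugs_in_both_cohorts():
    r = make_report(drugs=[("IBUPROFEN", "PS"), ("PARACETAMOL", "PS")],
                    reactions=[("Anuria", 10002847)])
    cohorts = build_cohorts([r], [IBU, APAP])
    assert cohorts["ibuprofen"].cases == [r]
    assert cohorts["acetaminophen"].cases == [r]


def test_dedup_and_suicide_filter_commute(universe):
    """Duplicates share indications, so the two filter orders agree."""
    raw = assemble_reports(universe["tables"])
    a = [r.primaryid for r in deduplicate_cases(raw) if not flag_suicide(r, IBU)]
    pre = [r for r in raw if not flag_suicide(r, IBU)]
    b = [r.primaryid for r in deduplicate_cases(pre)]
    assert a == b
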