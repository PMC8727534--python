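import pytest

from faerspv import (CaseReport, DrugEntry, PartialDate, Reaction,
                     SyntheticParams, assemble_reports, deduplicate_cases,
                     generate)


def make_report(primaryid="1000001", caseid="100000", drugs=(), reactions=(),
                outcomes=(), indications=(), event_date=None, version_date=None,
                **kw) -> CaseReport:
    """Terse CaseReport builder for handcrafted fixtures.

    ``drugs`` entries are (name, role) or (name, role, start_iso) or
    (name, role, start_iso, dose_grams); ``reactions`` entries are names or
    (name, code) pairs.
    """
    drug_entries = []
    for d in drugs:
        name, role, *rest = d
        start = PartialDate.from_isoformat(rest[0]) if rest and rest[0] else None
        dose = rest[1] if len(rest) > 1 else None
        drug_entries.append(DrugEntry(name=name, role=role, start_date=start,
                                      dose_grams=dose))
    reaction_entries = []
    for r in reactions:
        if isinstance(r, str):
            reaction_entries.append(Reaction(name=r))
        else:
            reaction_entries.append(Reaction(name=r[0], code=r[1]))
    return CaseReport(
        primaryid=primaryid, caseid=caseid,
        version_date=PartialDate.from_isoformat(version_date),
        event_date=PartialDate.from_isoformat(event_date),
        drugs=drug_entries, reactions=reaction_entries,
        outcomes=set(outcomes), indications=list(indications), **kw)


@pytest.fixture(scope="session")
def universe():
    """One mid-sized generated universe shared across the suite."""
    params = SyntheticParams(n_reports=4000, seed=7)
    tables, ledger, truth = generate(params)
    reports = deduplicate_cases(assemble_reports(tables))
    return {"params": params, "tables": tables, "ledger": ledger,
            "truth": truth, "reports": reports}
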