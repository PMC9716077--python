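import pytest
from hypothesis import settings

from pvsignal.reports import AEReport, DrugEntry, ReportSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def mk_report(
    rid="R1",
    case="C1",
    version=1,
    quarter="2015Q3",
    drugs=(("ranibizumab", "primary-suspect"),),
    pts=("Macular ischaemia",),
    sex="unknown",
    age=None,
    outcomes=(),
    country="US",
):
    """Terse report factory for hand-built fixtures."""
    return AEReport(
        report_id=rid,
        case_id=case,
        case_version=version,
        receipt_quarter=quarter,
        drugs=[DrugEntry(n, n.lower(), role) for n, role in drugs],
        reactions=list(pts),
        sex=sex,
        age_years=age,
        outcomes=frozenset(outcomes),
        country=country,
    )


@pytest.fixture
def lexicon():
    from pvsignal import DEFAULT_LEXICON

    return dict(DEFAULT_LEXICON)


@pytest.fixture
def four_cell_reports(lexicon):
    """One report per 2×2 cell for ranibizumab × macular ischaemia."""
    return ReportSet([
        mk_report("R1", "C1", pts=("Macular ischaemia",)),
        mk_report("R2", "C2", pts=("Headache",)),
        mk_report("R3", "C3", drugs=(("metformin", "primary-suspect"),), pts=("Macular ischaemia",)),
        mk_report("R4", "C4", drugs=(("metformin", "primary-suspect"),), pts=("Headache",)),
    ])


@pytest.fixture
def smq_map_file(tmp_path):
    rows = [
        ("Macular ischaemia", "Retinal disorders"),
        ("Retinal vasculitis", "Retinal disorders"),
        ("Retinal vasculitis", "Retinal disorders"),  # duplicate row collapses
        ("Endophthalmitis", "Ocular infections"),
        ("Intraocular pressure increased", "Glaucoma"),
        ("Dry eye", "Lacrimal disorders"),
    ]
    p = tmp_path / "smq.tsv"
    p.write_text("pt\tsmq\n" + "\n".join(f"{a}\t{b}" for a, b in rows) + "\n")
    return p
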