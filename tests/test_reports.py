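import pytest

from conftest import mk_report
from pvsignal import (
    ReportSet,
    SyntheticConfig,
    deduplicate,
    filter_primary_suspect,
    generate,
    read_reports,
    write_reports,
)

SIMPLE_HEADER = "report_id\tcase_id\tcase_version\tquarter\tdrug_name\tdrug_role\tpt_list\tsex\tage\toutcomes\tcountry\n"


def _simple_row(rid, case="C", ver=1, quarter="2015Q3", drug="Lucentis", role="PS",
                pts="Macular ischaemia", sex="female", age="70", outcomes="death", country="US"):
    return f"{rid}\t{case}{rid}\t{ver}\t{quarter}\t{drug}\t{role}\t{pts}\t{sex}\t{age}\t{outcomes}\t{country}\n"


def test_simple_table_ingestion(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text(SIMPLE_HEADER + "".join(_simple_row(f"R{i}") for i in range(3)))
    rs = read_reports(p, dialect="simple-table")
    assert len(rs) == 3
    assert rs.provenance["rejected_rows"] == 0
    r = rs.reports[0]
    assert r.drugs[0].role == "primary-suspect"
    assert r.drugs[0].name_normalized == "lucentis"
    assert r.reactions == ["Macular ischaemia"]
    assert r.outcomes == frozenset({"death"})


def test_row_without_reactions_rejected_and_counted(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text(
        SIMPLE_HEADER
        + _simple_row("R1")
        + _simple_row("R2", pts="")  # no PT: rejected at read time
        + _simple_row("R3")
    )
    rs = read_reports(p)
    assert len(rs) == 2
    assert rs.provenance["rejected_rows"] == 1


def test_unparseable_quarter_is_row_level_rejection(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text(SIMPLE_HEADER + _simple_row("R1") + _simple_row("R2", quarter="2015-07"))
    rs = read_reports(p)
    assert len(rs) == 1
    assert rs.provenance["rejected_rows"] == 1


def test_missing_mandatory_column_is_hard_error(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text("report_id\tcase_id\n" + "R1\tC1\n")
    with pytest.raises(ValueError, match="case_version"):
        read_reports(p)


@pytest.mark.parametrize("dialect", ["simple-table", "faers-multitable"])
def test_write_read_roundtrip_is_identity(tmp_path, dialect):
    """Round-trip through either on-disk dialect preserves every report field."""
    cfg = SyntheticConfig(
        seed=7, n_reports=1000, drugs={"ranibizumab": 0.2, "aflibercept": 0.1},
        events={"Macular ischaemia": 0.05, "Endophthalmitis": 0.02},
        planted_signals=[("ranibizumab", "Macular ischaemia", 8.0)],
        duplicate_case_rate=0.05, multi_pt_rate=0.7,
    )
    rs = generate(cfg)
    target = tmp_path / ("r.tsv" if dialect == "simple-table" else "multi")
    write_reports(rs, target, dialect=dialect)
    back = read_reports(target, dialect=dialect)
    assert back.provenance["rejected_rows"] == 0
    assert len(back) == len(rs)
    by_id = {r.report_id: r for r in back}
    for r in rs:
        s = by_id[r.report_id]
        assert (s.case_id, s.case_version, s.receipt_quarter) == (r.case_id, r.case_version, r.receipt_quarter)
        assert [(d.name_normalized, d.role) for d in s.drugs] == [(d.name_normalized, d.role) for d in r.drugs]
        assert s.reactions == r.reactions
        assert (s.sex, s.age_years, s.outcomes, s.country) == (r.sex, r.age_years, r.outcomes, r.country)


def test_duplicate_report_ids_rejected():
    with pytest.raises(ValueError, match="duplicate report_id"):
        ReportSet([mk_report("R1"), mk_report("R1", "C2")])


class TestDeduplicate:
    def test_highest_version_survives(self):
        rs = ReportSet([mk_report("R1", "C1", version=1), mk_report("R2", "C1", version=2)])
        out = deduplicate(rs)
        assert [r.report_id for r in out] == ["R2"]

    def test_version_tie_broken_by_quarter_then_report_id(self):
        rs = ReportSet([
            mk_report("R1", "C1", version=1, quarter="2015Q1"),
            mk_report("R2", "C1", version=1, quarter="2016Q1"),
            mk_report("R3", "C2", version=1, quarter="2015Q1"),
            mk_report("R4", "C2", version=1, quarter="2015Q1"),
        ])
        survivors = {r.report_id for r in deduplicate(rs)}
        assert survivors == {"R2", "R4"}

    def test_identity_on_distinct_case_ids(self):
        rs = ReportSet([mk_report(f"R{i}", f"C{i}") for i in range(10)])
        assert [r.report_id for r in deduplicate(rs)] == [r.report_id for r in rs]

    def test_against_groupby_oracle_on_synthetic_versions(self):
        """Survivor set matches an independent group-by-and-max recount."""
        import random

        rng = random.Random(42)
        reports = []
        k = 0
        for case in range(500):
            n_ver = rng.randint(2, 4) if case < 50 else 1
            for v in range(1, n_ver + 1):
                reports.append(mk_report(f"R{k}", f"C{case}", version=v,
                                         quarter=f"20{10 + rng.randint(0, 9)}Q{rng.randint(1, 4)}"))
                k += 1
        rs = ReportSet(reports)
        out = deduplicate(rs)
        assert len(out) == 500
        # brute-force oracle: max key per case_id
        from pvsignal.reports import quarter_key

        expect = {}
        for r in reports:
            key = (r.case_version, quarter_key(r.receipt_quarter), r.report_id)
            if r.case_id not in expect or key > expect[r.case_id][0]:
                expect[r.case_id] = (key, r.report_id)
        assert {r.report_id for r in out} == {v[1] for v in expect.values()}

    def test_idempotent(self):
        rs = ReportSet([mk_report(f"R{i}", f"C{i % 5}", version=i) for i in range(1, 11)])
        once = deduplicate(rs)
        twice = deduplicate(once)
        assert [r.report_id for r in once] == [r.report_id for r in twice]


class TestPrimarySuspectFilter:
    def test_brand_name_resolves_to_generic(self, lexicon):
        rs = ReportSet([mk_report("R1", drugs=(("LUCENTIS", "primary-suspect"),))])
        out = filter_primary_suspect(rs, lexicon, "ranibizumab")
        assert len(out) == 1

    def test_concomitant_role_excluded(self, lexicon):
        rs = ReportSet([mk_report("R1", drugs=(("ranibizumab", "concomitant"),))])
        assert len(filter_primary_suspect(rs, lexicon, "ranibizumab")) == 0

    def test_unknown_drug_errors_with_known_names(self, lexicon):
        rs = ReportSet([mk_report("R1")])
        with pytest.raises(ValueError, match="ranibizumab"):
            filter_primary_suspect(rs, lexicon, "bevacizumab")

    def test_cohorts_partition_single_suspect_data(self):
        """With one primary suspect per report, per-drug cohorts partition the set."""
        cfg = SyntheticConfig(
            seed=3, n_reports=2000,
            drugs={"ranibizumab": 0.3, "aflibercept": 0.3, "brolucizumab": 0.4},
            events={"Dry eye": 0.02},
        )
        rs = generate(cfg)
        lex = cfg.lexicon()
        sizes = [len(filter_primary_suspect(rs, lex, d)) for d in cfg.drugs]
        assert sum(sizes) == len(rs)
        assert sizes == [rs.provenance["cohort_counts"][d] for d in cfg.drugs]
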