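import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import (
    ContingencyTable,
    SyntheticConfig,
    build_table,
    deduplicate,
    generate,
    realize_table,
    ror,
    solve_joint_cell,
    write_reports,
)


def _serialize(rs):
    buf = io.StringIO()
    import pandas as pd

    rows = [(r.report_id, r.case_id, r.case_version, r.receipt_quarter,
             tuple((d.name_normalized, d.role) for d in r.drugs),
             tuple(r.reactions), r.sex, r.age_years, tuple(sorted(r.outcomes)), r.country)
            for r in rs]
    print(rows, file=buf)
    return buf.getvalue()


def test_same_seed_gives_identical_output():
    cfg = SyntheticConfig(seed=99, n_reports=800, drugs={"drugx": 0.1},
                          events={"E": 0.02}, duplicate_case_rate=0.05, multi_pt_rate=0.4)
    assert _serialize(generate(cfg)) == _serialize(generate(cfg))


def test_different_seed_differs():
    cfg1 = SyntheticConfig(seed=1, n_reports=500, drugs={"drugx": 0.1}, events={"E": 0.05})
    cfg2 = SyntheticConfig(seed=2, n_reports=500, drugs={"drugx": 0.1}, events={"E": 0.05})
    assert _serialize(generate(cfg1)) != _serialize(generate(cfg2))


class TestJointCellSolver:
    def test_unit_odds_ratio_gives_independence(self):
        assert solve_joint_cell(0.2, 0.1, 1.0) == pytest.approx(0.02)

    @settings(max_examples=100, deadline=None)
    @given(px=st.floats(0.01, 0.6), py=st.floats(0.01, 0.6), psi=st.floats(0.1, 50.0))
    def test_solution_reproduces_the_odds_ratio(self, px, py, psi):
        p11 = solve_joint_cell(px, py, psi)
        p10, p01 = px - p11, py - p11
        p00 = 1 - px - py + p11
        if min(p10, p01, p00, p11) > 1e-9:
            assert p11 * p00 / (p10 * p01) == pytest.approx(psi, rel=1e-6)

    def test_infeasible_pair_is_hard_error_naming_the_pair(self):
        # a zero-mass cohort cannot carry a planted association
        cfg = SyntheticConfig(n_reports=10, drugs={"drugx": 0.0}, events={"E": 0.5},
                              planted_signals=[("drugx", "E", 5.0)])
        with pytest.raises(ValueError, match=r"drugx.*E"):
            generate(cfg)

    def test_double_planting_on_one_event_rejected(self):
        cfg = SyntheticConfig(n_reports=10, drugs={"a": 0.1, "b": 0.1},
                              events={"E": 0.05},
                              planted_signals=[("a", "E", 5.0), ("b", "E", 5.0)])
        with pytest.raises(ValueError, match="more than one planted"):
            generate(cfg)


def test_planted_cohort_counts_match_filter_sizes():
    cfg = SyntheticConfig(seed=4, n_reports=3000,
                          drugs={"a": 0.2, "b": 0.1}, events={"E": 0.03})
    rs = generate(cfg)
    from pvsignal import filter_primary_suspect

    for d in cfg.drugs:
        assert len(filter_primary_suspect(rs, cfg.lexicon(), d)) == rs.provenance["cohort_counts"][d]


def test_duplicate_versions_removed_by_dedup():
    cfg = SyntheticConfig(seed=6, n_reports=1000, drugs={"drugx": 0.1},
                          events={"E": 0.05}, duplicate_case_rate=0.2)
    rs = generate(cfg)
    assert len(rs) > 1000
    d = deduplicate(rs)
    assert len(d) == 1000
    assert all(r.case_version == max(x.case_version for x in rs if x.case_id == r.case_id)
               for r in list(d)[:20])


class TestRealizeTable:
    def test_scaled_published_table_roundtrips(self, lexicon):
        t = ContingencyTable(1, 21, 1, 10588)
        rs = realize_table(t, drug="ranibizumab", event="Macular ischaemia")
        assert len(rs) == 1 + 21 + 1 + 10588
        assert build_table(rs, lexicon, "ranibizumab", "Macular ischaemia") == t

    def test_empty_table_gives_empty_reportset(self):
        assert len(realize_table(ContingencyTable(0, 0, 0, 0))) == 0

    @settings(max_examples=30, deadline=None)
    @given(a=st.integers(0, 30), b=st.integers(0, 30), c=st.integers(0, 30), d=st.integers(0, 30))
    def test_roundtrip_for_arbitrary_tables(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        rs = realize_table(t, drug="drugx", event="E")
        assert build_table(rs, {"drugx": "drugx"}, "drugx", "E") == t


def test_parameter_recovery_improves_with_sample_size():
    """|mean log-ROR − log planted-OR| shrinks as n grows."""
    psi = 10.0

    def bias(n, seeds):
        logs = []
        for s in seeds:
            cfg = SyntheticConfig(seed=s, n_reports=n, drugs={"drugx": 0.2},
                                  events={"E": 0.05}, planted_signals=[("drugx", "E", psi)],
                                  concomitant_rate=0.0)
            t = build_table(generate(cfg), cfg.lexicon(), "drugx", "E")
            logs.append(math.log(ror(t).ror))
        return abs(float(np.mean(logs)) - math.log(psi))

    small = bias(2_000, range(10))
    large = bias(40_000, range(10))
    assert large < small


def test_realized_signal_recovers_planted_or_within_wald_ci():
    cfg = SyntheticConfig(seed=123, n_reports=100_000, drugs={"drugA": 0.1},
                          events={"E": 0.01}, planted_signals=[("drugA", "E", 20.0)],
                          concomitant_rate=0.0)
    t = build_table(generate(cfg), cfg.lexicon(), "drugA", "E")
    r = ror(t)
    assert r.ci_low < 20.0 < r.ci_high


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(drugs={"a": 0.8, "b": 0.4}).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(events={"E": 1.5}).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(duplicate_case_rate=1.0).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(planted_signals=[("nosuch", "E", 2.0)],
                        events={"E": 0.01}).validate()


def test_written_dialects_are_deterministic(tmp_path):
    cfg = SyntheticConfig(seed=31, n_reports=300, drugs={"drugx": 0.2}, events={"E": 0.05})
    for k in (1, 2):
        write_reports(generate(cfg), tmp_path / f"run{k}.tsv")
    assert (tmp_path / "run1.tsv").read_bytes() == (tmp_path / "run2.tsv").read_bytes()
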