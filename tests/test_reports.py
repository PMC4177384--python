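import logging

import pytest
from hypothesis import given, settings, strategies as st

from echoqc import (
    Dialect,
    EchoParameter,
    PARAMETERS,
    ParseError,
    Status,
    detect_dialect,
    parse_corpus,
    parse_report,
    render_report,
)

from conftest import build_report

P = EchoParameter

V1_TEXT = """REPORT ID: R000123
SUBJECT ID: S00042
DATE: 2003-07-15
IVSd: 1.1
LVPWd: 0.9
LVIDd: 4.8
LVIDs: 3
AO: 2.8
"""

V2_TEXT = """Echocardiography Report R000124
Patient: S00042
Study date: 2004-02-01

The interventricular septum measures 11 at end-diastole.
The left ventricle measures 48 mm at end-diastole.
The left ventricle measures 30 at end-systole.
The left atrium measures 37.
The aortic root measures 28.
"""

V3_TEXT = """ECHO REPORT
ID | R000125
Subject | S00042
Exam date | 2005-03-02
Septal thickness | 11.2
Posterior wall thickness | 9.1
LV end-diastolic diameter | 48.3
Left atrial diameter | 37.5
Aortic root diameter | 28.6
"""


class TestParseReport:
    def test_v1_key_value_line(self):
        rep = parse_report(V1_TEXT)
        assert rep.dialect == Dialect.V1
        assert rep.report_id == "R000123"
        assert rep.measurements[P.LVEDD].raw_value == 4.8
        # omitted LA line -> missing
        assert rep.measurements[P.LA].status == Status.MISSING

    def test_v2_prose_with_unit_token_ignored(self):
        rep = parse_report(V2_TEXT)
        assert rep.dialect == Dialect.V2
        # "measures 48 mm at end-diastole": number captured, unit not resolved
        assert rep.measurements[P.LVEDD].raw_value == 48
        assert rep.measurements[P.LVESD].raw_value == 30
        assert rep.measurements[P.PWT].status == Status.MISSING

    def test_v3_synonym_table(self):
        rep = parse_report(V3_TEXT)
        assert rep.dialect == Dialect.V3
        assert rep.measurements[P.SEPTUM].raw_value == 11.2
        assert rep.measurements[P.LVESD].status == Status.MISSING

    def test_missing_header_is_hard_error(self):
        with pytest.raises(ParseError, match="bad.txt"):
            parse_report("IVSd: 1.1\n", source="bad.txt")

    def test_duplicate_label_rejects_both_values(self, caplog):
        text = V1_TEXT + "LVIDd: 5.2\n"
        with caplog.at_level(logging.WARNING):
            rep = parse_report(text)
        assert rep.measurements[P.LVEDD].status == Status.MISSING
        assert any("duplicate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("text,expected", [
        (V1_TEXT, Dialect.V1), (V2_TEXT, Dialect.V2), (V3_TEXT, Dialect.V3)])
    def test_dialect_autodetection(self, text, expected):
        assert detect_dialect(text) == expected


_value_grid = st.one_of(
    st.none(),
    st.integers(1, 9900).map(lambda n: n / 100.0),  # up to 2 decimals
)


class TestRenderParseRoundTrip:
    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        values=st.lists(_value_grid, min_size=6, max_size=6),
        dialect=st.sampled_from(list(Dialect)),
    )
    def test_round_trip_identity(self, values, dialect):
        """Render -> parse recovers raw values and missingness exactly,
        whatever the dialect and whatever the unit regime of the numbers."""
        rep = build_report("R000777", dict(zip(PARAMETERS, values)),
                           dialect=dialect)
        back = parse_report(render_report(rep))
        assert back.dialect == dialect
        assert back.report_id == rep.report_id
        assert back.subject_id == rep.subject_id
        for p in PARAMETERS:
            assert back.measurements[p].raw_value == rep.measurements[p].raw_value

    def test_all_missing_report_round_trips(self):
        rep = build_report("R000778", {})
        back = parse_report(render_report(rep))
        assert all(back.measurements[p].status == Status.MISSING
                   for p in PARAMETERS)


class TestParseCorpus:
    def test_corrupt_file_is_skipped_not_fatal(self, tmp_path):
        (tmp_path / "a.txt").write_text(V1_TEXT)
        (tmp_path / "b.txt").write_text(V2_TEXT)
        (tmp_path / "c.txt").write_text("not a report\n")
        ds, log = parse_corpus(tmp_path)
        assert ds.n_reports == 2
        assert log.n_files == 3 and len(log.failures) == 1
        assert log.dialect_counts == {"V1": 1, "V2": 1}

    def test_empty_directory_yields_empty_dataset(self, tmp_path):
        ds, log = parse_corpus(tmp_path)
        assert ds.n_reports == 0 and log.n_files == 0

    def test_stream_format_with_record_separator(self, tmp_path):
        stream = V1_TEXT + "%%\n" + V3_TEXT
        fp = tmp_path / "all.txt"
        fp.write_text(stream)
        ds, log = parse_corpus(fp)
        assert ds.n_reports == 2
        assert {r.report_id for r in ds.reports} == {"R000123", "R000125"}

    def test_generated_corpus_recovers_exactly(self, tmp_path,
                                               small_corrupted_corpus):
        ds, _ledger = small_corrupted_corpus
        from echoqc import write_corpus
        write_corpus(ds, tmp_path)
        back, log = parse_corpus(tmp_path)
        assert back.n_reports == ds.n_reports
        assert log.failures == []
        orig = {r.report_id: r for r in ds.reports}
        for rep in back.reports:
            src = orig[rep.report_id]
            for p in PARAMETERS:
                assert rep.measurements[p].raw_value == \
                    src.measurements[p].raw_value
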