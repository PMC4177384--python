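import io

import pytest

from echoqc import (
    Disposition,
    EchoDataset,
    EchoParameter,
    FlagReason,
    FlagRecord,
    Measurement,
    PARAMETERS,
    PlausibilityConfig,
    Status,
    validate_dataset,
)

from conftest import build_dataset, build_report

P = EchoParameter


class TestValidateDataset:
    def test_well_formed_dataset_has_no_violations(self):
        ds = build_dataset(
            build_report("R1", {P.LVEDD: 4.8, P.AO: 2.8}),
            build_report("R2", {P.SEPTUM: 11, P.PWT: 9, P.LVEDD: 48,
                                P.LVESD: 30, P.LA: 37, P.AO: 28}),
        )
        assert validate_dataset(ds) == []

    def test_duplicate_report_id_is_named(self):
        ds = build_dataset(build_report("R1", {P.LVEDD: 4.8}),
                           build_report("R1", {P.LVEDD: 5.0}))
        violations = validate_dataset(ds)
        assert len(violations) == 1
        assert "R1" in violations[0]

    def test_point_accounting_at_cohort_scale(self):
        # 6,076 reports carry 36,456 potential data points
        ds = build_dataset(*(build_report(f"R{i}", {P.LVEDD: 48.0})
                             for i in range(6076)))
        assert ds.total_points == 36456
        assert ds.n_present + ds.n_missing == ds.total_points
        assert validate_dataset(ds) == []

    def test_status_value_mm_inconsistencies_are_reported(self):
        r = build_report("R1", {P.LVEDD: 48.0})
        r.measurements[P.LVEDD].value_mm = 48.0
        r.measurements[P.LVEDD].status = Status.REMOVED
        assert any("value_mm" in v for v in validate_dataset(build_dataset(r)))

        r2 = build_report("R2", {P.LVEDD: 48.0})
        r2.measurements[P.LVEDD].status = Status.EDITED  # no edit flag
        assert any("edit flag" in v for v in validate_dataset(build_dataset(r2)))

    def test_edited_point_with_single_edit_flag_is_valid(self):
        r = build_report("R1", {P.LVEDD: 480.0})
        m = r.measurements[P.LVEDD]
        m.status = Status.EDITED
        m.value_mm = 48.0
        m.flags.append(FlagRecord(
            report_id="R1", parameter=P.LVEDD, step=2,
            reason=FlagReason.UNIT_DISCORDANT,
            disposition=Disposition.EDIT, edited_value=48.0))
        assert validate_dataset(build_dataset(r)) == []


class TestInterchangeRoundTrip:
    def test_csv_round_trip_is_identity(self):
        ds = build_dataset(
            build_report("R1", {P.LVEDD: 4.8, P.AO: 2.8}),
            build_report("R2", {P.SEPTUM: 11.2}),
        )
        ds.reports[0].measurements[P.LVEDD].value_mm = 48.0
        ds.reports[0].measurements[P.LVEDD].status = Status.RETAINED
        ds.provenance = {"description": "fixture", "config_hash": "abc"}
        buf = io.StringIO()
        ds.to_csv(buf)
        back = EchoDataset.read_csv(io.StringIO(buf.getvalue()))
        assert back.provenance == ds.provenance
        assert len(back.reports) == len(ds.reports)
        for a, b in zip(ds.reports, back.reports):
            assert (a.report_id, a.subject_id, a.exam_date) == \
                (b.report_id, b.subject_id, b.exam_date)
            assert a.dialect == b.dialect and a.unit_class == b.unit_class
            for p in PARAMETERS:
                ma, mb = a.measurements[p], b.measurements[p]
                assert ma.raw_value == mb.raw_value
                assert ma.value_mm == mb.value_mm
                assert ma.status == mb.status


class TestPlausibilityConfig:
    @pytest.mark.parametrize("kwargs", [
        {"windows_mm": {P.LVEDD: (100.0, 15.0)}},
        {"threshold_factor": 0.9},
        {"unit_scale": 0.5},
    ])
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PlausibilityConfig(**kwargs)

    def test_window_compatibility_both_regimes(self):
        cfg = PlausibilityConfig()
        assert cfg.compatible_as_mm(P.LVEDD, 48.0)
        assert not cfg.compatible_as_mm(P.LVEDD, 4.8)
        assert cfg.compatible_as_cm(P.LVEDD, 4.8)
        assert not cfg.compatible_as_cm(P.LVEDD, 48.0)

    def test_config_hash_tracks_content(self):
        a, b = PlausibilityConfig(), PlausibilityConfig(residual_k=5.0)
        assert a.config_hash() == PlausibilityConfig().config_hash()
        assert a.config_hash() != b.config_hash()
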