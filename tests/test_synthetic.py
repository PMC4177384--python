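import numpy as np
import pandas as pd
import pytest

from echoqc import (
    DEFAULT_CORRELATION,
    EchoParameter,
    ErrorInjectionSpec,
    GeneratorConfig,
    PARAMETERS,
    PlausibilityConfig,
    generate_cohort,
    inject_errors,
    validate_dataset,
)

P = EchoParameter


class TestGenerateCohort:
    def test_single_subject_single_exam(self):
        ds, ledger = generate_cohort(GeneratorConfig(
            n_subjects=1, n_reports=1, missing_rate=0.0, seed=1))
        assert ds.n_reports == 1
        cfg = PlausibilityConfig()
        r = ds.reports[0]
        for p in PARAMETERS:
            t = ledger.true_mm(r.report_id, p)
            lo, hi = cfg.window(p)
            assert lo <= t <= hi

    def test_identical_seed_and_config_reproduce_the_corpus(self):
        a, la = generate_cohort(GeneratorConfig(n_subjects=120, seed=5))
        b, lb = generate_cohort(GeneratorConfig(n_subjects=120, seed=5))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        pd.testing.assert_frame_equal(la.points, lb.points)
        c, _ = generate_cohort(GeneratorConfig(n_subjects=120, seed=6))
        assert not a.to_frame().equals(c.to_frame())

    def test_exam_count_distribution(self):
        ds, _ = generate_cohort(GeneratorConfig(n_subjects=2000, seed=7))
        counts = pd.Series([r.subject_id for r in ds.reports]).value_counts()
        assert counts.median() == 1
        q1, q3 = np.percentile(counts, [25, 75])
        assert (q1, q3) == (1, 2)
        assert counts.max() <= 30

    def test_report_level_attributes_hit_their_targets(self, small_clean_corpus):
        ds, ledger = small_clean_corpus
        n = ds.n_reports
        cm = (ledger.reports["unit_regime"] == "cm").sum()
        assert cm == round(2132 / 6076 * n)
        missing_frac = ds.n_missing / ds.total_points
        assert abs(missing_frac - 0.09) < 0.01
        sexes = ledger.subjects["sex"].value_counts(normalize=True)
        assert sexes["F"] == pytest.approx(0.598, abs=0.01)
        assert validate_dataset(ds) == []

    def test_cm_reports_carry_tenth_scale_raw_values(self, small_clean_corpus):
        ds, ledger = small_clean_corpus
        for r in ds.reports[:50]:
            regime = ledger.unit_regime(r.report_id)
            for p in PARAMETERS:
                m = r.measurements[p]
                if not m.is_present:
                    continue
                t = ledger.true_mm(r.report_id, p)
                expected = round(t / 10.0, 2) if regime == "cm" else round(t, 1)
                assert m.raw_value == expected

    def test_truth_respects_anatomy(self, small_clean_corpus):
        ds, ledger = small_clean_corpus
        for r in ds.reports:
            if (r.measurements[P.LVESD].is_present
                    and r.measurements[P.LVEDD].is_present):
                assert ledger.true_mm(r.report_id, P.LVESD) < \
                    ledger.true_mm(r.report_id, P.LVEDD)

    def test_correlation_default_is_positive_definite(self):
        np.linalg.cholesky(DEFAULT_CORRELATION)


class TestInjectErrors:
    def test_zero_counts_leave_dataset_unchanged(self, small_clean_corpus):
        ds, ledger = small_clean_corpus
        spec = ErrorInjectionSpec(nonsense_extreme=0, within_report_unit_mix=0,
                                  sysdias_swap_records=0, ao_la_swap_records=0,
                                  genuine_extreme=0, seed=3)
        out, led = inject_errors(ds, ledger, spec)
        pd.testing.assert_frame_equal(out.to_frame(), ds.to_frame())
        assert led.n_injected_errors == 0

    def test_counts_rescale_half_up_with_corpus_size(self):
        spec = ErrorInjectionSpec()
        assert spec.scaled_counts(6076) == {
            "nonsense_extreme": 16, "within_report_unit_mix": 55,
            "sysdias_swap_records": 16, "ao_la_swap_records": 2,
            "genuine_extreme": 3}
        half = spec.scaled_counts(3038)
        assert half["nonsense_extreme"] == 8
        assert half["within_report_unit_mix"] == 28  # 27.5 rounds half-up

    def test_sysdias_swap_exchanges_the_raw_fields(self, small_corrupted_corpus):
        ds, ledger = small_corrupted_corpus
        swapped = ledger.points[ledger.points.error_class == "sysdias_swap"]
        assert len(swapped) > 0 and len(swapped) % 2 == 0
        for rid in swapped.report_id.unique():
            r = ds.report(rid)
            assert ledger.repair(rid, P.LVESD) == "swap:LVEDD"
            regime = ledger.unit_regime(rid)
            scale = 0.1 if regime == "cm" else 1.0
            esd_t = ledger.true_mm(rid, P.LVESD)
            edd_t = ledger.true_mm(rid, P.LVEDD)
            assert r.measurements[P.LVESD].raw_value == pytest.approx(
                round(edd_t * scale, 2))
            assert r.measurements[P.LVEDD].raw_value == pytest.approx(
                round(esd_t * scale, 2))

    def test_repairs_restore_the_clean_corpus(self, small_clean_corpus,
                                              small_corrupted_corpus):
        """Oracle closure: applying each ledger repair to its corrupted
        point reproduces the clean raw value exactly."""
        clean, _ = small_clean_corpus
        corrupted, ledger = small_corrupted_corpus
        clean_by_id = {r.report_id: r for r in clean.reports}
        n_checked = 0
        for row in ledger.injected_error_points().itertuples(index=False):
            p = EchoParameter(row.parameter)
            r = corrupted.report(row.report_id)
            raw = r.measurements[p].raw_value
            if str(row.repair).startswith("scale:"):
                restored = round(raw * float(str(row.repair).split(":")[1]), 2)
            elif str(row.repair).startswith("swap:"):
                q = EchoParameter(str(row.repair).split(":")[1])
                restored = r.measurements[q].raw_value
            else:
                continue  # nonsense values are unrepairable by design
            expected = clean_by_id[row.report_id].measurements[p].raw_value
            assert restored == pytest.approx(expected)
            n_checked += 1
        assert n_checked > 0

    def test_error_classes_never_overlap_on_a_point(self, small_corrupted_corpus):
        _, ledger = small_corrupted_corpus
        touched = ledger.points[ledger.points.error_class != "none"]
        keys = list(zip(touched.report_id, touched.parameter))
        assert len(keys) == len(set(keys))

    def test_impossible_request_is_hard_error(self):
        ds, ledger = generate_cohort(GeneratorConfig(n_subjects=5, seed=9))
        spec = ErrorInjectionSpec(nonsense_extreme=10**6,
                                  reference_reports=ds.n_reports)
        with pytest.raises(ValueError, match="not enough eligible"):
            inject_errors(ds, ledger, spec)

    def test_cleaning_preserves_parameter_means(self, small_clean_corpus,
                                                small_corrupted_corpus):
        """Errors are rare, so the cleaned corrupted corpus must reproduce
        the clean corpus per-parameter means within 0.5 mm."""
        from echoqc import run_pipeline
        clean, clean_ledger = small_clean_corpus
        corrupted, ledger = small_corrupted_corpus
        result = run_pipeline(corrupted, ledger=ledger)
        for p in PARAMETERS:
            truth = [clean_ledger.true_mm(r.report_id, p)
                     for r in clean.reports if r.measurements[p].is_present]
            cleaned = [r.measurements[p].value_mm
                       for r in result.cleaned.reports
                       if r.measurements[p].is_live
                       and r.measurements[p].value_mm is not None]
            assert abs(np.mean(cleaned) - np.mean(truth)) < 0.5
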