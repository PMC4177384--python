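import numpy as np
import pytest

from echoqc import (
    EchoParameter,
    PARAMETERS,
    cohort_summary,
    completeness_summary,
    run_pipeline,
    score_against_ledger,
)

from conftest import build_dataset, build_report

P = EchoParameter


@pytest.fixture(scope="module")
def scored(small_corrupted_corpus):
    ds, ledger = small_corrupted_corpus
    result = run_pipeline(ds, ledger=ledger)
    return result, ledger, score_against_ledger(result, ledger)


class TestScoreAgainstLedger:
    def test_metric_consistency(self, scored):
        _result, _ledger, rep = scored
        assert rep.reviewed == sum(rep.flags_by_step.values())
        assert rep.accuracy * rep.reviewed == rep.confirmed
        assert rep.completeness * rep.total_points == rep.present_points
        assert rep.removed_points + rep.surviving_points == rep.present_points

    def test_sensitivity_and_agreement_on_modeled_errors(self, scored):
        _result, _ledger, rep = scored
        assert rep.sensitivity == 1.0
        assert rep.false_negatives == []
        # perfect point-wise agreement of surviving values with the truth
        assert rep.mismatched_points == 0

    def test_empty_review_queue_yields_not_applicable_metrics(
            self, small_clean_corpus):
        ds, ledger = small_clean_corpus
        from echoqc import ErrorInjectionSpec, inject_errors
        spec = ErrorInjectionSpec(nonsense_extreme=0, within_report_unit_mix=0,
                                  sysdias_swap_records=0, ao_la_swap_records=0,
                                  genuine_extreme=0, seed=3)
        out, led = inject_errors(ds, ledger, spec)
        result = run_pipeline(out, ledger=led)
        rep = score_against_ledger(result, led)
        assert rep.injected_errors == 0
        assert rep.sensitivity is None
        if rep.reviewed == 0:
            assert rep.accuracy is None

    def test_ledger_corpus_mismatch_is_hard_error(self, small_corrupted_corpus):
        ds, ledger = small_corrupted_corpus
        result = run_pipeline(ds, ledger=ledger)
        result.cleaned.reports.append(
            build_report("RZZZ", {P.LVEDD: 48.0}))
        with pytest.raises(ValueError, match="cover"):
            score_against_ledger(result, ledger)


class TestCompleteness:
    def test_half_present(self):
        r1 = build_report("R1", {p: 30.0 for p in PARAMETERS})
        r2 = build_report("R2", {})
        summary = completeness_summary(build_dataset(r1, r2))
        assert summary.total_points == 12
        assert summary.present_points == 6
        assert summary.percent_present == 50.0

    def test_all_present_is_hundred_percent(self):
        r = build_report("R1", {p: 30.0 for p in PARAMETERS})
        assert completeness_summary(build_dataset(r)).printed_percent == 100

    def test_per_parameter_missingness(self):
        r = build_report("R1", {P.LVEDD: 48.0})
        summary = completeness_summary(build_dataset(r))
        assert summary.missing_by_parameter["LVEDD"] == 0
        assert summary.missing_by_parameter["AO"] == 1


class TestCohortSummary:
    def test_one_subject_three_echos(self):
        ds = build_dataset(*(build_report(f"R{i}", {P.LVEDD: 48.0},
                                          subject_id="S1")
                             for i in range(3)))
        s = cohort_summary(ds)
        assert s.n_subjects == 1
        assert s.echos_median == 3
        assert s.echos_range == (3, 3)

    def test_coverage_percentage_one_decimal(self):
        ds = build_dataset(*(build_report(f"R{i}", {P.LVEDD: 48.0},
                                          subject_id=f"S{i}")
                             for i in range(2834)))
        s = cohort_summary(ds, cohort_size=13958)
        assert s.coverage_pct == 20.3

    def test_sex_difference_direction_in_aortic_root(self, small_clean_corpus):
        ds, ledger = small_clean_corpus
        from echoqc import run_pipeline
        result = run_pipeline(ds, ledger=ledger)
        s = cohort_summary(result.cleaned, subjects=ledger.subjects)
        row = s.by_sex.set_index("parameter").loc["AO"]
        assert row["mean_M"] > row["mean_F"]
        assert row["p_value"] < 0.01
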