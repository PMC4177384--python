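"""Scoring of pipeline performance and cohort-level summaries.

Metrics mirror how semi-automated EMR cleaning is evaluated in practice:
review *accuracy* (what fraction of the points sent to review really were
erroneous), *sensitivity* (what fraction of the true errors any step
caught), point-wise *agreement* of the cleaned values with the gold
standard, data-loss and completeness accounting, and review *burden* (the
fraction of present points a human would have to look at).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ledger import GroundTruthLedger
from .model import EchoDataset, EchoParameter, PARAMETERS, Status
from .pipeline import PipelineResult

__all__ = [
    "EvaluationReport",
    "score_against_ledger",
    "completeness_summary",
    "cohort_summary",
]

_AGREEMENT_ATOL = 1e-6


@dataclass
class EvaluationReport:
    flags_by_step: Dict[int, int]
    reviewed: int
    confirmed: int
    detected_errors: int
    injected_errors: int
    false_negatives: List[Tuple[str, str]]
    removed_points: int
    edited_points: int
    retained_points: int
    present_points: int
    total_points: int
    surviving_points: int
    mismatched_points: int

    @property
    def accuracy(self) -> Optional[float]:
        """Confirmed-error fraction of reviewed points (None if none reviewed)."""
        return self.confirmed / self.reviewed if self.reviewed else None

    @property
    def sensitivity(self) -> Optional[float]:
        return (self.detected_errors / self.injected_errors
                if self.injected_errors else None)

    @property
    def completeness(self) -> float:
        return self.present_points / self.total_points if self.total_points else 0.0

    @property
    def review_burden(self) -> Optional[float]:
        return self.reviewed / self.present_points if self.present_points else None

    def to_frame(self) -> pd.DataFrame:
        def pct(x: Optional[float]) -> Optional[float]:
            return None if x is None else round(100.0 * x, 1)
        rows = [
            ("reviewed_points", self.reviewed),
            ("confirmed_errors", self.confirmed),
            ("accuracy_pct", pct(self.accuracy)),
            ("injected_errors", self.injected_errors),
            ("detected_errors", self.detected_errors),
            ("sensitivity_pct", pct(self.sensitivity)),
            ("removed_points", self.removed_points),
            ("edited_points", self.edited_points),
            ("retained_points", self.retained_points),
            ("present_points", self.present_points),
            ("total_points", self.total_points),
            ("completeness_pct", pct(self.completeness)),
            ("review_burden_pct", pct(self.review_burden)),
            ("surviving_points", self.surviving_points),
            ("mismatched_points", self.mismatched_points),
        ]
        rows += [(f"step{k}_flags", v) for k, v in sorted(self.flags_by_step.items())]
        return pd.DataFrame(rows, columns=["metric", "value"])


def score_against_ledger(result: PipelineResult,
                         ledger: GroundTruthLedger) -> EvaluationReport:
    """Score a pipeline run against the ground-truth ledger.

    A reviewed (flagged) point is *confirmed* when the ledger marks it
    erroneous; an injected error is *detected* when it was flagged at any
    step; a surviving point is *mismatched* when its harmonized value
    differs from the ledger truth.  Raises when the ledger does not cover
    the corpus.
    """
    ds = result.cleaned
    if not ledger.covers(ds):
        raise ValueError("ledger does not cover the scored corpus")

    flags_by_step: Dict[int, int] = {k: 0 for k in (1, 2, 3, 5)}
    confirmed = 0
    flagged_points: set = set()
    for f in result.queue:
        flags_by_step[f.step] += 1
        flagged_points.add((f.report_id, f.parameter.value))
        if ledger.is_erroneous(f.report_id, f.parameter):
            confirmed += 1
    reviewed = sum(flags_by_step.values())

    injected = ledger.injected_error_points()
    injected_errors = len(injected)
    false_negatives = [
        (str(row.report_id), str(row.parameter))
        for row in injected.itertuples(index=False)
        if (str(row.report_id), str(row.parameter)) not in flagged_points]
    detected = injected_errors - len(false_negatives)

    removed = edited = retained = surviving = mismatched = 0
    for r in ds.reports:
        for p in PARAMETERS:
            m = r.measurements[p]
            if not m.is_present:
                continue
            if m.status == Status.REMOVED:
                removed += 1
                continue
            if m.status == Status.EDITED:
                edited += 1
            elif m.status == Status.RETAINED:
                retained += 1
            surviving += 1
            truth = ledger.true_mm(r.report_id, p)
            if m.value_mm is None or abs(m.value_mm - truth) > _AGREEMENT_ATOL:
                mismatched += 1

    return EvaluationReport(
        flags_by_step=flags_by_step,
        reviewed=reviewed,
        confirmed=confirmed,
        detected_errors=detected,
        injected_errors=injected_errors,
        false_negatives=false_negatives,
        removed_points=removed,
        edited_points=edited,
        retained_points=retained,
        present_points=ds.n_present,
        total_points=ds.total_points,
        surviving_points=surviving,
        mismatched_points=mismatched,
    )


# ----------------------------------------------------------------------
# Dataset summaries
# ----------------------------------------------------------------------

@dataclass
class CompletenessSummary:
    total_points: int
    present_points: int
    percent_present: float          # one decimal
    printed_percent: int            # as printed in cohort reports
    missing_by_parameter: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [("total_points", self.total_points),
                ("present_points", self.present_points),
                ("percent_present", self.percent_present),
                ("printed_percent", self.printed_percent)]
        rows += [(f"missing_{k}", v)
                 for k, v in self.missing_by_parameter.items()]
        return pd.DataFrame(rows, columns=["metric", "value"])


def completeness_summary(ds: EchoDataset) -> CompletenessSummary:
    """Potential/present point accounting (6 points per report)."""
    total = ds.total_points
    present = ds.n_present
    pct = 100.0 * present / total if total else 0.0
    missing = {p.value: 0 for p in PARAMETERS}
    for r in ds.reports:
        for p in PARAMETERS:
            if not r.measurements[p].is_present:
                missing[p.value] += 1
    return CompletenessSummary(
        total_points=total,
        present_points=present,
        percent_present=round(pct, 1),
        printed_percent=int(round(pct)),
        missing_by_parameter=missing,
    )


@dataclass
class CohortSummary:
    n_subjects: int
    n_reports: int
    coverage_pct: Optional[float]        # share of the cohort with >= 1 echo
    echos_median: float
    echos_iqr: Tuple[float, float]
    echos_range: Tuple[int, int]
    echo_count_table: pd.DataFrame       # exams-per-subject frequency table
    by_sex: pd.DataFrame                 # per-sex mean +/- SD and p-value


def cohort_summary(ds: EchoDataset,
                   subjects: Optional[pd.DataFrame] = None,
                   cohort_size: Optional[int] = None) -> CohortSummary:
    """Cohort-level accounting of a (cleaned) dataset.

    ``subjects`` maps subject_id to sex for the per-sex parameter table;
    ``cohort_size`` is the denominator population (e.g. all adults in the
    source cohort) for the coverage percentage.  The sex comparison uses a
    Welch two-sample t-test; it is presentation plumbing, not part of the
    filtering method.
    """
    per_subject = pd.Series(
        [r.subject_id for r in ds.reports]).value_counts()
    n_subjects = int(per_subject.shape[0])
    counts = per_subject.to_numpy()
    coverage = (round(100.0 * n_subjects / cohort_size, 1)
                if cohort_size else None)
    freq = (pd.Series(counts).value_counts().sort_index()
            .rename_axis("echocardiograms").reset_index(name="subjects"))

    rows = []
    if subjects is not None and len(subjects):
        sex_map = dict(zip(subjects["subject_id"].astype(str),
                           subjects["sex"].astype(str)))
        for p in PARAMETERS:
            groups: Dict[str, List[float]] = {"F": [], "M": []}
            for r in ds.reports:
                m = r.measurements[p]
                v = m.value_mm if m.value_mm is not None else m.raw_value
                sex = sex_map.get(r.subject_id)
                if m.is_live and v is not None and sex in groups:
                    groups[sex].append(v)
            f, mvals = np.asarray(groups["F"]), np.asarray(groups["M"])
            pval = (stats.ttest_ind(f, mvals, equal_var=False).pvalue
                    if len(f) > 1 and len(mvals) > 1 else float("nan"))
            rows.append({
                "parameter": p.value,
                "mean_F": round(float(f.mean()), 1) if len(f) else float("nan"),
                "sd_F": round(float(f.std(ddof=1)), 1) if len(f) > 1 else float("nan"),
                "n_F": len(f),
                "mean_M": round(float(mvals.mean()), 1) if len(mvals) else float("nan"),
                "sd_M": round(float(mvals.std(ddof=1)), 1) if len(mvals) > 1 else float("nan"),
                "n_M": len(mvals),
                "p_value": pval,
            })
    by_sex = pd.DataFrame(rows, columns=[
        "parameter", "mean_F", "sd_F", "n_F", "mean_M", "sd_M", "n_M",
        "p_value"])

    if len(counts):
        q1, med, q3 = np.percentile(counts, [25, 50, 75])
        rng = (int(counts.min()), int(counts.max()))
    else:
        q1 = med = q3 = float("nan")
        rng = (0, 0)
    return CohortSummary(
        n_subjects=n_subjects,
        n_reports=ds.n_reports,
        coverage_pct=coverage,
        echos_median=float(med),
        echos_iqr=(float(q1), float(q3)),
        echos_range=rng,
        echo_count_table=freq,
        by_sex=by_sex,
    )
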