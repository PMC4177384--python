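from __future__ import annotations

from typing import Dict, Optional

import pytest

from echoqc import (
    Dialect,
    EchoDataset,
    EchoParameter,
    EchoReport,
    ErrorInjectionSpec,
    GeneratorConfig,
    Measurement,
    PARAMETERS,
    generate_cohort,
    inject_errors,
)


def build_report(report_id: str,
                 values: Dict[EchoParameter, Optional[float]],
                 subject_id: str = "S00001",
                 dialect: Dialect = Dialect.V1,
                 exam_date: str = "2004-06-01") -> EchoReport:
    """Construct a report from a {parameter: raw value} mapping."""
    measurements = {
        p: Measurement(parameter=p, raw_value=values.get(p))
        for p in PARAMETERS
    }
    return EchoReport(report_id=report_id, subject_id=subject_id,
                      exam_date=exam_date, dialect=dialect,
                      measurements=measurements)


def build_dataset(*reports: EchoReport) -> EchoDataset:
    return EchoDataset(reports=list(reports))


@pytest.fixture(scope="session")
def small_clean_corpus():
    """A clean 300-subject synthetic corpus with its ground-truth ledger."""
    return generate_cohort(GeneratorConfig(n_subjects=300, seed=11))


@pytest.fixture(scope="session")
def small_corrupted_corpus(small_clean_corpus):
    """The same corpus with proportionally scaled injected errors."""
    ds, ledger = small_clean_corpus
    return inject_errors(ds, ledger, ErrorInjectionSpec(seed=12))
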