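"""Ground-truth ledger for synthetic corpora.

The ledger records, for every present data point, the true value in
millimetres, the error class injected into it (if any) and the repair that
restores the truth.  It is the oracle behind automatic adjudication and
pipeline scoring; real-EMR workflows have no ledger and use the exportable
review queue instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import pandas as pd

from .model import EchoDataset, EchoParameter, PARAMETERS

__all__ = ["ERROR_CLASSES", "GroundTruthLedger"]

#: Injectable error classes.  ``genuine_extreme`` is not an error: it marks
#: a valid but extreme value that the pipeline should flag and then retain.
ERROR_CLASSES = (
    "nonsense_extreme",
    "within_report_unit_mix",
    "sysdias_swap",
    "ao_la_field_swap",
    "genuine_extreme",
)

_REPAIRABLE = {"within_report_unit_mix", "sysdias_swap", "ao_la_field_swap"}


@dataclass
class GroundTruthLedger:
    """Per-point truth table plus per-report and per-subject side tables.

    ``points`` columns: report_id, parameter, true_mm, error_class, repair.
    ``error_class`` is ``"none"`` for untouched points.  ``repair`` is one of
    ``""`` (nothing to repair / unrepairable), ``"scale:10"``,
    ``"scale:0.1"`` (multiply the corrupted raw by the factor) or
    ``"swap:<PARAM>"`` (exchange with the named partner field).

    ``reports`` columns: report_id, subject_id, unit_regime ("cm"/"mm").
    ``subjects`` columns: subject_id, sex ("F"/"M"), age.
    """

    points: pd.DataFrame
    reports: pd.DataFrame = field(default_factory=pd.DataFrame)
    subjects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self._index: Dict[Tuple[str, str], Tuple[float, str, str]] = {
            (str(r.report_id), str(r.parameter)): (
                float(r.true_mm), str(r.error_class), str(r.repair or ""))
            for r in self.points.itertuples(index=False)
        }
        self._regime: Dict[str, str] = {}
        if len(self.reports):
            self._regime = dict(
                zip(self.reports["report_id"].astype(str),
                    self.reports["unit_regime"].astype(str)))

    # -- lookups --------------------------------------------------------

    def has_point(self, report_id: str, parameter: EchoParameter) -> bool:
        return (report_id, parameter.value) in self._index

    def true_mm(self, report_id: str, parameter: EchoParameter) -> float:
        return self._index[(report_id, parameter.value)][0]

    def error_class(self, report_id: str, parameter: EchoParameter) -> str:
        return self._index[(report_id, parameter.value)][1]

    def repair(self, report_id: str, parameter: EchoParameter) -> str:
        return self._index[(report_id, parameter.value)][2]

    def is_erroneous(self, report_id: str, parameter: EchoParameter) -> bool:
        cls = self.error_class(report_id, parameter)
        return cls not in ("none", "genuine_extreme")

    def unit_regime(self, report_id: str) -> Optional[str]:
        return self._regime.get(report_id)

    @property
    def n_injected_errors(self) -> int:
        return int((~self.points["error_class"].isin(
            ["none", "genuine_extreme"])).sum())

    def injected_error_points(self) -> pd.DataFrame:
        return self.points[~self.points["error_class"].isin(
            ["none", "genuine_extreme"])]

    def set_point(self, report_id: str, parameter: EchoParameter,
                  true_mm: Optional[float] = None,
                  error_class: Optional[str] = None,
                  repair: Optional[str] = None) -> None:
        key = (report_id, parameter.value)
        old_true, old_cls, old_rep = self._index[key]
        new = (true_mm if true_mm is not None else old_true,
               error_class if error_class is not None else old_cls,
               repair if repair is not None else old_rep)
        self._index[key] = new
        mask = ((self.points["report_id"] == report_id)
                & (self.points["parameter"] == parameter.value))
        self.points.loc[mask, ["true_mm", "error_class", "repair"]] = list(new)

    def covers(self, ds: EchoDataset) -> bool:
        """True when every present point of ``ds`` has a ledger row."""
        for r in ds.reports:
            for p in PARAMETERS:
                if r.measurements[p].is_present and not self.has_point(r.report_id, p):
                    return False
        return True

    # -- serialization --------------------------------------------------

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reports: Optional[pd.DataFrame] = None,
                 subjects: Optional[pd.DataFrame] = None) -> "GroundTruthLedger":
        points = pd.read_csv(path, dtype={"report_id": str, "parameter": str})
        points["repair"] = points.get("repair", "").fillna("")
        return cls(points=points,
                   reports=reports if reports is not None else pd.DataFrame(),
                   subjects=subjects if subjects is not None else pd.DataFrame())
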