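"""Core domain model for quantitative echocardiographic datasets.

The package works on six canonical structural measurements per exam:
interventricular septal thickness (SEPTUM), LV posterior wall thickness
(PWT), LV end-diastolic and end-systolic internal diameters (LVEDD, LVESD),
left atrial diameter (LA) and aortic root diameter (AO).  Raw values parsed
from report text are unit-unresolved (clinical reports mix centimetres and
millimetres); the cleaning pipeline resolves the unit of every report and
harmonizes all surviving values to millimetres, keeping the verbatim raw
value forever as the audit trail.
"""

from __future__ import annotations

import enum
import hashlib
import io
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

__all__ = [
    "EchoParameter",
    "PARAMETERS",
    "Status",
    "Dialect",
    "UnitClass",
    "FlagReason",
    "Disposition",
    "FlagRecord",
    "Measurement",
    "EchoReport",
    "EchoDataset",
    "PlausibilityConfig",
    "DEFAULT_WINDOWS_MM",
    "validate_dataset",
]


class EchoParameter(str, enum.Enum):
    """The six structural parameters extracted from every report."""

    SEPTUM = "SEPTUM"  # interventricular septal thickness
    PWT = "PWT"        # LV posterior wall thickness
    LVEDD = "LVEDD"    # LV end-diastolic diameter
    LVESD = "LVESD"    # LV end-systolic diameter
    LA = "LA"          # left atrial diameter
    AO = "AO"          # aortic root diameter

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PARAMETERS: Tuple[EchoParameter, ...] = tuple(EchoParameter)


class Status(str, enum.Enum):
    PRESENT = "present"
    MISSING = "missing"
    RETAINED = "retained"   # flagged, reviewed, confirmed valid
    EDITED = "edited"       # flagged, repaired by an enumerated rule
    REMOVED = "removed"     # flagged, unrepairable


class Dialect(str, enum.Enum):
    """Report text formatting generations."""

    V1 = "V1"  # tabular LABEL: value
    V2 = "V2"  # labelled prose sentences
    V3 = "V3"  # two-column table with synonym labels


class UnitClass(str, enum.Enum):
    UNKNOWN = "unknown"
    CM = "cm"
    MM = "mm"


class FlagReason(str, enum.Enum):
    EXTREME_OUTLIER = "extreme_outlier"
    UNIT_DISCORDANT = "unit_discordant"
    ANATOMICALLY_IMPOSSIBLE = "anatomically_impossible"
    RESIDUAL_OUTLIER = "residual_outlier"


class Disposition(str, enum.Enum):
    PENDING = "pending"
    RETAIN = "retain"
    EDIT = "edit"
    REMOVE = "remove"


@dataclass
class FlagRecord:
    """One pipeline finding on one data point.

    ``proposed_value`` is a detection-time repair suggestion (same scale as
    the value it applies to); ``edited_value`` is the value actually applied
    when the disposition is ``edit``.  ``partner`` links the two members of a
    swap finding (systolic/diastolic or AO/LA field swaps).
    """

    report_id: str
    parameter: EchoParameter
    step: int
    reason: FlagReason
    disposition: Disposition = Disposition.PENDING
    proposed_value: Optional[float] = None
    edited_value: Optional[float] = None
    partner: Optional[EchoParameter] = None
    note: str = ""


@dataclass
class Measurement:
    """One parameter value within one report.

    ``raw_value`` is kept verbatim as parsed.  ``edited_value`` holds a
    rule-based repair applied while units are still unresolved (steps 2-3);
    ``value_mm`` is filled at harmonization and may be edited afterwards
    (step 5 repairs operate in mm).
    """

    parameter: EchoParameter
    raw_value: Optional[float] = None
    value_mm: Optional[float] = None
    status: Status = Status.MISSING
    edited_value: Optional[float] = None
    flags: List[FlagRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.raw_value is not None and self.status == Status.MISSING:
            self.status = Status.PRESENT

    @property
    def effective_raw(self) -> Optional[float]:
        """Raw value with any pre-harmonization edit applied."""
        return self.raw_value if self.edited_value is None else self.edited_value

    @property
    def is_present(self) -> bool:
        return self.raw_value is not None

    @property
    def is_live(self) -> bool:
        """Present and not removed."""
        return self.is_present and self.status != Status.REMOVED


@dataclass
class EchoReport:
    """One echocardiography exam with its six (possibly missing) values."""

    report_id: str
    subject_id: str
    exam_date: str
    dialect: Dialect = Dialect.V1
    measurements: Dict[EchoParameter, Measurement] = field(default_factory=dict)
    unit_class: UnitClass = UnitClass.UNKNOWN

    def __post_init__(self) -> None:
        for p in PARAMETERS:
            if p not in self.measurements:
                self.measurements[p] = Measurement(parameter=p)

    def present_parameters(self) -> List[EchoParameter]:
        return [p for p in PARAMETERS if self.measurements[p].is_present]

    def live_parameters(self) -> List[EchoParameter]:
        return [p for p in PARAMETERS if self.measurements[p].is_live]


@dataclass
class EchoDataset:
    reports: List[EchoReport] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def total_points(self) -> int:
        return 6 * len(self.reports)

    @property
    def n_present(self) -> int:
        return sum(1 for r in self.reports for p in PARAMETERS
                   if r.measurements[p].is_present)

    @property
    def n_missing(self) -> int:
        return self.total_points - self.n_present

    def report(self, report_id: str) -> EchoReport:
        for r in self.reports:
            if r.report_id == report_id:
                return r
        raise KeyError(report_id)

    # ------------------------------------------------------------------
    # Tabular interchange (CSV): one row per report; raw, harmonized mm and
    # status columns per parameter; empty cell = missing.  Provenance rides
    # in a single leading comment line so a round trip is lossless.
    # ------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            row: Dict[str, object] = {
                "report_id": r.report_id,
                "subject_id": r.subject_id,
                "exam_date": r.exam_date,
                "dialect": r.dialect.value,
                "unit_class": r.unit_class.value,
            }
            for p in PARAMETERS:
                m = r.measurements[p]
                row[f"raw_{p.value}"] = m.raw_value
                row[f"mm_{p.value}"] = m.value_mm
                row[f"status_{p.value}"] = m.status.value
            rows.append(row)
        return pd.DataFrame(rows, columns=_INTERCHANGE_COLUMNS)

    def to_csv(self, path_or_buf) -> None:
        frame = self.to_frame()
        header = "# provenance: " + json.dumps(self.provenance, sort_keys=True) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            frame.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(header)
                frame.to_csv(fh, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   provenance: Optional[Dict[str, str]] = None) -> "EchoDataset":
        reports: List[EchoReport] = []
        for _, row in frame.iterrows():
            measurements: Dict[EchoParameter, Measurement] = {}
            for p in PARAMETERS:
                raw = row.get(f"raw_{p.value}")
                mm = row.get(f"mm_{p.value}")
                status = row.get(f"status_{p.value}")
                raw = None if pd.isna(raw) else float(raw)
                mm = None if pd.isna(mm) else float(mm)
                if status is None or pd.isna(status):
                    status = Status.PRESENT if raw is not None else Status.MISSING
                else:
                    status = Status(str(status))
                measurements[p] = Measurement(
                    parameter=p, raw_value=raw, value_mm=mm, status=status)
            unit_class = row.get("unit_class")
            unit_class = (UnitClass(str(unit_class))
                          if unit_class is not None and not pd.isna(unit_class)
                          else UnitClass.UNKNOWN)
            reports.append(EchoReport(
                report_id=str(row["report_id"]),
                subject_id=str(row["subject_id"]),
                exam_date=str(row["exam_date"]),
                dialect=Dialect(str(row["dialect"])),
                measurements=measurements,
                unit_class=unit_class,
            ))
        return cls(reports=reports, provenance=dict(provenance or {}))

    @classmethod
    def read_csv(cls, path_or_buf) -> "EchoDataset":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf, "r", encoding="utf-8") as fh:
                text = fh.read()
        provenance: Dict[str, str] = {}
        if text.startswith("# provenance: "):
            first, _, rest = text.partition("\n")
            provenance = json.loads(first[len("# provenance: "):])
            text = rest
        frame = pd.read_csv(io.StringIO(text), dtype={
            "report_id": str, "subject_id": str, "exam_date": str})
        return cls.from_frame(frame, provenance=provenance)


_INTERCHANGE_COLUMNS = (
    ["report_id", "subject_id", "exam_date", "dialect", "unit_class"]
    + [f"raw_{p.value}" for p in PARAMETERS]
    + [f"mm_{p.value}" for p in PARAMETERS]
    + [f"status_{p.value}" for p in PARAMETERS]
)


# ----------------------------------------------------------------------
# Plausibility configuration
# ----------------------------------------------------------------------

#: Default physiologic plausibility windows in millimetres.  These are wide
#: on purpose: genuinely extreme but real values (e.g. a severely dilated
#: left atrium) must stay inside the window so that they reach review
#: instead of being auto-deleted.
DEFAULT_WINDOWS_MM: Dict[EchoParameter, Tuple[float, float]] = {
    EchoParameter.SEPTUM: (3.0, 35.0),
    EchoParameter.PWT: (3.0, 35.0),
    EchoParameter.LVEDD: (15.0, 100.0),
    EchoParameter.LVESD: (8.0, 90.0),
    EchoParameter.LA: (10.0, 80.0),
    EchoParameter.AO: (10.0, 70.0),
}


@dataclass
class PlausibilityConfig:
    """Windows and pipeline tuning shared by all filtering steps.

    ``threshold_factor`` is the multiplier applied to the origin-proximal
    (centimetre) cluster maximum when deriving per-parameter unit
    thresholds.  ``unit_scale`` is the cm->mm conversion factor and is fixed
    at 10 for this domain.  ``residual_k`` scales the robust
    median-absolute-deviation cutoff of the final residual scan.
    ``cluster_min_frac`` is the minimum fraction of a parameter's values
    that each side of a candidate unit-regime split must hold before the
    split is believed (guards against reading a distribution tail as a
    second unit regime).
    """

    windows_mm: Dict[EchoParameter, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS_MM))
    threshold_factor: float = 1.10
    unit_scale: float = 10.0
    residual_k: float = 6.0
    cluster_min_frac: float = 0.01

    def __post_init__(self) -> None:
        for p, (lo, hi) in self.windows_mm.items():
            if not (0 < lo < hi):
                raise ValueError(f"window for {p} must satisfy 0 < lo < hi")
        if self.threshold_factor <= 1:
            raise ValueError("threshold_factor must exceed 1")
        if self.unit_scale <= 1:
            raise ValueError("unit_scale must exceed 1")

    def window(self, p: EchoParameter) -> Tuple[float, float]:
        return self.windows_mm[p]

    def compatible_as_mm(self, p: EchoParameter, v: float) -> bool:
        lo, hi = self.windows_mm[p]
        return lo <= v <= hi

    def compatible_as_cm(self, p: EchoParameter, v: float) -> bool:
        lo, hi = self.windows_mm[p]
        return lo <= v * self.unit_scale <= hi

    # -- serialization --------------------------------------------------

    def to_dict(self) -> Dict[str, object]:
        return {
            "windows_mm": {p.value: list(w) for p, w in self.windows_mm.items()},
            "threshold_factor": self.threshold_factor,
            "unit_scale": self.unit_scale,
            "residual_k": self.residual_k,
            "cluster_min_frac": self.cluster_min_frac,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PlausibilityConfig":
        windows = dict(DEFAULT_WINDOWS_MM)
        for key, w in dict(d.get("windows_mm", {})).items():
            windows[EchoParameter(key)] = (float(w[0]), float(w[1]))
        return cls(
            windows_mm=windows,
            threshold_factor=float(d.get("threshold_factor", 1.10)),
            unit_scale=float(d.get("unit_scale", 10.0)),
            residual_k=float(d.get("residual_k", 6.0)),
            cluster_min_frac=float(d.get("cluster_min_frac", 0.01)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PlausibilityConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ----------------------------------------------------------------------
# Structural validation
# ----------------------------------------------------------------------

def validate_dataset(ds: EchoDataset) -> List[str]:
    """Check the structural invariants of a dataset.

    Returns a list of human-readable violations (empty when the dataset is
    well formed).  Never raises on content.
    """
    violations: List[str] = []
    seen_ids: set = set()
    for r in ds.reports:
        if r.report_id in seen_ids:
            violations.append(f"duplicate report_id: {r.report_id}")
        seen_ids.add(r.report_id)
        if set(r.measurements) != set(PARAMETERS):
            violations.append(
                f"{r.report_id}: measurements must cover exactly the six parameters")
            continue
        for p in PARAMETERS:
            m = r.measurements[p]
            where = f"{r.report_id}/{p.value}"
            if (m.status == Status.MISSING) != (m.raw_value is None):
                violations.append(
                    f"{where}: status=missing must coincide with absent raw_value")
            if m.value_mm is not None:
                if m.status not in (Status.PRESENT, Status.RETAINED, Status.EDITED):
                    violations.append(
                        f"{where}: value_mm present with status={m.status.value}")
                elif m.value_mm <= 0:
                    violations.append(f"{where}: value_mm must be positive")
            if m.status == Status.EDITED:
                n_edit_flags = sum(
                    1 for f in m.flags if f.disposition == Disposition.EDIT)
                if n_edit_flags != 1:
                    violations.append(
                        f"{where}: edited measurement must carry exactly one "
                        f"edit flag (found {n_edit_flags})")
    n_present = ds.n_present
    if n_present + ds.n_missing != ds.total_points:
        violations.append("present + missing point counts do not sum to 6 x reports")
    return violations
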