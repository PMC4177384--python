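"""Plain-text echocardiography report parsing and rendering.

Clinical echo reports at a single institution typically cycle through a few
formatting generations.  Three concrete dialects are defined here:

* ``V1`` - tabular ``LABEL: value`` lines with terse sonographer labels,
* ``V2`` - labelled prose sentences ("The left ventricle measures 48 at
  end-diastole."),
* ``V3`` - a two-column pipe-separated table with descriptive synonym
  labels.

The layouts are fixed, documented conventions of this package (real report
layouts are institution-specific and not public); they exist to exercise
dialect-robust extraction.  Parsing is strictly unit-agnostic: the parser
captures numbers only and never resolves cm versus mm — unit resolution is
the filtering pipeline's job.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (
    PARAMETERS,
    Dialect,
    EchoDataset,
    EchoParameter,
    EchoReport,
    Measurement,
    Status,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DialectSpec",
    "DIALECTS",
    "ParseError",
    "ParseLog",
    "parse_report",
    "render_report",
    "parse_corpus",
    "detect_dialect",
    "RECORD_SEPARATOR",
]

_NUM = r"(\d+(?:\.\d{1,2})?)"
_UNIT = r"(?:\s*(?:mm|cm))?"

#: Separator line for the newline-delimited multi-report stream format.
RECORD_SEPARATOR = "%%"


class ParseError(ValueError):
    """Raised when a report lacks a parseable header (ids)."""


@dataclass(frozen=True)
class DialectSpec:
    """Labels, layout and header conventions of one report dialect."""

    dialect: Dialect
    labels: Dict[EchoParameter, Tuple[str, ...]]
    header_id: str
    header_subject: str
    header_date: str
    style: str  # "keyvalue" | "prose" | "table"


_V1 = DialectSpec(
    dialect=Dialect.V1,
    labels={
        EchoParameter.SEPTUM: ("IVSd",),
        EchoParameter.PWT: ("LVPWd",),
        EchoParameter.LVEDD: ("LVIDd",),
        EchoParameter.LVESD: ("LVIDs",),
        EchoParameter.LA: ("LA",),
        EchoParameter.AO: ("AO",),
    },
    header_id="REPORT ID",
    header_subject="SUBJECT ID",
    header_date="DATE",
    style="keyvalue",
)

_V3 = DialectSpec(
    dialect=Dialect.V3,
    labels={
        EchoParameter.SEPTUM: ("Septal thickness", "Interventricular septum"),
        EchoParameter.PWT: ("Posterior wall thickness",),
        EchoParameter.LVEDD: ("LV end-diastolic diameter",),
        EchoParameter.LVESD: ("LV end-systolic diameter",),
        EchoParameter.LA: ("Left atrial diameter",),
        EchoParameter.AO: ("Aortic root diameter",),
    },
    header_id="ID",
    header_subject="Subject",
    header_date="Exam date",
    style="table",
)

# V2 prose sentences: one sentence per parameter, rendered from the first
# template; parsing accepts an optional (ignored) unit token after the
# number.
_V2_TEMPLATES: Dict[EchoParameter, str] = {
    EchoParameter.SEPTUM: "The interventricular septum measures {v} at end-diastole.",
    EchoParameter.PWT: "The posterior wall measures {v}.",
    EchoParameter.LVEDD: "The left ventricle measures {v} at end-diastole.",
    EchoParameter.LVESD: "The left ventricle measures {v} at end-systole.",
    EchoParameter.LA: "The left atrium measures {v}.",
    EchoParameter.AO: "The aortic root measures {v}.",
}

_V2_PATTERNS: Dict[EchoParameter, re.Pattern] = {
    EchoParameter.SEPTUM: re.compile(
        rf"interventricular septum measures\s+{_NUM}{_UNIT}", re.I),
    EchoParameter.PWT: re.compile(rf"posterior wall measures\s+{_NUM}{_UNIT}", re.I),
    EchoParameter.LVEDD: re.compile(
        rf"left ventricle measures\s+{_NUM}{_UNIT}\s+at end-diastole", re.I),
    EchoParameter.LVESD: re.compile(
        rf"left ventricle measures\s+{_NUM}{_UNIT}\s+at end-systole", re.I),
    EchoParameter.LA: re.compile(rf"left atrium measures\s+{_NUM}{_UNIT}", re.I),
    EchoParameter.AO: re.compile(rf"aortic root measures\s+{_NUM}{_UNIT}", re.I),
}

_V2 = DialectSpec(
    dialect=Dialect.V2,
    labels={p: (tmpl.split(" measures")[0].replace("The ", ""),)
            for p, tmpl in _V2_TEMPLATES.items()},
    header_id="Echocardiography Report",
    header_subject="Patient",
    header_date="Study date",
    style="prose",
)

DIALECTS: Dict[Dialect, DialectSpec] = {Dialect.V1: _V1, Dialect.V2: _V2, Dialect.V3: _V3}


def _format_number(v: float) -> str:
    """Render a value with at most two decimals, trimming trailing zeros."""
    s = f"{v:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------

def render_report(report: EchoReport, spec: Optional[DialectSpec] = None) -> str:
    """Render a report as text in its (or the given) dialect.

    The inverse of :func:`parse_report` on raw values and missingness.
    """
    spec = spec or DIALECTS[report.dialect]
    lines: List[str] = []
    if spec.style == "keyvalue":
        lines.append(f"{spec.header_id}: {report.report_id}")
        lines.append(f"{spec.header_subject}: {report.subject_id}")
        lines.append(f"{spec.header_date}: {report.exam_date}")
        for p in PARAMETERS:
            m = report.measurements[p]
            if m.raw_value is not None:
                lines.append(f"{spec.labels[p][0]}: {_format_number(m.raw_value)}")
    elif spec.style == "table":
        lines.append("ECHO REPORT")
        lines.append(f"{spec.header_id} | {report.report_id}")
        lines.append(f"{spec.header_subject} | {report.subject_id}")
        lines.append(f"{spec.header_date} | {report.exam_date}")
        for p in PARAMETERS:
            m = report.measurements[p]
            if m.raw_value is not None:
                lines.append(f"{spec.labels[p][0]} | {_format_number(m.raw_value)}")
    else:  # prose
        lines.append(f"{spec.header_id} {report.report_id}")
        lines.append(f"{spec.header_subject}: {report.subject_id}")
        lines.append(f"{spec.header_date}: {report.exam_date}")
        lines.append("")
        for p in PARAMETERS:
            m = report.measurements[p]
            if m.raw_value is not None:
                lines.append(_V2_TEMPLATES[p].format(v=_format_number(m.raw_value)))
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# Parsing
# ----------------------------------------------------------------------

def detect_dialect(text: str) -> Dialect:
    """Pick the dialect whose label set matches the most lines (ties -> V1)."""
    scores: Dict[Dialect, int] = {}
    scores[Dialect.V1] = len(re.findall(
        r"^(?:REPORT ID|SUBJECT ID|DATE|IVSd|LVPWd|LVIDd|LVIDs|LA|AO):",
        text, re.M))
    scores[Dialect.V3] = len(re.findall(r"^[^|\n]+\|", text, re.M))
    scores[Dialect.V2] = sum(
        1 for pat in _V2_PATTERNS.values() if pat.search(text))
    scores[Dialect.V2] += len(re.findall(r"^Echocardiography Report\b", text, re.M))
    best = max(scores.values())
    for d in (Dialect.V1, Dialect.V2, Dialect.V3):  # deterministic tie-break
        if scores[d] == best:
            return d
    return Dialect.V1  # pragma: no cover


def _parse_header_kv(text: str, spec: DialectSpec, sep: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for key, name in ((spec.header_id, "report_id"),
                      (spec.header_subject, "subject_id"),
                      (spec.header_date, "exam_date")):
        m = re.search(rf"^{re.escape(key)}\s*{re.escape(sep)}\s*(\S.*?)\s*$",
                      text, re.M)
        if m:
            out[name] = m.group(1)
    return out


def parse_report(text: str, spec: Optional[DialectSpec] = None,
                 source: str = "<string>") -> EchoReport:
    """Parse one report text into an :class:`EchoReport`.

    Captures each labelled numeric field as an unresolved raw value.  A
    label occurring more than once in one report is ambiguous: both values
    are rejected, the parameter becomes missing and a warning is logged.
    Raises :class:`ParseError` when the header ids cannot be found.
    """
    if not text.strip():
        raise ParseError(f"{source}: empty report text")
    if spec is None:
        spec = DIALECTS[detect_dialect(text)]

    if spec.style == "prose":
        header = {}
        m = re.search(rf"^{re.escape(spec.header_id)}\s+(\S+)\s*$", text, re.M)
        if m:
            header["report_id"] = m.group(1)
        header.update({k: v for k, v in _parse_header_kv(text, spec, ":").items()
                       if k != "report_id"})
    elif spec.style == "table":
        header = _parse_header_kv(text, spec, "|")
    else:
        header = _parse_header_kv(text, spec, ":")

    if "report_id" not in header or "subject_id" not in header:
        raise ParseError(f"{source}: report header missing report/subject id")

    measurements: Dict[EchoParameter, Measurement] = {}
    for p in PARAMETERS:
        values: List[float] = []
        if spec.style == "prose":
            values = [float(v) for v in _V2_PATTERNS[p].findall(text)]
        else:
            sep = "|" if spec.style == "table" else ":"
            for label in spec.labels[p]:
                pat = re.compile(
                    rf"^{re.escape(label)}\s*{re.escape(sep)}\s*{_NUM}{_UNIT}\s*$",
                    re.M | re.I)
                values.extend(float(v) for v in pat.findall(text))
        if len(values) > 1:
            logger.warning("%s: ambiguous duplicate label for %s; "
                           "parameter set to missing", source, p.value)
            values = []
        measurements[p] = Measurement(
            parameter=p,
            raw_value=values[0] if values else None,
        )

    return EchoReport(
        report_id=header["report_id"],
        subject_id=header["subject_id"],
        exam_date=header.get("exam_date", ""),
        dialect=spec.dialect,
        measurements=measurements,
    )


# ----------------------------------------------------------------------
# Corpus parsing
# ----------------------------------------------------------------------

@dataclass
class ParseLog:
    n_files: int = 0
    n_parsed: int = 0
    failures: List[str] = field(default_factory=list)
    dialect_counts: Dict[str, int] = field(default_factory=dict)
    missing_by_parameter: Dict[str, int] = field(default_factory=dict)

    def lines(self) -> List[str]:
        out = [f"files={self.n_files} parsed={self.n_parsed} "
               f"failed={len(self.failures)}"]
        out += [f"dialect {d}: {n}" for d, n in sorted(self.dialect_counts.items())]
        out += [f"missing {p}: {n}"
                for p, n in sorted(self.missing_by_parameter.items())]
        out += [f"FAILED {f}" for f in self.failures]
        return out


def _iter_report_texts(source) -> Iterable[Tuple[str, str]]:
    """Yield (source-name, text) pairs from a directory, file or stream."""
    if hasattr(source, "read"):
        blob = source.read()
        for i, chunk in enumerate(_split_stream(blob)):
            yield f"<stream:{i}>", chunk
        return
    path = Path(source)
    if path.is_dir():
        for fp in sorted(path.glob("*.txt")):
            yield str(fp), fp.read_text(encoding="utf-8")
    else:
        blob = path.read_text(encoding="utf-8")
        for i, chunk in enumerate(_split_stream(blob)):
            yield f"{path}:{i}", chunk


def _split_stream(blob: str) -> List[str]:
    chunks = re.split(rf"^{re.escape(RECORD_SEPARATOR)}\s*$", blob, flags=re.M)
    return [c for c in chunks if c.strip()]


def parse_corpus(source) -> Tuple[EchoDataset, ParseLog]:
    """Parse a directory of ``.txt`` reports (or a separator-delimited
    stream) into a dataset plus a parse log.

    Individual file failures are logged and skipped; they never abort the
    corpus.  An empty source yields an empty dataset with a warning.
    """
    log = ParseLog(missing_by_parameter={p.value: 0 for p in PARAMETERS})
    reports: List[EchoReport] = []
    for name, text in _iter_report_texts(source):
        log.n_files += 1
        try:
            rep = parse_report(text, source=name)
        except ParseError as exc:
            logger.warning("skipping unparseable report: %s", exc)
            log.failures.append(str(exc))
            continue
        reports.append(rep)
        log.n_parsed += 1
        log.dialect_counts[rep.dialect.value] = (
            log.dialect_counts.get(rep.dialect.value, 0) + 1)
        for p in PARAMETERS:
            if not rep.measurements[p].is_present:
                log.missing_by_parameter[p.value] += 1
    if log.n_files == 0:
        logger.warning("parse_corpus: no report files found")
    return EchoDataset(reports=reports), log
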