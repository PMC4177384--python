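"""Five-step filtering of raw echocardiographic measurements.

The pipeline takes a parsed dataset whose values are unit-unresolved (each
report is internally consistent in either centimetres or millimetres, apart
from errors) and produces an analysis-ready dataset in millimetres with a
fully dispositioned review queue:

1. flag values implausible under *both* unit readings (extreme outliers);
2. derive per-parameter unit thresholds from the origin-proximal
   (centimetre) cluster — 110% of that cluster's maximum — and flag values
   on the minority unit side of their own report (unit-discordant points);
3. flag systolic/diastolic diameter pairs with ratio >= 1 (anatomically
   impossible);
4. classify each report's unit regime and harmonize everything to mm
   (centimetre reports are multiplied by 10);
5. rescan the harmonized data with the plausibility windows plus a robust
   median/MAD criterion, including an AO<->LA field-swap repair check.

Flags raised at steps 1-3 and 5 are adjudicated — against a ground-truth
ledger when one exists (synthetic corpora), by conservative repair rules
otherwise — into retain / edit / remove dispositions.  Individual data
points may be removed but reports never are.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ledger import GroundTruthLedger
from .model import (
    PARAMETERS,
    Disposition,
    EchoDataset,
    EchoParameter,
    EchoReport,
    FlagReason,
    FlagRecord,
    Measurement,
    PlausibilityConfig,
    Status,
    UnitClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UnitThresholds",
    "PipelineResult",
    "PipelineError",
    "detect_extreme_outliers",
    "compute_unit_thresholds",
    "detect_unit_discordant",
    "check_anatomical_constraints",
    "harmonize_units",
    "residual_scan",
    "adjudicate",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """Hard error: a pipeline invariant was breached."""


# ----------------------------------------------------------------------
# Step 2a: unit thresholds
# ----------------------------------------------------------------------

@dataclass
class UnitThresholds:
    """Per-parameter thresholds separating centimetre from millimetre values.

    ``threshold[p]`` is ``threshold_factor x cluster_max[p]`` where
    ``cluster_max[p]`` is the maximum of the origin-proximal (cm) cluster.
    ``origin[p]`` records how the threshold was derived: ``"gap"`` when a
    two-cluster split was found in the data, ``"fallback"`` when the corpus
    shows a single regime for that parameter and the threshold defaults to
    the window-boundary value ``hi_mm / unit_scale x threshold_factor``.
    Fallback parameters are classified by window fit rather than by the
    nominal threshold (see :func:`classify_value`).
    """

    threshold: Dict[EchoParameter, float]
    cluster_max: Dict[EchoParameter, float]
    origin: Dict[EchoParameter, str]
    config: PlausibilityConfig

    def classify_value(self, p: EchoParameter, v: float) -> str:
        """Classify one raw value as ``"cm"``, ``"mm"`` or ``"ambiguous"``.

        Gap-derived thresholds split decisively.  For fallback parameters
        there is no empirical regime boundary, so classification falls back
        to window fit; values compatible with both windows (possible only
        where the cm and mm windows overlap, i.e. wall thicknesses and
        LVESD) are ambiguous and follow their report's majority.
        """
        cfg = self.config
        if self.origin[p] == "gap":
            return "cm" if v < self.threshold[p] else "mm"
        cm_ok = cfg.compatible_as_cm(p, v)
        mm_ok = cfg.compatible_as_mm(p, v)
        if cm_ok and not mm_ok:
            return "cm"
        if mm_ok and not cm_ok:
            return "mm"
        return "ambiguous"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": [p.value for p in PARAMETERS],
            "threshold": [self.threshold[p] for p in PARAMETERS],
            "cluster_max": [self.cluster_max[p] for p in PARAMETERS],
            "origin": [self.origin[p] for p in PARAMETERS],
        })


def compute_unit_thresholds(ds: EchoDataset,
                            cfg: PlausibilityConfig) -> UnitThresholds:
    """Derive per-parameter unit thresholds (step 2a).

    For each parameter the present (live) raw values are sorted and the
    origin-proximal cluster is identified as everything below the best
    regime gap: a gap between consecutive values ``a < b`` qualifies when

    * ``b > threshold_factor x a`` (the threshold ``1.1 a`` actually
      separates the clusters),
    * ``a`` fits the centimetre window (``a <= hi / unit_scale``) and ``b``
      fits the millimetre window (``b >= lo``), so the split is a credible
      cm/mm boundary rather than an arbitrary hole, and
    * both sides hold at least ``max(2, cluster_min_frac x n)`` values, so a
      distribution tail is never mistaken for a second unit regime.

    The qualifying gap with the largest ratio ``b / a`` wins (ties break
    toward the smaller-valued cluster) and the threshold is
    ``threshold_factor x a``.  Parameters with fewer than two live values or
    no qualifying gap fall back to the window-boundary threshold
    ``hi / unit_scale x threshold_factor`` (logged); fallback parameters are
    subsequently classified by window fit.

    Step-1 flags must be resolved first: removed extreme values are
    excluded from the derivation.
    """
    thresholds: Dict[EchoParameter, float] = {}
    cluster_max: Dict[EchoParameter, float] = {}
    origin: Dict[EchoParameter, str] = {}
    for p in PARAMETERS:
        lo, hi = cfg.window(p)
        fallback_t = hi / cfg.unit_scale * cfg.threshold_factor
        values = sorted({
            m.effective_raw
            for r in ds.reports
            for m in [r.measurements[p]]
            if m.is_live and m.effective_raw is not None
        })
        if len(values) >= 2:
            # multiplicities matter for the mass condition
            all_vals = sorted(
                m.effective_raw for r in ds.reports
                for m in [r.measurements[p]]
                if m.is_live and m.effective_raw is not None)
            n = len(all_vals)
            min_mass = max(2, math.ceil(cfg.cluster_min_frac * n))
            arr = np.asarray(all_vals)
            best: Optional[Tuple[float, float]] = None  # (ratio, a)
            for a, b in zip(values[:-1], values[1:]):
                if b <= cfg.threshold_factor * a:
                    continue
                if a > hi / cfg.unit_scale or b < lo:
                    continue
                n_below = int((arr <= a).sum())
                n_above = n - n_below
                if n_below < min_mass or n_above < min_mass:
                    continue
                ratio = b / a
                if best is None or ratio > best[0] or (
                        ratio == best[0] and a < best[1]):
                    best = (ratio, a)
            if best is not None:
                cluster_max[p] = best[1]
                thresholds[p] = cfg.threshold_factor * best[1]
                origin[p] = "gap"
                continue
        logger.info("no unit-regime gap for %s; falling back to window "
                    "boundary threshold", p.value)
        cluster_max[p] = hi / cfg.unit_scale
        thresholds[p] = fallback_t
        origin[p] = "fallback"
    return UnitThresholds(threshold=thresholds, cluster_max=cluster_max,
                          origin=origin, config=cfg)


# ----------------------------------------------------------------------
# Detection steps
# ----------------------------------------------------------------------

def detect_extreme_outliers(ds: EchoDataset,
                            cfg: PlausibilityConfig) -> List[FlagRecord]:
    """Step 1: flag values implausible under both unit readings.

    A raw value is window-compatible as mm when it lies inside the
    parameter's plausibility window, and as cm when ten times the value
    does.  Values compatible with neither reading cannot be real
    measurements under any unit convention and go to review.
    """
    flags: List[FlagRecord] = []
    for r in ds.reports:
        for p in PARAMETERS:
            m = r.measurements[p]
            if not m.is_live:
                continue
            v = m.effective_raw
            if cfg.compatible_as_mm(p, v) or cfg.compatible_as_cm(p, v):
                continue
            flags.append(_attach(m, FlagRecord(
                report_id=r.report_id, parameter=p, step=1,
                reason=FlagReason.EXTREME_OUTLIER,
                note=f"raw {v} implausible as mm and as cm")))
    return flags


def _attach(m: Measurement, flag: FlagRecord) -> FlagRecord:
    m.flags.append(flag)
    return flag


def _report_sides(r: EchoReport, th: UnitThresholds) -> Dict[EchoParameter, str]:
    return {p: th.classify_value(p, r.measurements[p].effective_raw)
            for p in r.live_parameters()}


def _corpus_majority_side(ds: EchoDataset, th: UnitThresholds) -> str:
    votes = {"cm": 0, "mm": 0}
    for r in ds.reports:
        for side in _report_sides(r, th).values():
            if side in votes:
                votes[side] += 1
    return "cm" if votes["cm"] > votes["mm"] else "mm"


def detect_unit_discordant(ds: EchoDataset,
                           th: UnitThresholds) -> List[FlagRecord]:
    """Step 2b: flag minority-unit values within internally mixed reports.

    Each live value is classified cm- or mm-side by its parameter's
    threshold.  A report whose definite classifications are not unanimous is
    internally unit-inconsistent; its minority-side points are flagged with
    a proposed unit repair (divide by the unit scale for an mm-side minority
    in a cm report, multiply otherwise).  Reports with a single live value
    cannot be internally discordant and are skipped.  A tied split is
    resolved by treating the report as centimetre-unit (the classic mistake
    is a millimetre entry slipping into a centimetre-era form), so the
    mm-side values are the ones flagged.
    """
    scale = th.config.unit_scale
    flags: List[FlagRecord] = []
    for r in ds.reports:
        live = r.live_parameters()
        if len(live) < 2:
            continue
        sides = _report_sides(r, th)
        n_cm = sum(1 for s in sides.values() if s == "cm")
        n_mm = sum(1 for s in sides.values() if s == "mm")
        if n_cm == 0 or n_mm == 0:
            continue
        majority = "cm" if n_cm >= n_mm else "mm"
        minority = "mm" if majority == "cm" else "cm"
        for p, side in sides.items():
            if side != minority:
                continue
            m = r.measurements[p]
            v = m.effective_raw
            proposed = v / scale if minority == "mm" else v * scale
            flags.append(_attach(m, FlagRecord(
                report_id=r.report_id, parameter=p, step=2,
                reason=FlagReason.UNIT_DISCORDANT,
                proposed_value=round(proposed, 6),
                note=f"{minority}-side value in a {majority}-unit report")))
    return flags


def check_anatomical_constraints(ds: EchoDataset) -> List[FlagRecord]:
    """Step 3: flag reports whose LVESD/LVEDD ratio is >= 1.

    The systolic diameter must be strictly smaller than the diastolic one;
    a ratio at or above one is anatomically impossible.  Both members of
    the pair enter the review queue.  The test is scale-free, so it is safe
    on still-unresolved units as long as step-2 discordance on the pair has
    been repaired.  Reports lacking either value are untestable and logged.
    """
    flags: List[FlagRecord] = []
    for r in ds.reports:
        esd = r.measurements[EchoParameter.LVESD]
        edd = r.measurements[EchoParameter.LVEDD]
        if not (esd.is_live and edd.is_live):
            if esd.is_live or edd.is_live:
                logger.debug("%s: LVESD/LVEDD ratio untestable (one value "
                             "absent)", r.report_id)
            continue
        if esd.effective_raw / edd.effective_raw < 1.0:
            continue
        note = f"LVESD {esd.effective_raw} >= LVEDD {edd.effective_raw}"
        flags.append(_attach(esd, FlagRecord(
            report_id=r.report_id, parameter=EchoParameter.LVESD, step=3,
            reason=FlagReason.ANATOMICALLY_IMPOSSIBLE,
            partner=EchoParameter.LVEDD, note=note)))
        flags.append(_attach(edd, FlagRecord(
            report_id=r.report_id, parameter=EchoParameter.LVEDD, step=3,
            reason=FlagReason.ANATOMICALLY_IMPOSSIBLE,
            partner=EchoParameter.LVESD, note=note)))
    return flags


# ----------------------------------------------------------------------
# Step 4: harmonization
# ----------------------------------------------------------------------

def harmonize_units(ds: EchoDataset, th: UnitThresholds,
                    cfg: PlausibilityConfig) -> EchoDataset:
    """Step 4: classify each report's unit regime and convert to mm.

    Centimetre reports have every live value below its parameter threshold
    and are converted with the fixed factor of 10; millimetre reports are
    taken as-is.  A minority-side value surviving here is legal only when a
    reviewer retained it at step 2 (a genuine value that happens to sit
    across the threshold); such reports take their majority regime.  Any
    other mixed report is an invariant breach and raises
    :class:`PipelineError`.  All-missing reports keep an unknown regime.
    """
    corpus_majority = _corpus_majority_side(ds, th)
    for r in ds.reports:
        live = r.live_parameters()
        if not live:
            continue
        sides = _report_sides(r, th)
        n_cm = sum(1 for s in sides.values() if s == "cm")
        n_mm = sum(1 for s in sides.values() if s == "mm")
        if n_cm and n_mm:
            majority = "cm" if n_cm >= n_mm else "mm"
            minority = "mm" if majority == "cm" else "cm"
            for p, side in sides.items():
                if side != minority:
                    continue
                m = r.measurements[p]
                retained = any(
                    f.step == 2 and f.disposition in
                    (Disposition.RETAIN, Disposition.EDIT) for f in m.flags)
                if not retained:
                    raise PipelineError(
                        f"{r.report_id}/{p.value}: report still unit-mixed at "
                        "harmonization; step 2 should have resolved it")
            regime = majority
        elif n_cm or n_mm:
            regime = "cm" if n_cm else "mm"
        else:
            regime = corpus_majority  # every live value ambiguous
        r.unit_class = UnitClass.CM if regime == "cm" else UnitClass.MM
        factor = cfg.unit_scale if regime == "cm" else 1.0
        for p in live:
            m = r.measurements[p]
            m.value_mm = round(m.effective_raw * factor, 6)
    return ds


# ----------------------------------------------------------------------
# Step 5: residual scan
# ----------------------------------------------------------------------

def residual_scan(ds: EchoDataset, cfg: PlausibilityConfig) -> List[FlagRecord]:
    """Step 5: rescan harmonized values for residual aberrations.

    Re-applies the plausibility windows (now single-regime, in mm) and a
    robust distance criterion: values farther than ``residual_k`` median
    absolute deviations from their parameter's median are flagged.  For a
    flagged aortic root or left atrial value, a field-swap repair is
    probed: when exchanging the two values would make both typical, the
    pair is flagged together with proposed swap edits.
    """
    med: Dict[EchoParameter, float] = {}
    mad: Dict[EchoParameter, float] = {}
    for p in PARAMETERS:
        vals = np.asarray([
            r.measurements[p].value_mm for r in ds.reports
            if r.measurements[p].is_live
            and r.measurements[p].value_mm is not None])
        if len(vals) == 0:
            med[p], mad[p] = float("nan"), 0.0
            continue
        med[p] = float(np.median(vals))
        mad[p] = float(np.median(np.abs(vals - med[p])))

    def typical(p: EchoParameter, v: float) -> bool:
        lo, hi = cfg.window(p)
        if not (lo <= v <= hi):
            return False
        if mad[p] <= 0:
            return True  # degenerate spread: window check only
        return abs(v - med[p]) <= cfg.residual_k * mad[p]

    flags: List[FlagRecord] = []
    for r in ds.reports:
        flagged_here: Dict[EchoParameter, FlagRecord] = {}
        for p in PARAMETERS:
            m = r.measurements[p]
            if not m.is_live or m.value_mm is None:
                continue
            if typical(p, m.value_mm):
                continue
            rec = _attach(m, FlagRecord(
                report_id=r.report_id, parameter=p, step=5,
                reason=FlagReason.RESIDUAL_OUTLIER,
                note=f"harmonized {m.value_mm} mm beyond robust cutoff "
                     f"(median {med[p]:.1f}, MAD {mad[p]:.2f})"))
            flags.append(rec)
            flagged_here[p] = rec

        # AO<->LA field-swap probe on exactly one flagged member of the pair
        for p, q in ((EchoParameter.AO, EchoParameter.LA),
                     (EchoParameter.LA, EchoParameter.AO)):
            rec = flagged_here.get(p)
            if rec is None or flagged_here.get(q) is not None:
                continue
            mp, mq = r.measurements[p], r.measurements[q]
            if not (mq.is_live and mq.value_mm is not None):
                continue
            if typical(p, mq.value_mm) and typical(q, mp.value_mm):
                rec.partner = q
                rec.proposed_value = mq.value_mm
                rec.note += "; field-swap with partner restores typicality"
                partner_rec = _attach(mq, FlagRecord(
                    report_id=r.report_id, parameter=q, step=5,
                    reason=FlagReason.RESIDUAL_OUTLIER,
                    partner=p, proposed_value=mp.value_mm,
                    note="partner of proposed field swap"))
                flags.append(partner_rec)
                break
    return flags


# ----------------------------------------------------------------------
# Adjudication
# ----------------------------------------------------------------------

def _apply_retain(m: Measurement, flag: FlagRecord) -> None:
    flag.disposition = Disposition.RETAIN
    if m.status == Status.PRESENT:
        m.status = Status.RETAINED


def _apply_remove(m: Measurement, flag: FlagRecord) -> None:
    flag.disposition = Disposition.REMOVE
    m.status = Status.REMOVED
    m.value_mm = None


def _apply_edit(m: Measurement, flag: FlagRecord, value: float,
                mm_stage: bool) -> None:
    flag.disposition = Disposition.EDIT
    flag.edited_value = round(value, 6)
    if mm_stage:
        m.value_mm = round(value, 6)
    else:
        m.edited_value = round(value, 6)
    m.status = Status.EDITED


def _swap_pair(r: EchoReport, a: EchoParameter, b: EchoParameter,
               flag_a: FlagRecord, flag_b: Optional[FlagRecord],
               mm_stage: bool) -> None:
    ma, mb = r.measurements[a], r.measurements[b]
    if mm_stage:
        va, vb = ma.value_mm, mb.value_mm
    else:
        va, vb = ma.effective_raw, mb.effective_raw
    _apply_edit(ma, flag_a, vb, mm_stage)
    if flag_b is None:
        flag_b = _attach(mb, FlagRecord(
            report_id=r.report_id, parameter=b, step=flag_a.step,
            reason=flag_a.reason, partner=a,
            note="partner of applied field swap"))
    _apply_edit(mb, flag_b, va, mm_stage)


def adjudicate(queue: Sequence[FlagRecord], ds: EchoDataset,
               ledger: Optional[GroundTruthLedger] = None,
               review_map: Optional[Dict[Tuple[str, str, int], Tuple[str, Optional[float]]]] = None,
               ) -> List[FlagRecord]:
    """Resolve pending flags into retain / edit / remove dispositions.

    Three policies, in order of precedence:

    * an ingested manual-review map (``(report_id, parameter, step) ->
      (disposition, edited_value)``) decides directly;
    * a ground-truth ledger decides automatically — genuine values are
      retained, repairable injected errors are edited back to truth, the
      rest are removed;
    * otherwise conservative repair rules apply: the systolic/diastolic
      swap when swapping fixes the ratio and both values stay plausible,
      the step-2 unit-fix proposal, and the step-5 field-swap proposal.
      Every other flag is removed — edits only ever come from an enumerated
      repair rule, never from guesswork.
    """
    pending = [f for f in queue if f.disposition == Disposition.PENDING]
    handled: set = set()
    for flag in pending:
        key = (flag.report_id, flag.parameter.value, flag.step)
        if key in handled or flag.disposition != Disposition.PENDING:
            continue
        r = ds.report(flag.report_id)
        m = r.measurements[flag.parameter]
        mm_stage = flag.step == 5
        partner_flag = None
        if flag.partner is not None:
            partner_flag = next(
                (f for f in r.measurements[flag.partner].flags
                 if f.step == flag.step and f.disposition == Disposition.PENDING
                 and f is not flag), None)

        if review_map is not None:
            _adjudicate_manual(r, m, flag, review_map, mm_stage)
        elif ledger is not None:
            _adjudicate_ledger(r, m, flag, partner_flag, ledger, mm_stage)
        else:
            _adjudicate_rules(r, m, flag, partner_flag, mm_stage)

        handled.add(key)
        if flag.partner is not None:
            handled.add((flag.report_id, flag.partner.value, flag.step))
    return list(queue)


def _adjudicate_manual(r, m, flag, review_map, mm_stage) -> None:
    key = (flag.report_id, flag.parameter.value, flag.step)
    if key not in review_map:
        raise PipelineError(f"manual review missing disposition for {key}")
    token, value = review_map[key]
    if token == "retain":
        _apply_retain(m, flag)
    elif token == "remove":
        _apply_remove(m, flag)
    elif token == "edit":
        if value is None:
            raise PipelineError(f"manual edit without value for {key}")
        _apply_edit(m, flag, value, mm_stage)
    else:
        raise PipelineError(
            f"unknown disposition token {token!r} for {key}")


def _adjudicate_ledger(r, m, flag, partner_flag, ledger, mm_stage) -> None:
    cls = ledger.error_class(r.report_id, flag.parameter)
    if cls in ("none", "genuine_extreme"):
        _apply_retain(m, flag)
        if partner_flag is not None:
            pm = r.measurements[flag.partner]
            pcls = ledger.error_class(r.report_id, flag.partner)
            if pcls in ("none", "genuine_extreme"):
                _apply_retain(pm, partner_flag)
        return
    repair = ledger.repair(r.report_id, flag.parameter)
    if repair.startswith("scale:"):
        factor = float(repair.split(":", 1)[1])
        base = m.value_mm if mm_stage else m.effective_raw
        _apply_edit(m, flag, base * factor, mm_stage)
    elif repair.startswith("swap:"):
        partner = EchoParameter(repair.split(":", 1)[1])
        _swap_pair(r, flag.parameter, partner, flag, partner_flag, mm_stage)
    else:
        _apply_remove(m, flag)
        if partner_flag is not None and ledger.is_erroneous(
                r.report_id, flag.partner):
            prepair = ledger.repair(r.report_id, flag.partner)
            if not prepair:
                _apply_remove(r.measurements[flag.partner], partner_flag)


def _adjudicate_rules(r, m, flag, partner_flag, mm_stage) -> None:
    cfg_compat = None
    if flag.reason == FlagReason.UNIT_DISCORDANT and flag.proposed_value is not None:
        _apply_edit(m, flag, flag.proposed_value, mm_stage)
        return
    if flag.reason == FlagReason.ANATOMICALLY_IMPOSSIBLE and flag.partner is not None:
        # swap repairs the ratio whenever the original ratio was >= 1 and
        # strictly so; equal values cannot be fixed by swapping
        esd = r.measurements[EchoParameter.LVESD].effective_raw
        edd = r.measurements[EchoParameter.LVEDD].effective_raw
        if esd is not None and edd is not None and edd < esd:
            _swap_pair(r, flag.parameter, flag.partner, flag, partner_flag,
                       mm_stage)
            return
    if (flag.reason == FlagReason.RESIDUAL_OUTLIER and flag.partner is not None
            and flag.proposed_value is not None):
        _swap_pair(r, flag.parameter, flag.partner, flag, partner_flag, mm_stage)
        return
    _apply_remove(m, flag)
    if partner_flag is not None:
        _apply_remove(r.measurements[flag.partner], partner_flag)


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

@dataclass
class PipelineResult:
    cleaned: EchoDataset
    queue: List[FlagRecord]
    thresholds: UnitThresholds
    counters: Dict[str, Dict[str, int]]
    config: PlausibilityConfig

    def audit_frame(self) -> pd.DataFrame:
        """One row per flag: the full audit trail."""
        rows = []
        for f in self.queue:
            r = self.cleaned.report(f.report_id)
            m = r.measurements[f.parameter]
            rows.append({
                "report_id": f.report_id,
                "parameter": f.parameter.value,
                "step": f.step,
                "reason": f.reason.value,
                "disposition": f.disposition.value,
                "raw": m.raw_value,
                "edited": f.edited_value,
                "final_mm": m.value_mm,
                "partner": f.partner.value if f.partner else "",
                "note": f.note,
            })
        return pd.DataFrame(rows, columns=[
            "report_id", "parameter", "step", "reason", "disposition",
            "raw", "edited", "final_mm", "partner", "note"])


def _count_step(queue: Sequence[FlagRecord], step: int) -> Dict[str, int]:
    flags = [f for f in queue if f.step == step]
    return {
        "flagged": len(flags),
        "retained": sum(1 for f in flags if f.disposition == Disposition.RETAIN),
        "edited": sum(1 for f in flags if f.disposition == Disposition.EDIT),
        "removed": sum(1 for f in flags if f.disposition == Disposition.REMOVE),
    }


def run_pipeline(ds: EchoDataset, cfg: Optional[PlausibilityConfig] = None,
                 ledger: Optional[GroundTruthLedger] = None,
                 review_map: Optional[Dict] = None) -> PipelineResult:
    """Run the five filtering steps in order on a copy of ``ds``.

    Deterministic given (dataset, config, ledger).  Detection steps 1-3
    each adjudicate before the next step runs, because threshold
    derivation, the discordance scan and the anatomical check are defined
    on data free of the previous step's errors.  Hard errors from
    components propagate; no partial result is returned.
    """
    cfg = cfg or PlausibilityConfig()
    if ledger is not None and not ledger.covers(ds):
        raise PipelineError("ground-truth ledger does not cover the corpus")
    work = copy.deepcopy(ds)
    queue: List[FlagRecord] = []

    step1 = detect_extreme_outliers(work, cfg)
    adjudicate(step1, work, ledger, review_map)
    queue.extend(step1)

    thresholds = compute_unit_thresholds(work, cfg)
    step2 = detect_unit_discordant(work, thresholds)
    adjudicate(step2, work, ledger, review_map)
    queue.extend(step2)

    step3 = check_anatomical_constraints(work)
    adjudicate(step3, work, ledger, review_map)
    queue.extend(step3)

    harmonize_units(work, thresholds, cfg)

    step5 = residual_scan(work, cfg)
    adjudicate(step5, work, ledger, review_map)
    queue.extend(step5)

    if any(f.disposition == Disposition.PENDING for f in queue):
        raise PipelineError("pending dispositions survived the pipeline")

    counters = {f"step{k}": _count_step(queue, k) for k in (1, 2, 3, 5)}
    counters["total"] = {
        key: sum(counters[f"step{k}"][key] for k in (1, 2, 3, 5))
        for key in ("flagged", "retained", "edited", "removed")}
    work.provenance = dict(work.provenance)
    work.provenance.update({
        "pipeline": "echoqc-5step",
        "config_hash": cfg.config_hash(),
    })
    for step_name in ("step1", "step2", "step3", "step5"):
        logger.info("%s: %s", step_name, counters[step_name])
    return PipelineResult(cleaned=work, queue=queue, thresholds=thresholds,
                          counters=counters, config=cfg)
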