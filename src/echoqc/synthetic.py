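"""Paper-calibrated synthetic echocardiography corpora with ground truth.

The generator emulates a clinic-based adult cohort: subject-level correlated
six-parameter profiles drawn from sex-specific distributions (published
EMR-cohort means and SDs), a geometric-tailed number of exams per subject
(median 1, IQR 1-2, truncated at 30), per-report measurement-unit regimes
(roughly a third of reports in centimetres), three report-text dialects,
~9% missing data points, and a configurable set of injected error classes
mimicking real transcription and unit mistakes.  Every present data point
is covered by a ground-truth ledger, so the filtering pipeline can be
adjudicated and scored without any EMR access.

Subject latent profiles use stratified (Latin-hypercube) normal scores so
that empirical per-sex means converge at O(1/n) rather than O(1/sqrt(n));
window truncation is pre-compensated so realized means sit on their
published targets.
"""

from __future__ import annotations

import copy
import datetime
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import truncnorm

from .ledger import GroundTruthLedger
from .model import (
    DEFAULT_WINDOWS_MM,
    PARAMETERS,
    Dialect,
    EchoDataset,
    EchoParameter,
    EchoReport,
    Measurement,
    PlausibilityConfig,
    Status,
)
from .reports import render_report

__all__ = [
    "GeneratorConfig",
    "ErrorInjectionSpec",
    "generate_cohort",
    "inject_errors",
    "write_corpus",
    "DEFAULT_CORRELATION",
]

_ORDER = list(PARAMETERS)  # SEPTUM, PWT, LVEDD, LVESD, LA, AO

#: Sex-specific parameter means and SDs in millimetres (clinic-based adult
#: African-American echo cohort values).
_MEANS_MM = {
    "F": {"SEPTUM": 11.0, "PWT": 10.5, "LVEDD": 44.4,
          "LVESD": 29.0, "LA": 37.4, "AO": 28.4},
    "M": {"SEPTUM": 12.0, "PWT": 11.4, "LVEDD": 48.5,
          "LVESD": 33.3, "LA": 40.1, "AO": 32.8},
}
_SDS_MM = {
    "F": {"SEPTUM": 2.5, "PWT": 2.2, "LVEDD": 7.6,
          "LVESD": 8.4, "LA": 7.3, "AO": 3.6},
    "M": {"SEPTUM": 2.8, "PWT": 2.5, "LVEDD": 8.8,
          "LVESD": 10.7, "LA": 8.0, "AO": 4.1},
}
_AGES = {"F": (57.9, 17.6), "M": (58.6, 15.9)}

#: Modest positive inter-parameter correlations; LV systolic and diastolic
#: diameters are strongly coupled so that anatomically impossible
#: (ESD >= EDD) profiles are vanishingly rare before injection.
#: Order: SEPTUM, PWT, LVEDD, LVESD, LA, AO.
DEFAULT_CORRELATION = np.array([
    [1.00, 0.60, 0.20, 0.20, 0.30, 0.30],
    [0.60, 1.00, 0.20, 0.20, 0.30, 0.30],
    [0.20, 0.20, 1.00, 0.80, 0.40, 0.30],
    [0.20, 0.20, 0.80, 1.00, 0.35, 0.25],
    [0.30, 0.30, 0.40, 0.35, 1.00, 0.40],
    [0.30, 0.30, 0.30, 0.25, 0.40, 1.00],
])


@dataclass
class GeneratorConfig:
    """Conditions of the emulated cohort.

    ``n_reports`` (when set) overrides ``n_subjects``: subjects are added
    until the corpus holds exactly that many reports.  ``echo_geom_p`` is
    the success probability of the geometric exam-count distribution
    (p = 0.55 gives median 1 and IQR [1, 2]).  ``cm_report_fraction``
    defaults to the published 2,132 / 6,076.  ``within_subject_sd_frac``
    scales repeat-exam noise relative to the between-subject SD.
    """

    n_subjects: int = 3000
    n_reports: Optional[int] = None
    echo_geom_p: float = 0.55
    echo_max: int = 30
    female_fraction: float = 0.598
    means_mm: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in _MEANS_MM.items()})
    sds_mm: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in _SDS_MM.items()})
    correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATION.copy())
    cm_report_fraction: float = 2132 / 6076
    dialect_weights: Dict[str, float] = field(
        default_factory=lambda: {"V1": 1 / 3, "V2": 1 / 3, "V3": 1 / 3})
    missing_rate: float = 0.09
    within_subject_sd_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for s in ("F", "M"):
            if any(v <= 0 for v in self.sds_mm[s].values()):
                raise ValueError("all SDs must be positive")
        np.linalg.cholesky(self.correlation)  # must be positive-definite
        for rate in (self.female_fraction, self.cm_report_fraction,
                     self.missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ErrorInjectionSpec:
    """Error-class counts, expressed per reference corpus size.

    Defaults reproduce the published review-queue composition at 6,076
    reports: 16 nonsense extreme values, 55 within-report unit mixes, 16
    records with swapped systolic/diastolic fields (32 data points), 2
    records with the aortic-root and left-atrial fields swapped, and 3
    genuinely extreme values that the pipeline must flag and retain.
    Counts rescale proportionally (half-up) for other corpus sizes.
    """

    nonsense_extreme: int = 16
    within_report_unit_mix: int = 55
    sysdias_swap_records: int = 16
    ao_la_swap_records: int = 2
    genuine_extreme: int = 3
    reference_reports: int = 6076
    seed: int = 1

    def scaled_counts(self, n_reports: int) -> Dict[str, int]:
        f = n_reports / self.reference_reports
        return {
            "nonsense_extreme": _round_half_up(self.nonsense_extreme * f),
            "within_report_unit_mix": _round_half_up(
                self.within_report_unit_mix * f),
            "sysdias_swap_records": _round_half_up(self.sysdias_swap_records * f),
            "ao_la_swap_records": _round_half_up(self.ao_la_swap_records * f),
            "genuine_extreme": _round_half_up(self.genuine_extreme * f),
        }


# ----------------------------------------------------------------------
# Cohort generation
# ----------------------------------------------------------------------

def _truncnorm_compensated_mu(mu: float, sd: float, lo: float,
                              hi: float) -> float:
    """Latent mean whose [lo, hi]-truncated mean equals the target ``mu``."""
    mu_adj = mu
    for _ in range(4):
        a, b = (lo - mu_adj) / sd, (hi - mu_adj) / sd
        mu_adj += mu - truncnorm.mean(a, b, loc=mu_adj, scale=sd)
    return mu_adj


def _valid_rows(vals: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Rows within all windows and with rounded LVESD < LVEDD."""
    ok = np.all((vals >= windows[:, 0]) & (vals <= windows[:, 1]), axis=1)
    i_edd = _ORDER.index(EchoParameter.LVEDD)
    i_esd = _ORDER.index(EchoParameter.LVESD)
    ok &= np.round(vals[:, i_esd], 1) < np.round(vals[:, i_edd], 1)
    return ok


def _stratified_normals(rng: np.random.Generator, n: int, dims: int) -> np.ndarray:
    """Latin-hypercube standard normal scores, one column per dimension."""
    z = np.empty((n, dims))
    for j in range(dims):
        u = (rng.permutation(n) + rng.random(n)) / n
        z[:, j] = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
    return z


def _draw_profiles(rng: np.random.Generator, n: int, sex: str,
                   cfg: GeneratorConfig, windows: np.ndarray) -> np.ndarray:
    mus = np.array([cfg.means_mm[sex][p.value] for p in _ORDER])
    sds = np.array([cfg.sds_mm[sex][p.value] for p in _ORDER])
    mus_adj = np.array([
        _truncnorm_compensated_mu(mu, sd, lo, hi)
        for mu, sd, (lo, hi) in zip(mus, sds, windows)])
    chol = np.linalg.cholesky(cfg.correlation)
    # Joint rejection (windows plus ESD < EDD) also shifts the means of
    # *correlated* parameters, which the marginal compensation above cannot
    # see; a short pilot simulation measures and removes the residual shift
    # so realized means sit on their published targets.
    n_pilot = 40000
    for _ in range(2):
        zp = rng.standard_normal((n_pilot, len(_ORDER)))
        pilot = mus_adj + (zp @ chol.T) * sds
        ok = _valid_rows(pilot, windows)
        mus_adj -= pilot[ok].mean(axis=0) - mus
    z = _stratified_normals(rng, n, len(_ORDER))
    vals = mus_adj + (z @ chol.T) * sds
    ok = _valid_rows(vals, windows)
    for _ in range(100):
        if ok.all():
            break
        bad = ~ok
        z_new = rng.standard_normal((int(bad.sum()), len(_ORDER)))
        vals[bad] = mus_adj + (z_new @ chol.T) * sds
        ok = _valid_rows(vals, windows)
    if not ok.all():
        raise RuntimeError("could not draw window-consistent profiles")
    return vals


def _exam_values(rng: np.random.Generator, latent: np.ndarray, sex: str,
                 cfg: GeneratorConfig, windows: np.ndarray) -> np.ndarray:
    sds = np.array([cfg.sds_mm[sex][p.value] for p in _ORDER])
    noise_sd = cfg.within_subject_sd_frac * sds
    vals = latent + rng.standard_normal(len(_ORDER)) * noise_sd
    for _ in range(100):
        if _valid_rows(vals[None, :], windows)[0]:
            return vals
        vals = latent + rng.standard_normal(len(_ORDER)) * noise_sd
    raise RuntimeError("could not draw a window-consistent exam")


def _exam_counts(rng: np.random.Generator, cfg: GeneratorConfig,
                 n: int) -> np.ndarray:
    counts = rng.geometric(cfg.echo_geom_p, size=n)
    while (counts > cfg.echo_max).any():
        bad = counts > cfg.echo_max
        counts[bad] = rng.geometric(cfg.echo_geom_p, size=int(bad.sum()))
    return counts


def generate_cohort(cfg: Optional[GeneratorConfig] = None,
                    plausibility: Optional[PlausibilityConfig] = None,
                    ) -> Tuple[EchoDataset, GroundTruthLedger]:
    """Generate a clean (error-free) corpus plus its ground-truth ledger.

    Truth values are drawn per subject from sex-specific correlated normals
    truncated (by redraw) to the plausibility windows, with per-exam
    within-subject noise, then rounded to 0.1 mm.  Each report is assigned
    a unit regime, a dialect and missing points; centimetre reports carry
    ``truth / 10`` as their raw values.  Identical config and seed give a
    byte-identical corpus.
    """
    cfg = cfg or GeneratorConfig()
    plaus = plausibility or PlausibilityConfig()
    windows = np.array([plaus.window(p) for p in _ORDER])
    rng = np.random.default_rng(cfg.seed)

    # exam counts / subject roster
    if cfg.n_reports is not None:
        counts_list: List[int] = []
        total = 0
        while total < cfg.n_reports:
            chunk = _exam_counts(rng, cfg, max(256, cfg.n_reports // 4))
            for c in chunk:
                c = int(min(c, cfg.n_reports - total))
                if c <= 0:
                    break
                counts_list.append(c)
                total += c
                if total >= cfg.n_reports:
                    break
        counts = np.array(counts_list)
    else:
        counts = _exam_counts(rng, cfg, cfg.n_subjects)
    n_subjects = len(counts)

    # sex assignment: exact female fraction, shuffled
    n_f = _round_half_up(cfg.female_fraction * n_subjects)
    sexes = np.array(["F"] * n_f + ["M"] * (n_subjects - n_f))
    rng.shuffle(sexes)

    # subject latent profiles, drawn per sex with stratified scores
    latents = np.empty((n_subjects, len(_ORDER)))
    ages = np.empty(n_subjects)
    for sex in ("F", "M"):
        idx = np.flatnonzero(sexes == sex)
        if len(idx) == 0:
            continue
        latents[idx] = _draw_profiles(rng, len(idx), sex, cfg, windows)
        mu_a, sd_a = _AGES[sex]
        a = rng.normal(mu_a, sd_a, size=len(idx))
        while (a < 18).any():
            bad = a < 18
            a[bad] = rng.normal(mu_a, sd_a, size=int(bad.sum()))
        ages[idx] = np.round(a, 1)

    n_reports = int(counts.sum())
    # per-report attributes: unit regime, dialect, missingness
    n_cm = _round_half_up(cfg.cm_report_fraction * n_reports)
    regimes = np.array(["cm"] * n_cm + ["mm"] * (n_reports - n_cm))
    rng.shuffle(regimes)

    names = sorted(cfg.dialect_weights)
    w = np.array([cfg.dialect_weights[d] for d in names], dtype=float)
    w = w / w.sum()
    dialect_counts = np.floor(w * n_reports).astype(int)
    rest = n_reports - dialect_counts.sum()
    for k in range(rest):
        dialect_counts[k % len(names)] += 1
    dialects = np.repeat(names, dialect_counts)
    rng.shuffle(dialects)

    n_missing = _round_half_up(cfg.missing_rate * 6 * n_reports)
    missing_idx = rng.choice(6 * n_reports, size=n_missing, replace=False)
    missing_mask = np.zeros(6 * n_reports, dtype=bool)
    missing_mask[missing_idx] = True

    reports: List[EchoReport] = []
    point_rows: List[Dict[str, object]] = []
    report_rows: List[Dict[str, object]] = []
    base_date = datetime.date(1997, 1, 1)
    rid = 0
    for si, (c, sex) in enumerate(zip(counts, sexes)):
        subject_id = f"S{si + 1:05d}"
        day_offsets = np.sort(rng.integers(0, 17 * 365, size=int(c)))
        for j in range(int(c)):
            report_id = f"R{rid + 1:06d}"
            regime = regimes[rid]
            exam = _exam_values(rng, latents[si], sex, cfg, windows)
            truth = np.round(exam, 1)
            measurements: Dict[EchoParameter, Measurement] = {}
            for k, p in enumerate(_ORDER):
                if missing_mask[rid * 6 + k]:
                    measurements[p] = Measurement(parameter=p)
                    continue
                t = float(truth[k])
                raw = round(t / 10.0, 2) if regime == "cm" else round(t, 1)
                measurements[p] = Measurement(parameter=p, raw_value=raw)
                point_rows.append({
                    "report_id": report_id, "parameter": p.value,
                    "true_mm": t, "error_class": "none", "repair": ""})
            exam_date = (base_date
                         + datetime.timedelta(days=int(day_offsets[j]))).isoformat()
            reports.append(EchoReport(
                report_id=report_id, subject_id=subject_id,
                exam_date=exam_date, dialect=Dialect(dialects[rid]),
                measurements=measurements))
            report_rows.append({
                "report_id": report_id, "subject_id": subject_id,
                "unit_regime": regime})
            rid += 1

    subjects = pd.DataFrame({
        "subject_id": [f"S{i + 1:05d}" for i in range(n_subjects)],
        "sex": sexes,
        "age": ages,
    })
    ds = EchoDataset(reports=reports, provenance={
        "description": "synthetic echo corpus",
        "generator_seed": str(cfg.seed),
    })
    ledger = GroundTruthLedger(
        points=pd.DataFrame(point_rows,
                            columns=["report_id", "parameter", "true_mm",
                                     "error_class", "repair"]),
        reports=pd.DataFrame(report_rows),
        subjects=subjects,
    )
    return ds, ledger


# ----------------------------------------------------------------------
# Error injection
# ----------------------------------------------------------------------

def _raw_for(regime: str, value_mm: float) -> float:
    return round(value_mm / 10.0, 2) if regime == "cm" else round(value_mm, 1)


def inject_errors(ds: EchoDataset, ledger: GroundTruthLedger,
                  spec: Optional[ErrorInjectionSpec] = None,
                  plausibility: Optional[PlausibilityConfig] = None,
                  ) -> Tuple[EchoDataset, GroundTruthLedger]:
    """Corrupt a clean corpus with the configured error classes.

    Classes never overlap: each touched report hosts at most one class.
    Targets are chosen so that every injected error is structurally
    detectable (swapped diameters stay window-plausible, unit mixes land in
    the body of the opposite cluster, swapped AO values exceed the robust
    review cutoff) — mirroring how these mistakes arise in real reports,
    where a mis-entered value is a plausible value of the wrong field or
    unit.  Raises when a requested count exceeds the eligible points.
    """
    spec = spec or ErrorInjectionSpec()
    plaus = plausibility or PlausibilityConfig()
    rng = np.random.default_rng(spec.seed)
    out = copy.deepcopy(ds)
    led = GroundTruthLedger(points=ledger.points.copy(),
                            reports=ledger.reports.copy(),
                            subjects=ledger.subjects.copy())
    counts = spec.scaled_counts(out.n_reports)

    # pooled per-parameter truth statistics drive eligibility margins
    pts = led.points
    mu_pool = {p: float(pts.loc[pts.parameter == p.value, "true_mm"].mean())
               for p in PARAMETERS}
    sd_pool = {p: float(pts.loc[pts.parameter == p.value, "true_mm"].std())
               for p in PARAMETERS}

    order = rng.permutation(out.n_reports)
    used: set = set()

    def regime_of(r: EchoReport) -> str:
        return led.unit_regime(r.report_id) or "mm"

    def take_reports(n_needed: int, eligible) -> List[EchoReport]:
        picked: List[EchoReport] = []
        for i in order:
            if len(picked) == n_needed:
                break
            r = out.reports[i]
            if r.report_id in used or not eligible(r):
                continue
            picked.append(r)
            used.add(r.report_id)
        if len(picked) < n_needed:
            raise ValueError(
                f"not enough eligible reports for injection "
                f"({len(picked)}/{n_needed})")
        return picked

    # -- genuine extremes: valid values just beyond the robust cutoff ----
    genuine_params = [EchoParameter.LA, EchoParameter.LA, EchoParameter.SEPTUM]
    n_gen = counts["genuine_extreme"]
    targets = [genuine_params[i % len(genuine_params)] for i in range(n_gen)]
    for p in targets:
        (r,) = take_reports(1, lambda rep, p=p: rep.measurements[p].is_present)
        lo, hi = plaus.window(p)
        v = mu_pool[p] + (4.3 + 0.4 * rng.random()) * sd_pool[p]
        v = round(min(v, hi - 0.1), 1)
        r.measurements[p].raw_value = _raw_for(regime_of(r), v)
        led.set_point(r.report_id, p, true_mm=v,
                      error_class="genuine_extreme", repair="")

    # -- AO<->LA field swaps ---------------------------------------------
    def ao_la_ok(r: EchoReport) -> bool:
        ao, la = r.measurements[EchoParameter.AO], r.measurements[EchoParameter.LA]
        if not (ao.is_present and la.is_present):
            return False
        la_t = led.true_mm(r.report_id, EchoParameter.LA)
        hi_ao = plaus.window(EchoParameter.AO)[1]
        return (la_t >= mu_pool[EchoParameter.AO]
                + 4.5 * sd_pool[EchoParameter.AO]
                and la_t <= hi_ao - 0.5)

    for r in take_reports(counts["ao_la_swap_records"], ao_la_ok):
        regime = regime_of(r)
        ao_t = led.true_mm(r.report_id, EchoParameter.AO)
        la_t = led.true_mm(r.report_id, EchoParameter.LA)
        r.measurements[EchoParameter.AO].raw_value = _raw_for(regime, la_t)
        r.measurements[EchoParameter.LA].raw_value = _raw_for(regime, ao_t)
        led.set_point(r.report_id, EchoParameter.AO,
                      error_class="ao_la_field_swap", repair="swap:LA")
        led.set_point(r.report_id, EchoParameter.LA,
                      error_class="ao_la_field_swap", repair="swap:AO")

    # -- systolic/diastolic field swaps ----------------------------------
    def sysdias_ok(r: EchoReport) -> bool:
        esd = r.measurements[EchoParameter.LVESD]
        edd = r.measurements[EchoParameter.LVEDD]
        if not (esd.is_present and edd.is_present):
            return False
        esd_t = led.true_mm(r.report_id, EchoParameter.LVESD)
        edd_t = led.true_mm(r.report_id, EchoParameter.LVEDD)
        lo_edd, _hi_edd = plaus.window(EchoParameter.LVEDD)
        _lo_esd, hi_esd = plaus.window(EchoParameter.LVESD)
        # swapped values must stay window-plausible in both fields
        return esd_t >= lo_edd and edd_t <= hi_esd

    for r in take_reports(counts["sysdias_swap_records"], sysdias_ok):
        regime = regime_of(r)
        esd_t = led.true_mm(r.report_id, EchoParameter.LVESD)
        edd_t = led.true_mm(r.report_id, EchoParameter.LVEDD)
        r.measurements[EchoParameter.LVESD].raw_value = _raw_for(regime, edd_t)
        r.measurements[EchoParameter.LVEDD].raw_value = _raw_for(regime, esd_t)
        led.set_point(r.report_id, EchoParameter.LVESD,
                      error_class="sysdias_swap", repair="swap:LVEDD")
        led.set_point(r.report_id, EchoParameter.LVEDD,
                      error_class="sysdias_swap", repair="swap:LVESD")

    # -- within-report unit mixes ----------------------------------------
    def mix_candidates(r: EchoReport) -> List[EchoParameter]:
        if len(r.present_parameters()) < 3:
            return []
        out_p = []
        for p in r.present_parameters():
            t = led.true_mm(r.report_id, p)
            if abs(t - mu_pool[p]) <= 2.0 * sd_pool[p]:
                out_p.append(p)
        return out_p

    for r in take_reports(counts["within_report_unit_mix"],
                          lambda rep: bool(mix_candidates(rep))):
        cands = mix_candidates(r)
        p = cands[int(rng.integers(len(cands)))]
        m = r.measurements[p]
        regime = regime_of(r)
        if regime == "cm":  # one value entered in millimetres
            m.raw_value = round(m.raw_value * 10.0, 2)
            led.set_point(r.report_id, p,
                          error_class="within_report_unit_mix",
                          repair="scale:0.1")
        else:               # one value entered in centimetres
            m.raw_value = round(m.raw_value / 10.0, 2)
            led.set_point(r.report_id, p,
                          error_class="within_report_unit_mix",
                          repair="scale:10")

    # -- nonsense extreme values -----------------------------------------
    for r in take_reports(counts["nonsense_extreme"],
                          lambda rep: bool(rep.present_parameters())):
        present = r.present_parameters()
        p = present[int(rng.integers(len(present)))]
        _lo, hi = plaus.window(p)
        v = round(hi * (2.0 + 8.0 * rng.random()), 1)
        r.measurements[p].raw_value = v
        led.set_point(r.report_id, p,
                      error_class="nonsense_extreme", repair="")

    return out, led


# ----------------------------------------------------------------------
# Corpus rendering
# ----------------------------------------------------------------------

def write_corpus(ds: EchoDataset, out_dir) -> List[Path]:
    """Render every report to ``<out_dir>/<report_id>.txt`` in its dialect.

    ``parse_corpus`` over the output recovers raw values and missingness
    exactly.  Raises on an unwritable directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    for r in ds.reports:
        fp = out / f"{r.report_id}.txt"
        fp.write_text(render_report(r), encoding="utf-8")
        paths.append(fp)
    return paths
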