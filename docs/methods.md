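# Methods

This note documents the models, rules and numerical choices behind
`echoqc`: what the filtering pipeline assumes, what the synthetic corpus
generator does and does not emulate, and where the design was genuinely
open.

## Data model and units

Six structural parameters are modelled per exam: SEPTUM (interventricular
septal thickness), PWT (posterior wall thickness), LVEDD / LVESD (LV
end-diastolic / end-systolic internal diameters), LA (left atrial
diameter), AO (aortic root diameter). The canonical unit downstream of
harmonization is the millimetre, converted from centimetres by the fixed
factor 10. The parsed raw value is kept verbatim forever; edits are stored
separately so that the audit trail reconstructs every transformation. A
surviving value is always one of: the raw value, the raw value × 10, or a
documented swap of two raw values (optionally × 10). No other
transformation exists, and no value is ever imputed.

Dates are treated as opaque ordered strings (source EMR dates are
randomly shifted), and reports are never removed wholesale — only
individual data points are.

## Plausibility windows

Defaults, in mm: SEPTUM [3, 35], PWT [3, 35], LVEDD [15, 100], LVESD
[8, 90], LA [10, 80], AO [10, 70]. These are deliberately *wide* —
roughly the envelope of extreme pathology rather than reference ranges —
because their job is to catch values impossible under **either** unit
reading, while keeping genuinely extreme physiology (a severely dilated
atrium, massive hypertrophy) inside the window so it reaches review
instead of being silently deleted. A raw value is "compatible as mm" when
inside the window and "compatible as cm" when ten times it is; step 1
flags values compatible with neither. All windows are configurable via
YAML.

Note the structural consequence: for LVEDD, LA and AO the cm range
(window/10) and the mm window do not overlap, so a single value decides
its unit; for the wall thicknesses and LVESD the ranges adjoin
([3, 3.5], [8, 9]), so a small sliver of values is intrinsically
unit-ambiguous in isolation and must be resolved by report context.

## Unit-threshold derivation (step 2)

The defining rule is: threshold = `threshold_factor` (default 1.10) × the
maximum of the origin-proximal (centimetre) cluster, per parameter. The
open design question is how to find that cluster automatically in pooled
data (the original procedure was visual). The rule used here: sort the
live values; a gap between consecutive values `a < b` is a credible
regime split when

* `b > 1.10 a` — the derived threshold actually separates the clusters;
* `a ≤ h_p/10` and `b ≥ ℓ_p` — the lower side fits the cm window and the
  upper side the mm window, so the split sits where a cm/mm boundary can
  physically be;
* both sides hold at least `max(2, 1% of n)` values (`cluster_min_frac`),
  so a sparse distribution tail is never read as a second unit regime.

The qualifying gap with the largest ratio `b/a` wins; ties break toward
the smaller cluster. This matters because realistic cm and mm clusters
*adjoin* rather than gape: with ~20% coefficients of variation the top of
the cm cluster and the bottom of the mm cluster sit only a factor ~1.3–2
apart, so any rule demanding a large absolute separation would never
fire. The mass condition is what keeps a lone small value in a
single-regime corpus from splitting it.

When no qualifying gap exists (single-regime corpus, or < 2 values) the
parameter falls back to the window-boundary threshold
`h_p/10 × 1.10` (logged), and — because that nominal boundary has no
empirical support — per-value classification for fallback parameters uses
window fit instead: values compatible only as cm are cm-side, only as mm
are mm-side, and values in the overlap sliver are *ambiguous* and follow
their report's majority. This keeps single-regime corpora stable: a
genuine 3.2 mm septum in an all-mm corpus is ambiguous, follows its
report, and is not spuriously "repaired" to 32 mm.

Within a report, minority-side values are flagged unit-discordant with a
proposed ×10 / ÷10 repair. Reports with one live value cannot be
internally discordant. A tied 1–1 split is resolved by treating the
report as centimetre-unit (so the mm-side value is flagged): the classic
real-world error is a millimetre entry slipping into a centimetre-era
form, and the convention is deterministic. Ties cannot arise from the
generator's injected mixes, which require at least three present values.

## Anatomical check and harmonization (steps 3–4)

LVESD/LVEDD ≥ 1 is anatomically impossible and both members of the pair
enter the queue (2 points per record). The ratio is scale-free, so the
check is safe before unit resolution as long as step-2 discordance on the
pair is already repaired — which is why adjudication runs after every
detection step rather than once at the end.

Harmonization classifies each report by the unanimous (or majority) side
of its values and multiplies cm reports by 10. A definite minority value
surviving to this point is legal only when review retained it (a genuine
value sitting across the threshold); such reports take their majority
regime. Any other mixed report raises a hard error, because step 2 is
obliged to have resolved it. All-missing reports keep an `unknown`
regime; reports whose every value is ambiguous take the corpus-majority
regime.

## Residual scan (step 5)

On harmonized values the windows are re-applied together with a robust
criterion: flag when `|x − median_p| > k × MAD_p`, `k = 6` (configurable;
MAD unscaled, so 6 MAD ≈ 4.0 σ for near-normal data). If MAD is zero the
criterion degenerates to the window check alone. For a flagged AO or LA
value the field-swap repair is probed: if exchanging the pair would make
both values typical, the pair is flagged together with proposed swap
edits. At ~4 σ the scan will flag roughly 5 × 10⁻⁵ of *valid* points
(about 1–2 per 33,000); with a ledger or reviewer these are confirmed
genuine and retained unchanged, which is the intended behaviour of a
review filter, not a defect. Consequently an error-free corpus passes
through with zero edits and zero removals, but not always with a
literally empty step-5 queue.

## Adjudication

Precedence: ingested manual dispositions → ground-truth ledger →
conservative rules. The rule set without ground truth is deliberately
minimal: sys/dias swap when swapping fixes the ratio, the step-2 unit
proposal, the step-5 field-swap proposal; **everything else is removed**.
Edits only ever come from an enumerated repair rule — the pipeline never
fabricates a value. The cost of rule-mode conservatism is that genuine
extreme values reaching step 5 are removed rather than retained; the
ledger (or a human pass via `--review-out`/`--review-in`) is what
recovers them.

## Synthetic cohort generator

What it emulates: sex-stratified six-parameter profiles with published
clinic-cohort means and SDs (e.g. LVEDD 44.4 ± 7.6 mm in women,
48.5 ± 8.8 in men; AO 28.4 ± 3.6 vs 32.8 ± 4.1), modest positive
inter-parameter correlations (0.2–0.6; LVESD–LVEDD 0.8 so that
anatomically impossible profiles are vanishingly rare before injection),
a geometric exam-count distribution (p = 0.55: median 1, IQR [1, 2],
truncated at 30), 59.8% female subjects, a 2,132/6,076 ≈ 35.1% share of
centimetre-unit reports, three report dialects in equal shares, and 9%
missing points. Repeat exams perturb the subject profile with
within-subject noise of 15% of the between-subject SD (unconstrained by
published data; chosen as plausibly small). Truth values are rounded to
0.1 mm; centimetre raw values are truth/10 at two decimals.

Numerical choices: subject profiles use Latin-hypercube (stratified)
normal scores so empirical means converge at O(1/n); window truncation is
by redraw (up to 100 attempts), never clipping, to avoid boundary atoms
that would confuse gap detection; and because joint rejection (all six
windows plus ESD < EDD) shifts the means of *correlated* parameters in a
way marginal truncated-normal compensation cannot see, a 40,000-row pilot
simulation measures and removes the residual shift before the final draw.
Realized per-sex means therefore sit on their published targets to within
Monte-Carlo error.

Error injection (defaults per 6,076 reports, rescaled half-up for other
sizes): 16 nonsense extremes (outside both unit readings), 55
within-report unit mixes (one value per report, ≥ 3 values present,
direction set by the report's regime), 16 records with swapped LVESD/LVEDD
(values constrained to stay window-plausible in the receiving fields, as
real transcription slips are), 2 AO↔LA field swaps (hosts chosen with LA
large enough that the transplanted value breaches the AO robust cutoff —
a swap of two mid-range values is undetectable by *any* plausibility
method and does not model the documented error), and 3 genuine extremes
(valid values placed ~4.3–4.7 σ out, ledger-marked valid). Classes never
share a report. The ledger records truth, class and the repair that
restores truth, so "oracle closure" (repair ∘ corrupt = identity) is
testable exactly.

What the generator does **not** emulate: real report layouts (the three
dialects are this package's own fixed conventions), OCR/PDF artefacts,
demographic covariates beyond sex and age, disease-state structure,
age–parameter dependence (not published for this cohort), correlated
missingness, or error classes outside the four modelled ones. Passing
tests therefore demonstrate correctness of the *mechanics* and
calibration of the pipeline against these error models — not parser
robustness to arbitrary hospital formats, nor sensitivity to error types
the filter was never designed to see.

## Evaluation conventions

Accuracy = confirmed / reviewed; sensitivity = detected / injected
(genuine extremes are not errors and count toward neither); completeness
= present / (6 × reports); burden = reviewed / present. Empty
denominators report as not-applicable rather than 0 or 100%. Percentages
are carried at one decimal internally and rounded to the integer only in
printed summaries. Point-wise agreement uses an absolute tolerance of
10⁻⁶ mm (values are exact decimals end-to-end; the tolerance only absorbs
binary floating-point representation). The sex-difference p-value in the
cohort table is a Welch t-test and is presentation plumbing, not part of
the filtering method.

## Problem sizes used in the shipped checks

Unit and property tests run on 150–300-subject corpora (a few hundred
reports); the end-to-end simulation uses the full 6,076-report corpus and
generator calibration is checked at 10,000 subjects. The whole suite
completes in well under a minute on one CPU.

## Known limitations

* A unit-discordant value in a two-value report is resolved by the fixed
  cm tie-break and can, in rule mode, repair the wrong member; with
  review or a ledger the adjudicator corrects this.
* The per-parameter (1-D) threshold derivation reduces the pairwise
  scatterplot procedure to its parameter-wise equivalent; pairwise
  scatter tables are exported as diagnostics only.
* Rule-mode (no ledger) removes rather than retains genuine extremes and
  can apply a field swap to a genuine AO outlier whose partner happens to
  be typical; both are consequences of refusing to fabricate data without
  review.
* The wall-thickness / LVESD unit ambiguity sliver is irreducible for
  single-value reports; classification there follows the threshold and
  can in principle mis-scale a report consisting of exactly one extreme
  wall value (probability ~10⁻⁸ per corpus under the calibrated model).
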