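# echoqc

Quantitative transthoracic echocardiography is the workhorse measurement of
cardiac structure: interventricular septal thickness (IVS), LV posterior
wall thickness (PWT), LV end-diastolic and end-systolic internal diameters
(LVEDD, LVESD), left atrial diameter (LA) and aortic root diameter (AO).
Electronic medical records hold these measurements at epidemiologic scale,
but the values arrive as semi-structured report text riddled with two
specific problems: inconsistent measurement units (centimetres in some
report eras, millimetres in others — sometimes mixed *within* one report)
and transcription errors (nonsense values, values typed into the wrong
field).

`echoqc` is a toolchain for researchers building echo phenotypes from
report text. It provides:

* a **parser** for plain-text echo reports in three formatting dialects
  (tabular key–value, labelled prose, and a synonym-labelled two-column
  table), strictly unit-agnostic;
* a **five-step rule-based filter** that detects, repairs or removes the
  error classes above and harmonizes everything to millimetres with a full
  per-point audit trail;
* a **synthetic corpus generator** calibrated to a published clinic-based
  adult cohort, with injected errors and a ground-truth ledger, so the
  whole pipeline can be validated end to end without any EMR access;
* **evaluation tools** computing review accuracy, error-detection
  sensitivity, data loss, completeness and review burden.

## The filtering method

Given raw, unit-unresolved values $x_{rp}$ (report $r$, parameter $p$) and
physiologic plausibility windows $[\ell_p, h_p]$ in mm:

1. **Extreme outliers** — flag $x$ when neither the mm reading
   ($x \in [\ell_p, h_p]$) nor the cm reading ($10x \in [\ell_p, h_p]$) is
   plausible.
2. **Unit thresholds and discordance** — per parameter, locate the
   origin-proximal (centimetre) cluster in the pooled distribution and set
   the threshold $t_p = 1.10 \times \max(\text{cm cluster})$, below which a
   value can reliably be read as centimetres (e.g. cluster maxima of 9.8
   and 5.6 give $t = 10.78$ and $6.16$). Within each report, values on the
   minority unit side are *unit-discordant* and are repaired by the factor
   10.
3. **Anatomical constraint** — flag every report with
   $\mathrm{LVESD}/\mathrm{LVEDD} \ge 1$ (impossible); a clean field swap
   is repaired, anything else is removed.
4. **Harmonization** — classify each report cm or mm via the thresholds;
   multiply cm reports by 10.
5. **Residual scan** — re-apply the windows in mm plus a robust cutoff
   $|x - \mathrm{med}_p| > 6\,\mathrm{MAD}_p$; an AO↔LA field-swap repair
   is probed for flagged aortic-root / atrial values.

Every flagged point is *adjudicated* to retain / edit / remove — against
the ground-truth ledger on synthetic corpora, by conservative enumerated
repair rules otherwise, or via an exportable review queue for human
adjudication. Raw values are never discarded: the cleaned dataset carries
raw value, harmonized mm value, status and flags for every point, and
reports are never dropped wholesale.

## Worked example

```python
from echoqc import (GeneratorConfig, ErrorInjectionSpec, generate_cohort,
                    inject_errors, run_pipeline, score_against_ledger)

ds, ledger = generate_cohort(GeneratorConfig(n_subjects=500, seed=7))
corrupted, ledger = inject_errors(ds, ledger, ErrorInjectionSpec(seed=8))
result = run_pipeline(corrupted, ledger=ledger)
for step in ("step1", "step2", "step3", "step5"):
    print(step, result.counters[step])
report = score_against_ledger(result, ledger)
print(f"review burden {100*report.review_burden:.2f}%  "
      f"sensitivity {100*report.sensitivity:.0f}%  "
      f"mismatches {report.mismatched_points}")
```

prints

```
step1 {'flagged': 2, 'retained': 0, 'edited': 0, 'removed': 2}
step2 {'flagged': 8, 'retained': 0, 'edited': 8, 'removed': 0}
step3 {'flagged': 4, 'retained': 0, 'edited': 4, 'removed': 0}
step5 {'flagged': 1, 'retained': 1, 'edited': 0, 'removed': 0}
review burden 0.30%  sensitivity 100%  mismatches 0
```

The ~900-report corpus received 2 nonsense values (removed at step 1),
8 within-report unit mixes (unit-fixed at step 2), 2 records with swapped
systolic/diastolic diameters (4 points, switched back at step 3), and one
genuinely extreme value that the residual scan surfaced and the ledger
confirmed valid (retained). Every injected error was caught, only 0.3% of
present points needed review, and the cleaned values agree point-for-point
with the ground truth.

The same chain is available from the shell:

```bash
echoqc generate --config gen.yaml --seed 7 --out-csv raw.csv --ledger truth.csv
echoqc clean --in raw.csv --ledger truth.csv --out clean.csv --audit audit.csv
echoqc evaluate --result clean.csv --audit audit.csv --ledger truth.csv
```

`clean` also accepts a directory of report text files, a YAML plausibility
configuration, and `--review-out` / `--review-in` for a manual-review round
trip. The audit CSV holds one row per flag: report, parameter, step,
reason, disposition, raw value, edited value and final mm value.

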