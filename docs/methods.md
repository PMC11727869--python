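# Methods

## Model and assumptions

The phenotype is a deterministic rule set over two EMR streams linked by
encounter id: timestamped hs-cTnT results and free-text ECG reports. It
assumes (a) a single troponin assay with URL 14 ng/L, integer reporting at or
above 3 ng/L and a `"<3"` sentinel below it; (b) ECG reports whose language
follows the MUSE auto-populated layout (header block, blank line, one finding
per line); (c) that the encounter's clinical episode is well captured by the
timestamps of its own labs and reports.

The two-step logic mirrors the modern definition of MI: acute myocardial
injury is necessary for MI, and ECG evidence is only consulted once the
troponin criteria are met. Encounters with fewer than two troponin values
are negative by construction — injury cannot be established from a single
level — even when an ECG report mentions acute MI.

### Troponin step

Two availability strata, because a substantial fraction of genuinely
diagnosed MIs lack two measurements within 6 h:

- **two_within_6h** — all measurement pairs with gap ≤ 6 h (inclusive) are
  examined; a pair qualifies when at least one member is ≥ 14 ng/L and the
  absolute difference is ≥ 10 ng/L. Rises and falls both count.
- **not_two_within_6h** — the encounter extremes are used instead:
  max ≥ 14 ng/L and max − min ≥ 10 ng/L. Labels in this stratum are more
  uncertain (longer sampling intervals admit more biological variation).

The relative criterion (rise > 50% from a reference ≤ URL, > 20% from a
reference above it; strict comparisons, rise-only as conventionally printed)
exists for the coverage/threshold-comparison tables only; the phenotype uses
the absolute criterion because it separates historical diagnoses better in
both directions. The asymmetry — absolute |Δ| vs relative rise-only — is
deliberate and kept as printed in the consensus formulas.

### ECG step

Order is fixed: discard → preprocess → flag. A report is discarded whole
when a line both says "no significant change" and cites a comparison ECG
dated more than one day (strict, > 24 h) before the encounter start; such a
report only tells us the ECG already looked like this before the encounter.
Preprocessing removes the header (everything up to the first blank line, or
a configurable marker), comparison sentences, "(cited on or before <date>)"
findings and "age undetermined" findings — entire lines, since the
annotation qualifies the whole finding. The three flag patterns then run on
the cleaned body only. Negation detection is deliberately absent: on this
document type it produces far more false positives than true positives, and
a rare false MI flag is preferred over a missed MI.

Cited dates are parsed as DD-MMM-YYYY (configurable list). Text matching is
case-insensitive; stored bodies keep original casing.

### Encounter start

The input schemas carry no admission timestamp, so the encounter start used
by the discard rule is the earliest timestamp observed for the encounter
across labs and reports. This is at most a few hours later than the true
admission time in typical data, and the discard rule's one-day margin makes
the decision insensitive to that slack except for comparison ECGs dated
within about a day of admission.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `url_ngl` | 14 | ng/L | 99th-percentile URL of the hs-cTnT assay |
| `abs_delta_ngl` | 10 | ng/L | absolute change threshold |
| `rel_delta_low` | 0.5 | fraction | relative rise when reference ≤ URL |
| `rel_delta_high` | 0.2 | fraction | relative rise when reference > URL |
| `window_hours` | 6 | h | serial-measurement window, inclusive |
| `mode` | absolute | — | change family used by the phenotype |
| `also_check_extremes` | off | — | extremes fallback inside the within-window stratum |

`also_check_extremes` exposes the other defensible reading of the stratum
rules. With the default off, the strata are genuine alternatives; a
consequence (documented and tested) is that adding a measurement can demote
a label by moving the encounter into the stricter within-window stratum.
With the switch on, labels are monotone under added measurements.

## Numerical and edge-case choices

- "Within 6 h" is inclusive; a gap of exactly 6 h qualifies. All the ≥/>
  comparisons on troponin thresholds are as printed above; ≥ 14 ng/L counts
  as elevated everywhere.
- `"<3"` → 2 ng/L; `">N"` → N; any other non-numeric string is dropped with
  a logged warning rather than failing the encounter (EMR extracts contain
  sentinels no schema enumerates). Only the assay's own `"<3"` has a defined
  coding; other `"<N"` strings are treated as unparseable.
- Duplicate timestamps are legal; a pair means two distinct measurement
  records, not distinct times. The qualifying pair reported in the evidence
  trail is the first by earlier-member time, smaller gap breaking ties.
- One timestamp format per run (default ISO 8601); mixed formats in one file
  are a hard error, as silent reinterpretation of dates is worse than a
  failure.
- Reports timestamped before the first troponin are eligible; all reports
  linked to the encounter count, with no timing constraint relative to the
  troponin change.
- Display rounding is half-up (coefficients two decimals, percentages one);
  machine-readable outputs keep full precision.

## Evaluation conventions

SMC = agreements / total after excluding 'maybe' historical labels, where a
phenotype call is positive iff its label lies in the chosen positive set
({MI} or {MI, ACUTE_INJURY}), and stratified variants filter on the
availability stratum first. Contingency tables keep 'maybe' as its own
column group. Coverage tables count, per historical stratum, each troponin
criterion (both change families, both time scopes — in both scopes requiring
at least one value of the compared pair at or above the URL, matching the
phenotype rule) and each ECG flag, the flags counted only on reports that
survive discarding and preprocessing.

## Synthetic cohorts

The generator emulates the structure of the real extracts: per-encounter
troponin trajectories built to realize an assigned true label under the
default criteria, MUSE-style report text, and historical labels drawn from a
configurable agreement matrix. Defaults: 2,000 encounters; prevalence
MI 0.3 / acute injury 0.3 / neither 0.4; probability 0.65 that a positive
case has two troponins within 6 h (matching the observed availability among
diagnosed MIs, roughly 64–66%); 10% of encounters lack reports (forced
present for MI cases, whose evidence requires one); agreement matrix
MI→yes 0.90, injury→yes 0.30, neither→yes 0.03, with 2% 'maybe' everywhere —
loosely shaped like published phenotype-vs-diagnosis margins where many acute
injuries lack an MI diagnosis.

Value magnitudes are drawn with guard margins (positive peaks ≥ 25 ng/L,
deltas ≥ 17; negative cases capped so no pair can reach a 10 ng/L delta or a
14 ng/L peak), so that away from boundaries the classifier provably recovers
the truth table — that round trip is what the generator is for. Distractors
injected throughout exercise the NLP and parsing paths: `"<3"` values,
header matter, cited-prior and age-undetermined infarct findings in negative
encounters, same-day comparison sentences, and wholly-discardable reports
that may even contain positive patterns. `boundary_fraction` instead places
cases exactly on the rule edges (delta 10, peak 14, gap 6 h).

What the generator does **not** emulate: realistic troponin release and
clearance kinetics, assay noise, free-text variability beyond the canonical
MUSE layout, negated findings, or any correlation between troponin magnitude
and report wording. A green round-trip test therefore establishes that the
implementation inverts its own rules exactly — not that the rules capture
clinical truth in messy real-world text, which is exactly the part that
needs site-specific validation.

## Limitations

- The phenotype cannot label acute injury without two troponin values nor MI
  without an ECG report; type 3 MIs (death before sampling) are
  under-captured by design.
- ECG report findings may be superseded by evidence the phenotype does not
  see (angiography, echo, MRI), and the regexes are tuned to MUSE-style
  reports; other ECG systems and other troponin assays require revalidation.
- The five MI subtypes and chronic myocardial injury (elevated but
  non-changing troponin) are out of scope.
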