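# mi-phenotype

A computational phenotype that separates **myocardial infarction (MI)** from
**acute myocardial injury** in electronic medical record (EMR) data, using
serial high-sensitivity cardiac troponin T (hs-cTnT) values and rule-based
NLP over free-text ECG reports.

The fourth universal definition of MI distinguishes acute myocardial injury —
a cardiac troponin above the 99th-percentile upper reference limit (URL) with
a rising or falling pattern — from MI proper, which additionally requires
evidence of ischemia such as ECG changes. Historical EMR data predate this
distinction, so administrative diagnoses conflate the two. This package is
for health-informatics and epidemiology teams who want to relabel historical
encounters under the modern definition and quantify how the relabelling
agrees with legacy diagnoses.

## The phenotype

For each hospital encounter, with URL $c_{99} = 14$ ng/L (Roche Elecsys
hs-cTnT; `"<3"` results coded as 2 ng/L):

1. **Acute myocardial injury (troponin step).**
   - If two measurements fall within 6 h of each other: injury iff some pair
     $(c_i, c_j)$ with $|t_j - t_i| \le 6\,\mathrm{h}$ has
     $\max(c_i, c_j) \ge c_{99}$ and $|c_j - c_i| \ge 10$ ng/L.
   - Otherwise: injury iff $c_{\max} \ge c_{99}$ and
     $c_{\max} - c_{\min} \ge 10$ ng/L over the whole encounter.
   - Encounters with fewer than two troponin measurements are negative.
2. **MI (ECG step).** An injury-positive encounter is upgraded to MI when any
   retained ECG report matches one of three case-insensitive patterns:
   `\* acute mi`, `infarc`, `ischem|ischaem`. Before matching, reports that
   show "no significant change" versus an ECG taken more than one day before
   the encounter are discarded, and the header block, comparison text,
   "(cited on or before ...)" findings and "age undetermined" findings are
   removed.

Relative change thresholds (rise > 50% when the reference value ≤ URL,
> 20% above it) are implemented for threshold-comparison coverage tables;
the phenotype itself uses the absolute criterion.

Agreement with historical yes/no/maybe MI labels is reported as simple
matching coefficients (SMC = agreements / total, 'maybe' excluded) and
contingency tables stratified by troponin availability.

## Worked example

Real cohorts cannot be shared, so the package ships a generator that emulates
the extract formats, including MUSE-style report text and distractor content:

```bash
printf 'n_encounters: 500\nseed: 42\n' > spec.yaml
phenotype synth --spec spec.yaml --out-dir fixtures
phenotype run --labs fixtures/labs.csv --reports fixtures/reports.csv --out classifications.csv
phenotype evaluate --classifications classifications.csv --labels fixtures/labels.csv \
    --labs fixtures/labs.csv --reports fixtures/reports.csv --out-dir results
```

prints

```
wrote 500 encounters: fixtures/labs.csv, fixtures/reports.csv, fixtures/labels.csv, fixtures/truth.csv
classified 500 encounters: {'NEITHER': 184, 'MI': 159, 'ACUTE_INJURY': 157}
evaluation written to results
```

`classifications.csv` carries one row per encounter with the label, the
availability stratum and the evidence trail (qualifying pair, basis,
positive report ids):

```
encounter_id,label,stratum,n_troponins,n_reports_retained,basis,qualifying_pair_values,qualifying_pair_gap_hours,positive_report_ids
E00000,ACUTE_INJURY,not_two_within_6h,3,1,encounter_extremes,95;2,38.4333,
E00003,NEITHER,not_two_within_6h,2,1,none,,,
```

`results/agreement.json` holds the SMCs; with the generator's default
agreement matrix (diagnosed MI mostly agrees, acute injury often undiagnosed)
the example gives, in the two-troponins-within-6 h stratum, SMC 0.83 for
"MI only" and 0.67 for "MI or acute injury" — the gap reflects the injuries
the historical labels never captured. `results/contingency.csv` breaks the
same comparison down by label, status and stratum, e.g.
`ACUTE_INJURY,33 (25.8),...` meaning 25.8% of historically diagnosed MIs with
two close troponins were relabelled as injury only.

The same workflow is available as library calls (`mi_phenotype.synth`,
`classify_cohort`, `simple_matching_coefficient`, `build_contingency`,
`coverage_table`).

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch — generates a
2,000-encounter cohort from the given seed, classifies it from the written
CSV extracts, checks the exact round-trip against the generator's truth
labels, and computes agreement, contingency and coverage tables:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model assumptions, parameter defaults, what the
synthetic generator does and does not emulate, and known limitations.
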