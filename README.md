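# ph3cohort

Computable-phenotype toolkit for identifying adult patients with **Group 3
pulmonary hypertension (PH) associated with COPD or ILD** in administrative
claims data.

Group 3 PH is pulmonary hypertension due to chronic lung disease and/or
hypoxia; chronic obstructive pulmonary disease (COPD) and interstitial lung
disease (ILD) are its two large subgroups. Claims databases record ICD-9-CM
and ICD-10-CM diagnosis codes, not clinical PH groups, so cohort studies
must reconstruct the group from code sets plus temporal logic. `ph3cohort`
is for epidemiologists and outcomes researchers who need to execute,
compare, and validate such phenotype definitions — without access to a
proprietary claims database.

## What it implements

The consensus algorithm has four components, each a configurable rule:

1. **COPD/ILD identification** — curated code sets (ICD-9-CM 491.x/492.x/496,
   ICD-10-CM J41–J44 for COPD; the ILD block including connective-tissue
   disease with lung involvement), ≥ 1 inpatient or ≥ 2 outpatient claims,
   primary or secondary diagnosis position.
2. **PH identification** — the consensus PH set (416, 416.0, 416.8, 416.9;
   I27 and its non-exclusionary children, including the designated Group 3
   code I27.23), confirmed by ≥ 1 inpatient claim or ≥ 2 outpatient claims
   **≥ 30 days apart**; the patient is indexed on the *first* PH-coded claim.
3. **Sequence** — a COPD/ILD rule must qualify in the baseline lookback
   window `[index − baseline_days, index]` (default 365 days; a 6-month
   variant is a named preset), enforcing PH-after-lung-disease.
4. **Other-group exclusions** — code sets for PH groups 1 (PAH),
   2 (left heart disease), 4 (CTEPH), 5 (multifactorial), and other Group 3
   conditions, counted **strictly before** the index date. I27.x codes are
   not used for exclusion by default (flaggable); sleep-apnea codes never
   exclude; patients meeting several groups can be excluded or routed to a
   separate multi-group cohort.

Around the core sit: a claims/enrollment data model with validating CSV
readers, 11 executable presets transcribing published study definitions
(plus the recommended algorithm and two baseline variants), a seeded
synthetic-claims generator with per-patient ground-truth labels, a
brute-force oracle that re-derives every cohort decision by exhaustive
enumeration, and diagnostic scoring (sensitivity, specificity, PPV, NPV).

## Worked example

```bash
ph3cohort simulate --spec spec.yaml --seed 11 --out sim
ph3cohort build-cohort --claims sim/claims.csv --enrollment sim/enrollment.csv \
    --preset recommended --out cohort
ph3cohort evaluate --cohort cohort/cohort.csv --truth sim/truth.csv --out metrics
```

with `spec.yaml` requesting 40 true PH–COPD, 20 true PH–ILD, 15 Group 2 PH,
15 PH-before-lung-disease, and 10 lung-disease-without-PH patients. The run
prints:

```
INFO ph3cohort: simulated 100 patients, 395 claims
INFO ph3cohort: cohort built: 100 patients, 60 included
INFO ph3cohort: metrics: {'tp': 60, 'fp': 0, 'fn': 0, 'tn': 40,
                          'sensitivity': 1.0, 'specificity': 1.0,
                          'ppv': 1.0, 'npv': 1.0}
```

and `cohort/attrition.csv` shows the sequential criteria at work:

```
criterion,n_remaining
total_patients,100
ph_confirmed,90            # 10 patients had no confirmed PH
adult_at_index,90
enrolled_through_baseline,90
baseline_lung_disease,75   # 15 indexed before their lung disease
no_other_group_exclusion,60  # 15 carried Group 2 codes pre-index
```

The 60 included patients are exactly the 40 + 20 simulated true Group 3
PH–COPD/ILD patients: on noise-free data the algorithm recovers the truth
perfectly, which is the generator's design contract, not a claim about real
claims data. Per-patient audit traces are available in the library:

```python
from ph3cohort import default_registry, preset_config, trace_patient
print(trace_patient("P000001", claims, patients, preset_config("recommended"),
                    default_registry()))
```

## Scope notes

Medication-based identification or exclusion is deliberately unsupported
(PH therapies are used across groups), and procedure codes appear only as
an optional sensitivity filter (e.g. the lung-transplant exclusion in one
preset). Non-US ICD editions, pharmacy claims, and provider-specialty
attribution are out of scope. See `docs/methods.md` for the model, its
assumptions, and known limitations.
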