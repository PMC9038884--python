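# Methods

## The phenotype model

`ph3cohort` executes claim-count phenotype definitions over longitudinal
administrative claims. A definition (`AlgorithmConfig`) is evaluated per
patient in a fixed order, and the first failing criterion determines the
patient's status:

1. **PH confirmation and index.** A `ConditionRule` has two qualification
   paths: an inpatient path (≥ `min_inpatient_claims` distinct inpatient
   claims with a set code in an allowed diagnosis position) and a
   repeat-claim path (≥ `min_outpatient_claims` claims in configurable
   settings whose consecutive qualifying claims are ≥
   `outpatient_min_separation_days` apart, first-to-last within
   `outpatient_max_span_days` if capped). Either path suffices. The
   defaults — 1 inpatient OR 2 outpatient ≥ 30 days apart, positions
   {1, 2} — encode the consensus recommendation; the 30-day separation is
   inclusive (a pair exactly 30 days apart qualifies). Once the rule is
   confirmed, the **index date** is the patient's *earliest* claim bearing
   a PH-set code in an allowed position, which may precede the
   qualification date; `index_on="confirmation"` indexes on the latter for
   sensitivity analyses. Unconfirmed patients are `not_ph`.
2. **Age** at index (birth-year arithmetic; default ≥ 18) →
   `excluded_age`.
3. **Continuous enrollment** covering `[index − baseline_days, index]`
   when required → `excluded_enrollment`.
4. **Lung disease before PH.** The COPD and ILD rules are evaluated inside
   `[index − baseline_days, index + sequence_tolerance_days]`. With the
   default tolerance of 0 this enforces PH-after-lung-disease. If neither
   rule qualifies in the window, the engine distinguishes
   `excluded_sequence` (a rule qualifies on the unrestricted timeline —
   the patient has the disease, but not demonstrably before PH) from
   `excluded_no_lung_disease` (no qualifying lung disease at all). Both
   rules are evaluated so that combined disease is reported as its own
   subtype (`copd_and_ild_ph`) rather than forcing a choice.
5. **Other-group exclusions.** Each configured exclusion set (groups 1, 2,
   4, 5 and other Group 3 conditions) excludes when its claim threshold
   (default ≥ 1 claim, any setting, any position) is met **strictly
   before** the index date; claims on the index date never exclude,
   because same-day codes typically reflect diagnostic workup rather than
   prior disease. `pre_and_post` mode (optionally capped at
   `exclusion_post_days`) reproduces studies that excluded on codes found
   anywhere. With `multi_group_mode="separate_cohort"` these patients are
   routed to a `multi_group` status instead of `excluded_other_group`.

Dates are calendar dates; all window arithmetic is in whole days and every
window boundary is inclusive. Ties on the same service date are broken by
evaluating the inpatient path first and then by claim-id order, so results
are deterministic and independent of input claim order.

## Code sets

The built-in registry transcribes the consensus diagnosis-code tables:
`copd`, `ild` (with `ctd_lung`, the connective-tissue-disease-with-lung-
involvement subset, also exposed separately), `ph`, and five exclusion
sets (`excl_group1` … `excl_group5`). Normalization is uppercase plus dot
removal, with no zero padding (padding would corrupt ICD-9 V/E codes);
matching is a pure string comparison, isolated per coding system. Each
entry carries an explicit match mode: `prefix` only where the source
notation uses a trailing ".x" wildcard (schistosomiasis 120.x/B65.x,
aortic-valve I35.x), `exact` everywhere else, including three-character
category parents. In particular the PH parents "416" and "I27" are exact
in the default registry so that the five-digit I27 children designating
other PH groups (I27.22, I27.24, I27.82) stay confined to the exclusion
sets; a documented `broad` registry variant promotes them to prefixes.
Those exclusionary I27.x entries are present in the exclusion sets as
printed but are **ignored at evaluation time** unless
`use_i27x_exclusions` is set, reflecting the tension between the published
exclusion table and the accompanying advice not to exclude on I27.x;
both behaviors are reachable. Sleep-apnea codes are members of no default
set, so they can never exclude. Custom registries loaded from file fully
replace the built-in one; there is no silent merging.

`copd_only_mode` adds a connective-tissue-disease exclusion for
COPD-only study designs. It uses the `ctd_lung` set — the registry's only
CTD set — which is narrower than an all-CTD exclusion; a custom registry
can supply a broader set under the same name.

## Presets

Eleven published study definitions are transcribed as far as a claim-count
engine can express them (claim counts, settings, positions, separations,
span caps, sequence windows, exclusion sets); each preset's `notes` field
states what was approximated or dropped. Medication-duration requirements,
specialist attribution, and reversed indexing (cohorts indexed on the lung
disease rather than PH) are not expressible; two studies built on such
criteria are omitted from the library, and two others are approximated
with widened windows and say so. One preset enables the optional
procedure-code exclusion (prior lung transplant via ICD-9 volume-3
33.5x/33.6x and ICD-10-PCS 0BY prefixes — standard transplant families
chosen by this package, since the source row prints no code list).

## Synthetic data

The generator is a *clean-skeleton-then-corrupt* design: each stratum
first emits a claim history that satisfies (or violates, per its label)
the recommended criteria by construction — dates drawn uniformly inside
stratum-specific constraint windows, codes drawn uniformly from the
relevant default set restricted to the era implied by the service date
(ICD-9 before 2015-10-01, ICD-10 after) — and noise is applied afterwards.
Four noise channels model the misclassification mechanisms that matter for
this phenotype: dropping the confirmatory PH claim, injecting a stray
exclusion code pre-index, demoting the target code to diagnosis position
3, and wrong-era coding. Ground-truth labels therefore stay interpretable:
`expected_status` is the status the *zero-noise* skeleton produces under
the recommended configuration.

Defaults: a 2013–2018 service window spanning the ICD-9→ICD-10 transition;
enrollment covering the whole window; birth years 1935–1970 (all adults);
index dates placed so that 365 days of lookback and 150 days of follow-up
fit inside the window (a shorter window is a configuration error, not a
silent truncation). Exclusion-code emission avoids I27.x entries so that
the intended exclusion fires under the default configuration.

What the generator does **not** emulate: utilization intensity, comorbidity
correlation, realistic code prevalence, pharmacy claims, or coder behavior.
Perfect recovery on clean simulations therefore certifies the *logic* of
an algorithm — that it implements its stated criteria exactly — not its
clinical accuracy on real claims, which only chart-review validation can
establish.

## Validation design

* **Oracle equivalence.** `brute_force_cohort` re-derives every status by
  exhaustive enumeration (all claim subsets of the required size tested
  against separation/span constraints) and shares no code with the
  engine's earliest-witness search; randomized noisy corpora are compared
  field by field. The engine's witness search iterates over starting
  claims and extends greedily: for a fixed first claim, always taking the
  earliest admissible next claim minimizes the finishing date and hence
  the span, so scanning all starts finds the earliest valid witness.
* **Boundary fixtures.** Hand-specified single-patient histories pin the
  inclusive boundaries: 29- vs 30-day PH pairs, a lung claim exactly
  `baseline_days` before index, an exclusion code on the index day, lung
  disease 30 days post-index with and without a 6-month tolerance.
* **Monotonicity.** Relaxing outpatient claim counts, or widening the
  baseline, never shrinks the included set; adding exclusion sets never
  grows it. Baseline widening is monotone *given a fixed enrollment
  requirement*: because a longer lookback also demands longer continuous
  enrollment, the property is stated and tested with the enrollment
  requirement held off on both sides.
* **Noise calibration.** Dropping the confirmatory claim with probability
  p is a per-patient Bernoulli event, so the included fraction of a true
  Group 3 stratum is binomial with mean 1 − p; it is checked within three
  binomial standard errors at n = 1,000.

Problem sizes in the shipped tests and acceptance script — 1,000-patient
clean and calibration runs, 200 oracle corpora of ≤ 50 patients in the
suite and 50 in the script — were chosen to give stable proportions while
keeping a full run in the low seconds on one core.

## Numerical and degenerate-input choices

Undefined diagnostic ratios (zero denominators) are reported as
missing/None, never coerced to 0, so small-stratum sweeps cannot
manufacture fake specificity. Patients with no claims are `not_ph`.
Overlapping or gap-≤-1-day enrollment spans are merged on read (verified
against a day-set union oracle). Era inference from the service date is a
fallback used only when a claims file carries no explicit coding-system
column, and it is logged; an explicit column always wins. Claim rows that
fail to parse abort the read with file/line context once the configured
error budget (default 0) is exceeded.

## Known limitations

Only US clinical modifications (ICD-9-CM/ICD-10-CM) are supported. A
multi-line inpatient stay is counted as multiple claims if it arrives
under distinct claim ids; collapsing same-day lines into one claim is left
to the data-preparation step. Age uses birth year only. The engine cannot
index on the lung disease, so reversed-index study designs are only
approximated. PPV/sensitivity reported here are against synthetic truth;
no real-database performance is claimed or reproduced.
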