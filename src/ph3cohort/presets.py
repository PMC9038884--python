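"""Named phenotype configurations: the recommended algorithm and the
published claims-study definitions it was benchmarked against.

Each preset transcribes a study's claim counts, care settings, diagnosis
positions, separation/sequence logic, and exclusions as far as a
claim-count rule engine can express them; inexpressible elements
(medication-duration requirements, specialist attribution, reversed
indexing) are stated in the preset's ``notes``.  Two studies are omitted
entirely: one assigned PH groups from PDE5-inhibitor use and one required a
pulmonologist-confirmed outpatient diagnosis, neither of which is a
diagnosis-code criterion.
"""

from __future__ import annotations

from .engine import AlgorithmConfig, ConditionRule, ExclusionRule, Positions

IN_OUT = ("inpatient", "outpatient")

_DEFAULT_EXCLUSIONS = tuple(
    ExclusionRule(name) for name in (
        "excl_group1", "excl_group2", "excl_group3_other",
        "excl_group4", "excl_group5",
    )
)


def _recommended(baseline_days: int = 365) -> AlgorithmConfig:
    return AlgorithmConfig(
        name="recommended",
        lung_rule=ConditionRule("copd", 1, 2, 1),
        ild_rule=ConditionRule("ild", 1, 2, 1),
        ph_rule=ConditionRule("ph", 1, 2, 30),
        baseline_days=baseline_days,
        exclusion_rules=_DEFAULT_EXCLUSIONS,
        notes=(
            "Consensus algorithm: confirmed PH (1 inpatient or 2 outpatient "
            "claims >=30 days apart, primary/secondary position), indexed on "
            "the first PH claim; COPD or ILD qualified in the baseline "
            "lookback before index; other-PH-group code sets excluded "
            "strictly pre-index; I27.x codes not used for exclusion."
        ),
    )


def _build_presets() -> dict[str, AlgorithmConfig]:
    presets: dict[str, AlgorithmConfig] = {}
    presets["recommended"] = _recommended(365)
    presets["baseline_12mo"] = _recommended(365)
    presets["baseline_6mo"] = _recommended(183)
    presets["baseline_6mo"].name = "baseline_6mo"
    presets["baseline_12mo"].name = "baseline_12mo"

    presets["collard2012"] = AlgorithmConfig(
        name="collard2012",
        lung_rule=None,
        ild_rule=ConditionRule(
            "collard_ipf", min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_min_separation_days=1, outpatient_settings=IN_OUT,
        ),
        ph_rule=ConditionRule(
            "ph_416_0", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT,
        ),
        exclusion_rules=(),
        notes=(
            "IPF cohort: >=2 inpatient/outpatient IPF claims on separate "
            "days; PH = any single 416.0 claim after the lung disease; no "
            "other-group exclusions reported. The study's alternative IPF "
            "path (one 516.3 followed by a 515) and its other-ILD exclusion "
            "are not expressible as a single claim-count rule and are not "
            "modeled."
        ),
    )
    presets["collard2015"] = AlgorithmConfig(
        name="collard2015",
        lung_rule=None,
        ild_rule=ConditionRule(
            "collard_ipf", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT,
        ),
        ph_rule=ConditionRule(
            "ph_416_0x", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT,
        ),
        baseline_days=3650,
        sequence_tolerance_days=3650,
        require_enrollment_through_baseline=False,
        exclusion_rules=(),
        notes=(
            "Single-claim IPF and single-claim PH (416.0 family); the study "
            "indexed on IPF and looked back for comorbid PH, the reverse of "
            "this engine's PH indexing, so sequence constraints are opened "
            "wide rather than enforced."
        ),
    )
    presets["heresi2017"] = AlgorithmConfig(
        name="heresi2017",
        lung_rule=ConditionRule(
            "copd", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT,
        ),
        ild_rule=ConditionRule(
            "ild", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT,
        ),
        ph_rule=ConditionRule(
            "ph_416_narrow", min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_min_separation_days=1, outpatient_max_span_days=365,
            outpatient_settings=IN_OUT,
        ),
        exclusion_rules=(
            ExclusionRule("excl_group2"), ExclusionRule("excl_group4"),
            ExclusionRule("excl_group5"),
        ),
        exclusion_window="pre_and_post",
        notes=(
            ">=1 lung-disease claim in baseline; PH = 2 inpatient/outpatient "
            "claims (416.0/416.8) separated by >=1 day within 12 months; "
            "groups 2/4/5 excluded anywhere in the study period. The "
            "companion right-heart-catheterization/echo requirement is a "
            "procedure criterion, available via the optional procedure "
            "filter but off in this preset."
        ),
    )
    presets["medrek2017"] = AlgorithmConfig(
        name="medrek2017",
        lung_rule=ConditionRule(
            "medrek_copd", min_inpatient_claims=1, min_outpatient_claims=2,
            outpatient_min_separation_days=1,
            allowed_positions=Positions.PRIMARY_ONLY,
        ),
        ild_rule=None,
        ph_rule=ConditionRule(
            "ph_416_narrow", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT, allowed_positions=Positions.ANY,
        ),
        exclusion_rules=(),
        notes=(
            "COPD-only: 1 hospitalization or 2 outpatient claims with COPD "
            "as the primary diagnosis; PH = any single 416.0/416.8 claim "
            "after COPD; no other-group exclusions reported."
        ),
    )
    presets["pedraza2019"] = AlgorithmConfig(
        name="pedraza2019",
        lung_rule=None,
        ild_rule=ConditionRule(
            "pedraza_ild", min_inpatient_claims=1, min_outpatient_claims=0,
            allowed_positions=Positions.ANY,
        ),
        ph_rule=ConditionRule(
            "ph_416_narrow", min_inpatient_claims=1, min_outpatient_claims=0,
            allowed_positions=Positions.ANY,
        ),
        baseline_days=1,
        sequence_tolerance_days=1,
        require_enrollment_through_baseline=False,
        exclusion_rules=(),
        notes=(
            "Hospital-discharge study: one ILD admission and one PH "
            "admission, diagnoses recorded on the same stay; approximated "
            "here with a one-day window around the PH index."
        ),
    )
    presets["wijeratne2018"] = AlgorithmConfig(
        name="wijeratne2018",
        lung_rule=ConditionRule(
            "copd", min_inpatient_claims=1, min_outpatient_claims=1,
            outpatient_settings=("emergency",), allowed_positions=Positions.ANY,
        ),
        ild_rule=ConditionRule(
            "ild", min_inpatient_claims=1, min_outpatient_claims=1,
            outpatient_settings=("emergency",), allowed_positions=Positions.ANY,
        ),
        ph_rule=ConditionRule(
            "wijeratne_ph", min_inpatient_claims=1, min_outpatient_claims=1,
            outpatient_settings=("emergency",), allowed_positions=Positions.ANY,
        ),
        baseline_days=1825,
        exclusion_rules=(ExclusionRule("excl_group2"), ExclusionRule("excl_group4")),
        multi_group_mode="separate_cohort",
        emergency_as_outpatient=False,
        notes=(
            "Hospitalization or emergency-department claims only; lung "
            "disease assessed in the 5 years before the first PH claim; "
            "patients with Group 2/4 codes analyzed as a multi-group cohort. "
            "The study used 4-digit non-US ICD-10 codes; this preset "
            "approximates them with ICD-10-CM prefixes."
        ),
    )
    presets["butt2019"] = AlgorithmConfig(
        name="butt2019",
        lung_rule=None,
        ild_rule=ConditionRule(
            "butt_ssc", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT, allowed_positions=Positions.ANY,
        ),
        ph_rule=ConditionRule(
            "butt_ph", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT, allowed_positions=Positions.ANY,
        ),
        baseline_days=3650,
        require_enrollment_through_baseline=False,
        exclusion_rules=(),
        notes=(
            "Systemic sclerosis registry study: single-claim SSc (M34 "
            "family except the CREST code) then single-claim PH (I27 "
            "family) after it. ICD-8 codes from the earliest registry years "
            "are outside this package's scope."
        ),
    )
    presets["hemnes2019"] = AlgorithmConfig(
        name="hemnes2019",
        lung_rule=ConditionRule(
            "copd", min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_min_separation_days=30, outpatient_settings=IN_OUT,
        ),
        ild_rule=ConditionRule(
            "ild", min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_min_separation_days=30, outpatient_settings=IN_OUT,
        ),
        ph_rule=ConditionRule(
            "hemnes_ph", min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_min_separation_days=30, outpatient_settings=IN_OUT,
        ),
        exclusion_rules=(
            ExclusionRule("excl_group2"), ExclusionRule("excl_group4"),
            ExclusionRule("excl_group5"),
        ),
        use_i27x_exclusions=True,
        notes=(
            "Two claims >=30 days apart (inpatient or outpatient combined) "
            "for lung disease and for PH; lung disease required in baseline "
            "before the PH claim; groups 2/4/5 excluded pre-index. Its PH "
            "code list includes I27.24, and its exclusion lists keep I27.x "
            "codes, so I27.x exclusions are enabled. CPT-procedure-based "
            "exclusion criteria are not modeled."
        ),
    )
    presets["trammell2019"] = AlgorithmConfig(
        name="trammell2019",
        lung_rule=ConditionRule(
            "copd", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT,
        ),
        ild_rule=ConditionRule(
            "ild", min_inpatient_claims=0, min_outpatient_claims=1,
            outpatient_settings=IN_OUT,
        ),
        ph_rule=ConditionRule(
            "trammell_ph", min_inpatient_claims=1, min_outpatient_claims=2,
            outpatient_min_separation_days=30,
        ),
        sequence_tolerance_days=183,
        exclusion_rules=(
            ExclusionRule("excl_group2"), ExclusionRule("excl_group4"),
            ExclusionRule("excl_group5"),
        ),
        exclusion_window="pre_and_post",
        exclusion_post_days=183,
        multi_group_mode="separate_cohort",
        notes=(
            "PH = 2 outpatient claims >=30 days apart or 1 inpatient claim "
            "(416.0/416.2/416.8/416.9); lung disease allowed in baseline or "
            "up to 6 months after the PH index; group 2/4/5 codes assessed "
            "in the same window route patients to a multiple-groups cohort."
        ),
    )
    presets["lautsch2020"] = AlgorithmConfig(
        name="lautsch2020",
        lung_rule=ConditionRule(
            "copd", min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_min_separation_days=1, outpatient_settings=IN_OUT,
        ),
        ild_rule=None,
        ph_rule=ConditionRule(
            "ph", min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_min_separation_days=1, outpatient_settings=IN_OUT,
        ),
        exclusion_rules=(ExclusionRule("excl_group2"), ExclusionRule("excl_group4")),
        proc_exclusion_prefixes=("33.5", "33.6", "0BY"),
        notes=(
            "COPD cohort: 2 inpatient/outpatient claims each for COPD and "
            "PH, COPD before PH; chronic-thromboembolic and left-heart PH "
            "diagnoses excluded pre-index; prior lung transplant excluded "
            "via procedure-code families (ICD-9 vol 3 33.5x/33.6x, "
            "ICD-10-PCS 0BY). The study's PAH-targeted-therapy exclusion is "
            "medication-based and not modeled."
        ),
    )
    presets["wu2020"] = AlgorithmConfig(
        name="wu2020",
        lung_rule=ConditionRule(
            "wu_copd", min_inpatient_claims=2, min_outpatient_claims=3,
            outpatient_min_separation_days=1, allowed_positions=Positions.ANY,
        ),
        ild_rule=None,
        ph_rule=ConditionRule(
            "wu_ph", min_inpatient_claims=2, min_outpatient_claims=3,
            outpatient_min_separation_days=1, allowed_positions=Positions.ANY,
        ),
        exclusion_rules=(
            ExclusionRule("excl_group1"), ExclusionRule("excl_group2"),
            ExclusionRule("excl_group4"),
            ExclusionRule("ctd_lung"), ExclusionRule("wu_sleep_apnea"),
        ),
        exclusion_window="pre_and_post",
        notes=(
            "COPD-only: >=3 outpatient or >=2 inpatient COPD claims; PH = "
            ">=3 outpatient or >=2 inpatient claims (emergency-room claims "
            "folded into the outpatient count here); PH claims before COPD "
            "excluded via the sequence rule; connective-tissue-disease and "
            "sleep-apnea claims anywhere exclude, unlike the consensus "
            "default. The COPD-medication-duration requirement is not "
            "modeled."
        ),
    )
    return presets


_PRESETS = _build_presets()

PRESET_TAGS = tuple(sorted(_PRESETS))

#: Table-derived study presets (excludes the recommended/baseline aliases).
STUDY_TAGS = tuple(
    t for t in PRESET_TAGS if t not in ("recommended", "baseline_12mo", "baseline_6mo")
)


def preset_config(study_tag: str) -> AlgorithmConfig:
    """A fresh copy of the named preset configuration."""
    try:
        base = _PRESETS[study_tag]
    except KeyError:
        raise KeyError(
            f"unknown preset {study_tag!r}; valid tags: {', '.join(PRESET_TAGS)}"
        ) from None
    # return a defensive copy (AlgorithmConfig is mutable)
    from .engine import config_from_dict, config_to_dict
    return config_from_dict(config_to_dict(base))
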