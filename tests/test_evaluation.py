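"""Oracle agreement, confusion metrics, sensitivity sweeps."""

import datetime as dt

import numpy as np
import pytest

from ph3cohort.claims import Claim, EnrollmentSpan, Patient, Setting
from ph3cohort.codesets import DxCode
from ph3cohort.engine import (
    ConditionRule,
    ExclusionRule,
    Status,
    build_cohort,
)
from ph3cohort.evaluation import (
    ConfusionMetrics,
    brute_force_cohort,
    compare_cohorts,
    confusion_metrics,
    criteria_sensitivity_sweep,
)
from ph3cohort.presets import preset_config
from ph3cohort.synthetic import (
    FIXTURE_TAGS,
    NoiseSpec,
    StratumSpec,
    make_fixture,
    simulate_population,
)

D = dt.date


def noisy_spec(rng):
    noise = NoiseSpec(
        p_drop_confirmatory_claim=0.3,
        p_stray_exclusion_code=0.3,
        p_position_demotion=0.3,
        p_era_mismatch=0.2,
    )
    strata = ("g3_copd", "g3_ild", "g3_both", "group2_ph", "group4_ph",
              "lung_no_ph", "ph_no_lung", "ph_before_lung",
              "multi_group_overlap", "clean_negative")
    return [
        StratumSpec(s, int(rng.integers(0, 6)), era="mixed", noise=noise)
        for s in strata
    ]


class TestBruteForceOracle:
    def test_subset_enumeration_example(self, registry):
        # claims at days 0, 10, 40 with 30-day separation: witness {0, 40}
        claims = [
            Claim("T", f"c{i}", d, Setting.OUTPATIENT,
                  (DxCode("I27.23", "ICD10CM"),))
            for i, d in enumerate([D(2016, 1, 1), D(2016, 1, 11), D(2016, 2, 10)])
        ]
        pats = [Patient("T", 1950, (EnrollmentSpan("T", D(2014, 1, 1), D(2017, 1, 1)),))]
        cfg = preset_config("recommended")
        res = brute_force_cohort(claims, pats, cfg, registry)["T"]
        assert res.status is not Status.NOT_PH  # PH rule qualified via {0, 40}
        assert res.index_date == D(2016, 1, 1)

    @pytest.mark.parametrize("tag", FIXTURE_TAGS)
    def test_fixture_agreement(self, registry, recommended, tag):
        claims, pats = make_fixture(tag)
        engine = build_cohort(claims, pats, recommended, registry)
        oracle = brute_force_cohort(claims, pats, recommended, registry)
        assert compare_cohorts(engine, oracle) == []

    @pytest.mark.parametrize("preset", ["recommended", "heresi2017", "trammell2019",
                                        "wu2020", "hemnes2019"])
    def test_randomized_agreement_across_presets(self, registry, preset):
        cfg = preset_config(preset)
        rng = np.random.default_rng(2024)
        for trial in range(15):
            seed = int(rng.integers(0, 2**31))
            claims, patients, _ = simulate_population(noisy_spec(rng), seed=seed)
            engine = build_cohort(claims, patients, cfg, registry)
            oracle = brute_force_cohort(claims, patients, cfg, registry)
            assert compare_cohorts(engine, oracle) == [], (preset, trial, seed)


class TestConfusionMetrics:
    def test_arithmetic(self):
        m = ConfusionMetrics(tp=43, fp=7, fn=0, tn=50)
        assert m.ppv == pytest.approx(0.86)
        assert m.sensitivity == 1.0

    def test_degenerate_denominators_flagged_not_zeroed(self):
        m = ConfusionMetrics(tp=0, fp=0, fn=0, tn=10)
        assert m.specificity == 1.0
        assert m.sensitivity is None
        assert m.ppv is None

    def test_perfect_clean_simulation(self, registry, recommended):
        spec = [StratumSpec(s, 10) for s in
                ("g3_copd", "g3_ild", "group2_ph", "lung_no_ph")]
        claims, patients, labels = simulate_population(spec, seed=4)
        results = build_cohort(claims, patients, recommended, registry)
        m = confusion_metrics(results, labels)
        assert (m.sensitivity, m.specificity, m.ppv) == (1.0, 1.0, 1.0)

    def test_unlabeled_patient_is_error(self, registry, recommended):
        claims, patients, labels = simulate_population(
            [StratumSpec("g3_copd", 3)], seed=4
        )
        results = build_cohort(claims, patients, recommended, registry)
        with pytest.raises(ValueError, match="truth"):
            confusion_metrics(results, labels[:-1])

    def test_multi_group_counting_knob(self, registry):
        cfg = preset_config("recommended")
        cfg.multi_group_mode = "separate_cohort"
        claims, patients, labels = simulate_population(
            [StratumSpec("multi_group_overlap", 5)], seed=6
        )
        results = build_cohort(claims, patients, cfg, registry)
        default = confusion_metrics(results, labels)
        as_included = confusion_metrics(results, labels, multi_group_as_included=True)
        assert default.fp == 0
        assert as_included.fp == 5  # multi-group stratum is a negative here


class TestSweep:
    def test_identity_jaccard(self, registry):
        claims, patients, _ = simulate_population(
            [StratumSpec("g3_copd", 10), StratumSpec("lung_no_ph", 5)], seed=8
        )
        df = criteria_sensitivity_sweep(
            claims, patients,
            [("ref", preset_config("recommended")),
             ("again", preset_config("recommended"))],
            registry,
        )
        assert list(df["jaccard_vs_reference"]) == [1.0, 1.0]

    def test_relaxation_grows_cohort(self, registry):
        claims, patients, _ = simulate_population(
            [StratumSpec("g3_copd", 30,
                         noise=NoiseSpec(p_drop_confirmatory_claim=0.4))],
            seed=12,
        )
        relaxed = preset_config("recommended")
        relaxed.ph_rule = ConditionRule(
            "ph", min_inpatient_claims=1, min_outpatient_claims=1,
        )
        df = criteria_sensitivity_sweep(
            claims, patients,
            [("recommended", preset_config("recommended")), ("1claim", relaxed)],
            registry,
        )
        assert df.loc[1, "n_included"] >= df.loc[0, "n_included"]

    def test_duplicate_labels_rejected(self, registry):
        with pytest.raises(ValueError, match="duplicate"):
            criteria_sensitivity_sweep(
                [], [], [("x", preset_config("recommended")),
                         ("x", preset_config("recommended"))], registry,
            )

    def test_all_presets_complete_on_one_corpus(self, registry):
        spec = [StratumSpec(s, 8) for s in
                ("g3_copd", "g3_ild", "group2_ph", "ph_before_lung", "clean_negative")]
        claims, patients, _ = simulate_population(spec, seed=33)
        from ph3cohort.presets import PRESET_TAGS
        configs = [(t, preset_config(t)) for t in PRESET_TAGS]
        df = criteria_sensitivity_sweep(claims, patients, configs, registry)
        assert len(df) == len(PRESET_TAGS)
        assert df["n_included"].nunique() > 1  # presets genuinely differ
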