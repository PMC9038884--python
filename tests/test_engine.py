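"""Condition rules, index dating, sequence logic, exclusions, cohort build."""

import datetime as dt

import pytest

from ph3cohort.claims import Claim, EnrollmentSpan, Patient, Setting
from ph3cohort.codesets import DxCode
from ph3cohort.engine import (
    AlgorithmConfig,
    ConditionRule,
    ConfigError,
    ExclusionRule,
    Positions,
    Status,
    Subtype,
    apply_group_exclusions,
    attrition_table,
    build_cohort,
    config_from_dict,
    config_to_dict,
    evaluate_condition_rule,
    find_ph_index,
    load_config,
    save_config,
    trace_patient,
)
from ph3cohort.synthetic import make_fixture

D = dt.date
OUT = Setting.OUTPATIENT
INP = Setting.INPATIENT


def claim(cid, date, setting, *codes, pid="T"):
    system = "ICD9CM" if date < D(2015, 10, 1) else "ICD10CM"
    return Claim(pid, cid, date, setting, tuple(DxCode(c, system) for c in codes))


def ph_rule(**kw):
    defaults = dict(
        codeset="ph", min_inpatient_claims=1, min_outpatient_claims=2,
        outpatient_min_separation_days=30,
    )
    defaults.update(kw)
    return ConditionRule(**defaults)


class TestConditionRule:
    def test_single_inpatient_claim_qualifies(self, registry):
        ev = evaluate_condition_rule(
            [claim("c1", D(2016, 1, 5), INP, "I27.23")], ph_rule(), registry
        )
        assert ev.qualified and ev.path == "inpatient"
        assert ev.qualification_date == D(2016, 1, 5)

    def test_outpatient_pair_below_separation_fails(self, registry):
        claims = [
            claim("c1", D(2016, 1, 5), OUT, "I27.23"),
            claim("c2", D(2016, 1, 15), OUT, "I27.23"),
        ]
        assert not evaluate_condition_rule(claims, ph_rule(), registry).qualified

    def test_outpatient_pair_at_separation_boundary_qualifies(self, registry):
        claims = [
            claim("c1", D(2016, 1, 1), OUT, "I27.23"),
            claim("c2", D(2016, 1, 31), OUT, "I27.23"),  # exactly 30 days
        ]
        ev = evaluate_condition_rule(claims, ph_rule(), registry)
        assert ev.qualified and ev.qualification_date == D(2016, 1, 31)

    def test_witness_search_skips_intermediate_claims(self, registry):
        # days 0, 10, 40: valid witness is {0, 40}
        claims = [
            claim("c1", D(2016, 1, 1), OUT, "I27.23"),
            claim("c2", D(2016, 1, 11), OUT, "I27.23"),
            claim("c3", D(2016, 2, 10), OUT, "I27.23"),
        ]
        ev = evaluate_condition_rule(claims, ph_rule(), registry)
        assert ev.qualified
        assert set(ev.qualifying_claim_ids) == {"c1", "c3"}

    def test_span_cap_blocks_distant_pair(self, registry):
        claims = [
            claim("c1", D(2014, 1, 1), OUT, "416.0"),
            claim("c2", D(2015, 3, 1), OUT, "416.8"),
        ]
        capped = ph_rule(
            min_inpatient_claims=0, outpatient_min_separation_days=1,
            outpatient_max_span_days=365,
        )
        uncapped = ph_rule(min_inpatient_claims=0, outpatient_min_separation_days=1)
        assert not evaluate_condition_rule(claims, capped, registry).qualified
        assert evaluate_condition_rule(claims, uncapped, registry).qualified

    def test_position_limits(self, registry):
        c = claim("c1", D(2016, 1, 5), INP, "I10", "E11.9", "I27.23")
        rule_any = ph_rule(allowed_positions=Positions.ANY)
        rule_ps = ph_rule()  # primary/secondary
        assert evaluate_condition_rule([c], rule_any, registry).qualified
        assert not evaluate_condition_rule([c], rule_ps, registry).qualified

    def test_combined_setting_counting(self, registry):
        # one inpatient + one outpatient claim counted toward the same pair
        claims = [
            claim("c1", D(2016, 1, 1), INP, "I27.23"),
            claim("c2", D(2016, 3, 1), OUT, "I27.23"),
        ]
        rule = ph_rule(
            min_inpatient_claims=0, min_outpatient_claims=2,
            outpatient_settings=("inpatient", "outpatient"),
        )
        assert evaluate_condition_rule(claims, rule, registry).qualified

    def test_rule_requires_a_path(self):
        with pytest.raises(ConfigError):
            ConditionRule("ph", min_inpatient_claims=0, min_outpatient_claims=0)


class TestPhIndex:
    def test_index_is_first_ph_claim_not_confirmation(self, registry):
        claims = [
            claim("c1", D(2016, 1, 5), OUT, "I27.23"),
            claim("c2", D(2016, 3, 1), OUT, "I27.23"),
        ]
        index, ev = find_ph_index(claims, ph_rule(), registry)
        assert index == D(2016, 1, 5)
        assert ev.qualification_date == D(2016, 3, 1)
        index_conf, _ = find_ph_index(claims, ph_rule(), registry, index_on="confirmation")
        assert index_conf == D(2016, 3, 1)

    def test_single_unconfirmed_claim_gives_no_index(self, registry):
        index, ev = find_ph_index(
            [claim("c1", D(2016, 1, 5), OUT, "I27.23")], ph_rule(), registry
        )
        assert index is None and not ev.qualified

    def test_no_ph_codes_gives_no_index(self, registry):
        index, _ = find_ph_index(
            [claim("c1", D(2016, 1, 5), OUT, "J44.9")], ph_rule(), registry
        )
        assert index is None


def patient(pid="T", birth_year=1950):
    return Patient(pid, birth_year, (EnrollmentSpan(pid, D(2012, 1, 1), D(2019, 12, 31)),))


class TestExclusions:
    def test_pre_index_exclusion_triggers(self, recommended, registry):
        claims = [claim("x1", D(2016, 1, 1), OUT, "I50.3")]
        hits = apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)
        assert [h.codeset for h in hits] == ["excl_group2"]
        assert hits[0].claim_ids == ("x1",)

    def test_group4_years_before_index(self, recommended, registry):
        claims = [claim("x1", D(2014, 6, 1), OUT, "415.1")]
        hits = apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)
        assert [h.codeset for h in hits] == ["excl_group4"]

    def test_post_index_code_does_not_exclude_by_default(self, recommended, registry):
        claims = [claim("x1", D(2016, 7, 1), OUT, "I50.3")]
        assert not apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)

    def test_index_day_code_does_not_exclude(self, recommended, registry):
        claims = [claim("x1", D(2016, 6, 1), OUT, "I50.3")]
        assert not apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)

    def test_i27x_exclusions_flag(self, recommended, registry):
        claims = [claim("x1", D(2016, 1, 1), OUT, "I27.24")]
        assert not apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)
        recommended.use_i27x_exclusions = True
        hits = apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)
        assert [h.codeset for h in hits] == ["excl_group4"]

    def test_copd_only_mode_adds_ctd_exclusion(self, recommended, registry):
        claims = [claim("x1", D(2016, 1, 1), OUT, "M34.81")]
        assert not apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)
        recommended.copd_only_mode = True
        hits = apply_group_exclusions(claims, D(2016, 6, 1), recommended, registry)
        assert [h.codeset for h in hits] == ["ctd_lung"]


class TestBuildCohort:
    def test_full_inclusion_composition(self, recommended, registry):
        claims = [
            claim("l1", D(2015, 8, 1), OUT, "491.21"),  # ICD-9 era
            claim("l2", D(2015, 11, 1), OUT, "J44.9"),  # ICD-10 era
            claim("p1", D(2016, 3, 1), OUT, "I27.23"),
            claim("p2", D(2016, 4, 15), OUT, "I27.23"),
        ]
        r = build_cohort(claims, [patient()], recommended, registry)["T"]
        assert r.status is Status.INCLUDED
        assert r.index_date == D(2016, 3, 1)
        assert r.subtype is Subtype.COPD_PH
        assert not r.exclusion_reasons

    def test_ph_before_lung_is_sequence_exclusion(self, recommended, registry):
        claims, pats = make_fixture("sequence_reversed")
        r = build_cohort(claims, pats, recommended, registry)["FX"]
        assert r.status is Status.EXCLUDED_SEQUENCE

    def test_minor_at_index_excluded(self, recommended, registry):
        claims = [
            claim("l1", D(2015, 8, 1), OUT, "491.21"),
            claim("l2", D(2015, 11, 1), OUT, "496"),
            claim("p1", D(2016, 3, 1), OUT, "I27.23"),
            claim("p2", D(2016, 4, 15), OUT, "I27.23"),
        ]
        r = build_cohort(claims, [patient(birth_year=2005)], recommended, registry)["T"]
        assert r.status is Status.EXCLUDED_AGE

    def test_enrollment_gap_excludes(self, recommended, registry):
        p = Patient("T", 1950, (EnrollmentSpan("T", D(2016, 1, 1), D(2019, 12, 31)),))
        claims = [
            claim("l1", D(2016, 2, 1), OUT, "J44.1"),
            claim("l2", D(2016, 3, 1), OUT, "J44.9"),
            claim("p1", D(2016, 6, 1), OUT, "I27.23"),
            claim("p2", D(2016, 8, 15), OUT, "I27.23"),
        ]
        r = build_cohort(claims, [p], recommended, registry)["T"]
        assert r.status is Status.EXCLUDED_ENROLLMENT
        recommended.require_enrollment_through_baseline = False
        r2 = build_cohort(claims, [p], recommended, registry)["T"]
        assert r2.status is Status.INCLUDED

    def test_both_lung_diseases_get_combined_subtype(self, recommended, registry):
        claims = [
            claim("l1", D(2015, 8, 1), OUT, "491.21"),
            claim("l2", D(2015, 11, 1), OUT, "J44.9"),
            claim("i1", D(2015, 9, 1), OUT, "516.31"),
            claim("i2", D(2015, 12, 1), OUT, "J84.10"),
            claim("p1", D(2016, 3, 1), OUT, "I27.23"),
            claim("p2", D(2016, 4, 15), OUT, "I27.23"),
        ]
        r = build_cohort(claims, [patient()], recommended, registry)["T"]
        assert r.status is Status.INCLUDED
        assert r.subtype is Subtype.COPD_AND_ILD_PH

    def test_multi_group_mode_routes_instead_of_excluding(self, recommended, registry):
        claims = [
            claim("l1", D(2015, 8, 1), OUT, "491.21"),
            claim("l2", D(2015, 11, 1), OUT, "J44.9"),
            claim("x1", D(2015, 12, 1), OUT, "I50.3"),
            claim("p1", D(2016, 3, 1), OUT, "I27.23"),
            claim("p2", D(2016, 4, 15), OUT, "I27.23"),
        ]
        r = build_cohort(claims, [patient()], recommended, registry)["T"]
        assert r.status is Status.EXCLUDED_OTHER_GROUP
        recommended.multi_group_mode = "separate_cohort"
        r2 = build_cohort(claims, [patient()], recommended, registry)["T"]
        assert r2.status is Status.MULTI_GROUP
        assert [h.codeset for h in r2.exclusion_reasons] == ["excl_group2"]

    def test_unknown_codeset_fails_before_processing(self, recommended, registry):
        recommended.exclusion_rules = (ExclusionRule("nonexistent"),)
        with pytest.raises(ConfigError, match="nonexistent"):
            build_cohort([], [patient()], recommended, registry)

    def test_every_patient_appears_once(self, recommended, registry):
        pats = [patient("A"), patient("B"), patient("C")]
        results = build_cohort([], pats, recommended, registry)
        assert sorted(results) == ["A", "B", "C"]
        assert all(r.status is Status.NOT_PH for r in results.values())

    def test_claim_order_invariance(self, recommended, registry):
        claims = [
            claim("l1", D(2015, 8, 1), OUT, "491.21"),
            claim("l2", D(2015, 11, 1), OUT, "496"),
            claim("p1", D(2016, 3, 1), OUT, "I27.23"),
            claim("p2", D(2016, 4, 15), OUT, "I27.23"),
            claim("x1", D(2014, 1, 1), OUT, "415.1"),
        ]
        fwd = build_cohort(claims, [patient()], recommended, registry)["T"]
        rev = build_cohort(list(reversed(claims)), [patient()], recommended, registry)["T"]
        assert fwd == rev

    def test_same_day_inpatient_outpatient_tie_prefers_inpatient(self, registry, recommended):
        claims = [
            claim("a_out", D(2016, 3, 1), OUT, "I27.23"),
            claim("b_inp", D(2016, 3, 1), INP, "I27.23"),
        ]
        _, ev = find_ph_index(claims, recommended.ph_rule, registry)
        assert ev.path == "inpatient"


class TestBoundaries:
    """Hand-built micro-histories at the algorithm's decision boundaries."""

    @pytest.mark.parametrize(
        "tag, expected",
        [
            ("ph_29day_gap", Status.NOT_PH),
            ("ph_30day_gap", Status.INCLUDED),
            ("baseline_boundary", Status.INCLUDED),
            ("index_day_excl", Status.INCLUDED),
            ("post_index_lung", Status.EXCLUDED_SEQUENCE),
            ("sequence_reversed", Status.EXCLUDED_SEQUENCE),
        ],
    )
    def test_recommended_boundaries(self, recommended, registry, tag, expected):
        claims, pats = make_fixture(tag)
        assert build_cohort(claims, pats, recommended, registry)["FX"].status is expected


class TestReporting:
    def test_attrition_counts_are_monotone(self, recommended, registry):
        claims = []
        pats = []
        for tag in ("ph_30day_gap", "ph_29day_gap", "sequence_reversed"):
            c, p = make_fixture(tag)
            pid = f"FX_{tag}"
            claims += [
                Claim(pid, f"{pid}-{x.claim_id}", x.service_date, x.setting, x.dx_codes)
                for x in c
            ]
            pats.append(Patient(pid, p[0].birth_year, tuple(
                EnrollmentSpan(pid, s.start_date, s.end_date) for s in p[0].enrollment
            )))
        results = build_cohort(claims, pats, recommended, registry)
        table = attrition_table(results)
        counts = [n for _, n in table]
        assert counts[0] == 3
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 1  # only the 30-day-gap patient survives

    def test_trace_matches_cohort_status(self, recommended, registry):
        claims, pats = make_fixture("index_day_excl")
        text = trace_patient("FX", claims, pats, recommended, registry)
        assert text.splitlines()[-1] == "  status: included"
        assert trace_patient("FX", claims, pats, recommended, registry) == text

    def test_trace_unknown_patient(self, recommended, registry):
        claims, pats = make_fixture("index_day_excl")
        with pytest.raises(KeyError):
            trace_patient("NOBODY", claims, pats, recommended, registry)

    def test_trace_names_exclusion_set(self, recommended, registry):
        claims, pats = make_fixture("sequence_reversed")
        extra = claim("x1", D(2014, 1, 1), OUT, "415.1", pid="FX")
        c2, _ = make_fixture("ph_30day_gap")
        full = [Claim("FX", x.claim_id, x.service_date, x.setting, x.dx_codes) for x in c2]
        text = trace_patient("FX", full + [extra], pats, recommended, registry)
        assert "exclusion excl_group4" in text
        assert "x1" in text
        assert text.splitlines()[-1] == "  status: excluded_other_group"


class TestConfigIO:
    def test_yaml_roundtrip(self, recommended, tmp_path):
        path = tmp_path / "cfg.yaml"
        save_config(recommended, path)
        loaded = load_config(path)
        assert config_to_dict(loaded) == config_to_dict(recommended)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="bogus_knob"):
            config_from_dict({"bogus_knob": 1})

    def test_unknown_rule_key_rejected(self, recommended):
        d = config_to_dict(recommended)
        d["ph_rule"]["fuzzy"] = True
        with pytest.raises(ConfigError, match="fuzzy"):
            config_from_dict(d)

    def test_invalid_values_rejected(self, recommended):
        d = config_to_dict(recommended)
        d["exclusion_window"] = "whenever"
        with pytest.raises(ConfigError):
            config_from_dict(d)
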