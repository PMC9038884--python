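"""Validation layer: brute-force oracle, confusion metrics, sensitivity sweeps.

``brute_force_cohort`` re-derives every patient's status by exhaustive
enumeration — for multi-claim rules it tests *all* subsets of the required
size against the separation/span constraints — and shares no code with the
engine's incremental witness search.  It is intentionally slow and only for
corpora up to a few thousand patients; its sole job is to certify the
engine on randomized inputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .claims import Claim, Patient, Setting
from .codesets import CodeSetRegistry, CodingSystem
from .engine import (
    AlgorithmConfig,
    CohortResult,
    ConditionRule,
    ExclusionHit,
    Status,
    Subtype,
    build_cohort,
)
from .synthetic import TruthLabel


# --------------------------------------------------------------------------
# oracle

def _bf_claim_matches(claim: Claim, codeset, positions: str) -> bool:
    if positions == "any":
        dx = list(claim.dx_codes)
    elif positions == "primary_only":
        dx = list(claim.dx_codes)[:1]
    else:
        dx = list(claim.dx_codes)[:2]
    return any(codeset.matches(d) for d in dx)


def _bf_setting(claim: Claim, emergency_as_outpatient: bool) -> str:
    if claim.setting is Setting.EMERGENCY and emergency_as_outpatient:
        return "outpatient"
    return claim.setting.value


def _bf_rule_dates(
    claims: Sequence[Claim],
    rule: ConditionRule,
    registry: CodeSetRegistry,
    emergency_as_outpatient: bool,
    window: tuple[dt.date, dt.date] | None,
) -> tuple[dt.date | None, dt.date | None]:
    """(earliest qualification date, earliest matching-claim date) via
    exhaustive subset enumeration; (None, first_date) when unqualified."""
    codeset = registry[rule.codeset]
    matching = [
        c for c in claims
        if _bf_claim_matches(c, codeset, rule.allowed_positions.value)
        and (window is None or window[0] <= c.service_date <= window[1])
    ]
    if not matching:
        return None, None
    first = min(c.service_date for c in matching)
    qual_dates: list[dt.date] = []
    if rule.min_inpatient_claims > 0:
        inpt = sorted(
            {c.claim_id: c for c in matching if c.setting is Setting.INPATIENT}.values(),
            key=lambda c: (c.service_date, c.claim_id),
        )
        if len(inpt) >= rule.min_inpatient_claims:
            qual_dates.append(inpt[rule.min_inpatient_claims - 1].service_date)
    if rule.min_outpatient_claims > 0:
        allowed = set(rule.outpatient_settings)
        outp = [
            c for c in matching
            if _bf_setting(c, emergency_as_outpatient) in allowed
            or c.setting.value in allowed
        ]
        k = rule.min_outpatient_claims
        for subset in combinations(sorted(outp, key=lambda c: (c.service_date, c.claim_id)), k):
            dates = sorted(c.service_date for c in subset)
            if all(
                (dates[i + 1] - dates[i]).days >= rule.outpatient_min_separation_days
                for i in range(k - 1)
            ) and (
                rule.outpatient_max_span_days is None
                or (dates[-1] - dates[0]).days <= rule.outpatient_max_span_days
            ):
                qual_dates.append(dates[-1])
    if not qual_dates:
        return None, first
    return min(qual_dates), first


def brute_force_cohort(
    claims: Sequence[Claim],
    patients: Sequence[Patient],
    config: AlgorithmConfig,
    registry: CodeSetRegistry,
) -> dict[str, CohortResult]:
    """Oracle reimplementation of the full algorithm by plain enumeration."""
    config.validate_against(registry)
    by_patient: dict[str, list[Claim]] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)

    results: dict[str, CohortResult] = {}
    for p in patients:
        pc = by_patient.get(p.patient_id, [])
        ea = config.emergency_as_outpatient

        ph_qual, ph_first = _bf_rule_dates(pc, config.ph_rule, registry, ea, None)
        if ph_qual is None:
            results[p.patient_id] = CohortResult(p.patient_id, Status.NOT_PH)
            continue
        index = ph_first if config.index_on == "first_claim" else ph_qual

        if index.year - p.birth_year < config.min_age_at_index:
            results[p.patient_id] = CohortResult(
                p.patient_id, Status.EXCLUDED_AGE, index_date=index
            )
            continue

        if config.require_enrollment_through_baseline:
            start = index - dt.timedelta(days=config.baseline_days)
            if not any(
                s.start_date <= start and index <= s.end_date for s in p.enrollment
            ):
                results[p.patient_id] = CohortResult(
                    p.patient_id, Status.EXCLUDED_ENROLLMENT, index_date=index
                )
                continue

        window = (
            index - dt.timedelta(days=config.baseline_days),
            index + dt.timedelta(days=config.sequence_tolerance_days),
        )
        copd_ok = ild_ok = False
        any_ever = False
        if config.lung_rule is not None:
            q, _ = _bf_rule_dates(pc, config.lung_rule, registry, ea, window)
            copd_ok = q is not None
            any_ever = any_ever or _bf_rule_dates(
                pc, config.lung_rule, registry, ea, None
            )[0] is not None
        if config.ild_rule is not None:
            q, _ = _bf_rule_dates(pc, config.ild_rule, registry, ea, window)
            ild_ok = q is not None
            any_ever = any_ever or _bf_rule_dates(
                pc, config.ild_rule, registry, ea, None
            )[0] is not None
        if not (copd_ok or ild_ok):
            status = Status.EXCLUDED_SEQUENCE if any_ever else Status.EXCLUDED_NO_LUNG_DISEASE
            results[p.patient_id] = CohortResult(p.patient_id, status, index_date=index)
            continue
        subtype = (
            Subtype.COPD_AND_ILD_PH if copd_ok and ild_ok
            else Subtype.COPD_PH if copd_ok else Subtype.ILD_PH
        )

        excluded_sets = []
        for rule in config.active_exclusion_rules():
            cs = registry[rule.codeset]
            if not config.use_i27x_exclusions:
                cs = cs.restricted(
                    lambda e: not (
                        e.system is CodingSystem.ICD10CM and e.pattern.startswith("I27")
                    )
                )
            n = 0
            for c in pc:
                if config.exclusion_window == "pre_index_only":
                    ok = c.service_date < index
                elif config.exclusion_post_days is not None:
                    ok = c.service_date <= index + dt.timedelta(
                        days=config.exclusion_post_days
                    )
                else:
                    ok = True
                if ok and any(cs.matches(d) for d in c.dx_codes):
                    n += 1
            if n >= rule.min_claims:
                excluded_sets.append(rule.codeset)
        if config.proc_exclusion_prefixes:
            prefixes = tuple(
                p.replace(".", "").upper() for p in config.proc_exclusion_prefixes
            )
            for c in pc:
                if config.exclusion_window == "pre_index_only":
                    ok = c.service_date < index
                elif config.exclusion_post_days is not None:
                    ok = c.service_date <= index + dt.timedelta(
                        days=config.exclusion_post_days
                    )
                else:
                    ok = True
                if ok and any(pr.startswith(prefixes) for pr in c.proc_codes):
                    excluded_sets.append("procedure_exclusion")
                    break

        if excluded_sets:
            status = (
                Status.MULTI_GROUP if config.multi_group_mode == "separate_cohort"
                else Status.EXCLUDED_OTHER_GROUP
            )
            # set names only; witness claim ids are an engine-side detail
            results[p.patient_id] = CohortResult(
                p.patient_id, status, index_date=index, subtype=subtype,
                exclusion_reasons=tuple(ExclusionHit(n, ()) for n in excluded_sets),
            )
            continue

        results[p.patient_id] = CohortResult(
            p.patient_id, Status.INCLUDED, index_date=index, subtype=subtype
        )
    return results


def compare_cohorts(
    engine_results: Mapping[str, CohortResult],
    oracle_results: Mapping[str, CohortResult],
) -> list[str]:
    """Field-level disagreements (status, index date, subtype, exclusion
    set names) between engine and oracle; empty list means equivalence."""
    problems = []
    if set(engine_results) != set(oracle_results):
        problems.append("patient id sets differ")
        return problems
    for pid in sorted(engine_results):
        e, o = engine_results[pid], oracle_results[pid]
        if e.status is not o.status:
            problems.append(f"{pid}: status {e.status.value} != {o.status.value}")
            continue
        if e.index_date != o.index_date:
            problems.append(f"{pid}: index {e.index_date} != {o.index_date}")
        if e.status in (Status.INCLUDED, Status.EXCLUDED_OTHER_GROUP, Status.MULTI_GROUP):
            if e.subtype is not o.subtype:
                problems.append(f"{pid}: subtype {e.subtype} != {o.subtype}")
        e_sets = sorted(h.codeset for h in e.exclusion_reasons)
        o_sets = sorted(h.codeset for h in o.exclusion_reasons)
        if e_sets != o_sets:
            problems.append(f"{pid}: exclusion sets {e_sets} != {o_sets}")
    return problems


# --------------------------------------------------------------------------
# confusion metrics

@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 agreement between algorithm inclusion and ground-truth stratum.

    Undefined ratios (zero denominators) are None, never coerced to 0."""

    tp: int
    fp: int
    fn: int
    tn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
        }


POSITIVE_STRATA = ("g3_copd", "g3_ild", "g3_both")


def confusion_metrics(
    results: Mapping[str, CohortResult],
    truth: Sequence[TruthLabel],
    positive_strata: Sequence[str] = POSITIVE_STRATA,
    *,
    multi_group_as_included: bool = False,
) -> ConfusionMetrics:
    """Score algorithm inclusion against simulator ground truth."""
    labels = {t.patient_id: t for t in truth}
    missing = sorted(set(results) - set(labels))
    if missing:
        raise ValueError(f"patients without truth labels: {missing[:10]}")
    tp = fp = fn = tn = 0
    included_statuses = {Status.INCLUDED}
    if multi_group_as_included:
        included_statuses.add(Status.MULTI_GROUP)
    for pid, r in results.items():
        predicted = r.status in included_statuses
        actual = labels[pid].stratum in set(positive_strata)
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return ConfusionMetrics(tp, fp, fn, tn)


# --------------------------------------------------------------------------
# criteria sensitivity sweep

def criteria_sensitivity_sweep(
    claims: Sequence[Claim],
    patients: Sequence[Patient],
    configs: Sequence[tuple[str, AlgorithmConfig]],
    registry: CodeSetRegistry,
) -> pd.DataFrame:
    """Run each labeled config; first config is the reference.

    Returns one row per config: included count, Jaccard overlap of the
    included set with the reference, and per-status counts."""
    if not configs:
        raise ValueError("at least one config required")
    labels = [label for label, _ in configs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate config labels in sweep: {labels}")
    rows = []
    reference: set[str] | None = None
    for label, config in configs:
        results = build_cohort(claims, patients, config, registry)
        included = {pid for pid, r in results.items() if r.status is Status.INCLUDED}
        if reference is None:
            reference = included
        union = reference | included
        jaccard = len(reference & included) / len(union) if union else 1.0
        row = {"config": label, "n_included": len(included), "jaccard_vs_reference": jaccard}
        for status in Status:
            row[f"n_{status.value}"] = sum(
                1 for r in results.values() if r.status is status
            )
        rows.append(row)
    return pd.DataFrame(rows)
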