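"""Phenotype execution engine for Group 3 PH with COPD or ILD.

The recommended algorithm has four components, evaluated per patient in a
fixed order:

1. **PH identification** — a confirmed PH diagnosis (default: one inpatient
   claim, or two outpatient claims at least 30 days apart, primary or
   secondary position).  The patient is indexed on the *first* PH-coded
   claim, even when confirmation arrives later.
2. **Age / enrollment** — adult at index and continuously enrolled through
   the baseline lookback window.
3. **COPD/ILD before PH** — a lung-disease rule must qualify inside
   ``[index - baseline_days, index + sequence_tolerance_days]``; with the
   default tolerance of 0 this enforces PH-after-lung-disease.
4. **Other-PH-group exclusions** — code sets for PH groups 1, 2, 4, 5 and
   other Group 3 conditions, counted strictly *before* the index date by
   default (claims on the index date never exclude: same-day workup codes
   are diagnostic noise, not prior disease).

Every decision is recorded in a :class:`CohortResult` with the qualifying
claim ids, so a cohort definition is auditable claim by claim.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .claims import Claim, Patient, Setting
from .codesets import CodeSet, CodeSetRegistry, CodingSystem


class Positions(str, Enum):
    PRIMARY_SECONDARY = "primary_secondary"
    ANY = "any"
    PRIMARY_ONLY = "primary_only"


class Status(str, Enum):
    INCLUDED = "included"
    NOT_PH = "not_ph"
    EXCLUDED_AGE = "excluded_age"
    EXCLUDED_ENROLLMENT = "excluded_enrollment"
    EXCLUDED_NO_LUNG_DISEASE = "excluded_no_lung_disease"
    EXCLUDED_SEQUENCE = "excluded_sequence"
    EXCLUDED_OTHER_GROUP = "excluded_other_group"
    MULTI_GROUP = "multi_group"


class Subtype(str, Enum):
    COPD_PH = "copd_ph"
    ILD_PH = "ild_ph"
    COPD_AND_ILD_PH = "copd_and_ild_ph"


class ConfigError(ValueError):
    """Invalid algorithm configuration (caught before any patient runs)."""


@dataclass(frozen=True)
class ConditionRule:
    """Claim-count rule for one condition.

    Two qualification paths, either of which suffices:

    * inpatient path: >= ``min_inpatient_claims`` distinct inpatient claims
      bearing a set code in an allowed position (0 disables the path);
    * repeat-claim path: >= ``min_outpatient_claims`` claims in
      ``outpatient_settings`` whose consecutive qualifying claims are at
      least ``outpatient_min_separation_days`` apart, first-to-last within
      ``outpatient_max_span_days`` (None = no cap).

    ``outpatient_settings`` defaults to outpatient only; study presets that
    count inpatient and outpatient claims toward one total widen it.
    """

    codeset: str
    min_inpatient_claims: int = 1
    min_outpatient_claims: int = 2
    outpatient_min_separation_days: int = 1
    outpatient_max_span_days: int | None = None
    allowed_positions: Positions = Positions.PRIMARY_SECONDARY
    outpatient_settings: tuple[str, ...] = ("outpatient",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_positions", Positions(self.allowed_positions))
        object.__setattr__(
            self, "outpatient_settings", tuple(sorted(set(self.outpatient_settings)))
        )
        if self.min_inpatient_claims < 0 or self.min_outpatient_claims < 0:
            raise ConfigError("claim-count thresholds must be >= 0")
        if self.min_inpatient_claims == 0 and self.min_outpatient_claims == 0:
            raise ConfigError("rule must enable at least one qualification path")
        if self.outpatient_min_separation_days < 0:
            raise ConfigError("separation days must be >= 0")
        if (
            self.outpatient_max_span_days is not None
            and self.min_outpatient_claims >= 2
            and self.outpatient_max_span_days
            < self.outpatient_min_separation_days * (self.min_outpatient_claims - 1)
        ):
            raise ConfigError("max span too short for the required separations")


@dataclass(frozen=True)
class ExclusionRule:
    codeset: str
    min_claims: int = 1

    def __post_init__(self) -> None:
        if self.min_claims < 1:
            raise ConfigError("exclusion claim threshold must be >= 1")


@dataclass
class AlgorithmConfig:
    """Every knob of a phenotype definition.  Defaults give the recommended
    algorithm (12-month baseline)."""

    name: str = "recommended"
    lung_rule: ConditionRule | None = field(
        default_factory=lambda: ConditionRule(codeset="copd")
    )
    ild_rule: ConditionRule | None = field(
        default_factory=lambda: ConditionRule(codeset="ild")
    )
    ph_rule: ConditionRule = field(
        default_factory=lambda: ConditionRule(
            codeset="ph", min_inpatient_claims=1, min_outpatient_claims=2,
            outpatient_min_separation_days=30,
        )
    )
    baseline_days: int = 365
    require_enrollment_through_baseline: bool = True
    min_age_at_index: int = 18
    exclusion_rules: tuple[ExclusionRule, ...] = field(
        default_factory=lambda: tuple(
            ExclusionRule(name) for name in (
                "excl_group1", "excl_group2", "excl_group3_other",
                "excl_group4", "excl_group5",
            )
        )
    )
    exclusion_window: str = "pre_index_only"  # or "pre_and_post"
    exclusion_post_days: int | None = None    # cap for pre_and_post mode
    multi_group_mode: str = "exclude"         # or "separate_cohort"
    copd_only_mode: bool = False
    use_i27x_exclusions: bool = False
    sequence_tolerance_days: int = 0
    index_on: str = "first_claim"             # or "confirmation"
    emergency_as_outpatient: bool = True
    proc_exclusion_prefixes: tuple[str, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.baseline_days < 1:
            raise ConfigError("baseline_days must be >= 1")
        if self.exclusion_window not in ("pre_index_only", "pre_and_post"):
            raise ConfigError(f"unknown exclusion_window {self.exclusion_window!r}")
        if self.multi_group_mode not in ("exclude", "separate_cohort"):
            raise ConfigError(f"unknown multi_group_mode {self.multi_group_mode!r}")
        if self.index_on not in ("first_claim", "confirmation"):
            raise ConfigError(f"unknown index_on {self.index_on!r}")
        if self.sequence_tolerance_days < 0:
            raise ConfigError("sequence_tolerance_days must be >= 0")
        if self.lung_rule is None and self.ild_rule is None:
            raise ConfigError("at least one of lung_rule/ild_rule must be set")

    def active_exclusion_rules(self) -> tuple[ExclusionRule, ...]:
        rules = list(self.exclusion_rules)
        if self.copd_only_mode and not any(r.codeset == "ctd_lung" for r in rules):
            rules.append(ExclusionRule("ctd_lung", 1))
        return tuple(rules)

    def validate_against(self, registry: CodeSetRegistry) -> None:
        """Raise ConfigError if any referenced code set is missing."""
        names = [r.codeset for r in (self.lung_rule, self.ild_rule, self.ph_rule) if r]
        names += [r.codeset for r in self.active_exclusion_rules()]
        for n in names:
            if n not in registry:
                raise ConfigError(
                    f"config {self.name!r} references unknown code set {n!r}"
                )


@dataclass(frozen=True)
class ConditionEvidence:
    qualified: bool
    path: str = "none"  # inpatient | outpatient | none
    qualifying_claim_ids: tuple[str, ...] = ()
    first_code_date: dt.date | None = None
    qualification_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.qualified:
            assert self.qualifying_claim_ids and self.qualification_date is not None
            assert self.first_code_date is not None
            assert self.first_code_date <= self.qualification_date


@dataclass(frozen=True)
class ExclusionHit:
    codeset: str
    claim_ids: tuple[str, ...]


@dataclass
class CohortResult:
    patient_id: str
    status: Status
    index_date: dt.date | None = None
    subtype: Subtype | None = None
    exclusion_reasons: tuple[ExclusionHit, ...] = ()
    ph_evidence: ConditionEvidence | None = None
    copd_evidence: ConditionEvidence | None = None
    ild_evidence: ConditionEvidence | None = None

    def __post_init__(self) -> None:
        if self.status is Status.INCLUDED:
            assert self.index_date is not None and self.subtype is not None
            assert not self.exclusion_reasons


# --------------------------------------------------------------------------
# rule evaluation

def _effective_setting(claim: Claim, config_emergency_as_outpatient: bool = True) -> str:
    if claim.setting is Setting.EMERGENCY and config_emergency_as_outpatient:
        return Setting.OUTPATIENT.value
    return claim.setting.value


def _positions_ok(claim: Claim, codeset: CodeSet, positions: Positions) -> bool:
    if positions is Positions.ANY:
        pool = claim.dx_codes
    elif positions is Positions.PRIMARY_ONLY:
        pool = claim.dx_codes[:1]
    else:
        pool = claim.dx_codes[:2]
    return any(codeset.matches(dx) for dx in pool)


def _sorted_claims(claims: Iterable[Claim]) -> list[Claim]:
    return sorted(claims, key=lambda c: (c.service_date, c.claim_id))


def _greedy_chain(
    claims: list[Claim], k: int, sep: int, max_span: int | None
) -> list[Claim] | None:
    """Earliest-finishing chain of k claims with consecutive gaps >= sep and
    total span <= max_span; None if none exists.

    For a fixed first claim the greedy continuation (always take the
    earliest admissible next claim) minimizes the finishing date and hence
    the span, so scanning all starting claims finds the earliest witness.
    """
    best: list[Claim] | None = None
    for i in range(len(claims)):
        chain = [claims[i]]
        for j in range(i + 1, len(claims)):
            if len(chain) == k:
                break
            if (claims[j].service_date - chain[-1].service_date).days >= sep:
                chain.append(claims[j])
        if len(chain) < k:
            continue
        if max_span is not None and (
            chain[-1].service_date - chain[0].service_date
        ).days > max_span:
            continue
        if best is None or chain[-1].service_date < best[-1].service_date:
            best = chain
    return best


def evaluate_condition_rule(
    patient_claims: Sequence[Claim],
    rule: ConditionRule,
    registry: CodeSetRegistry,
    window: tuple[dt.date, dt.date] | None = None,
    *,
    emergency_as_outpatient: bool = True,
) -> ConditionEvidence:
    """Evaluate one condition rule, optionally restricted to a date window
    (inclusive on both ends).  Deterministic; ties broken by claim id."""
    codeset = registry[rule.codeset]
    claims = _sorted_claims(
        c for c in patient_claims
        if (window is None or window[0] <= c.service_date <= window[1])
        and _positions_ok(c, codeset, rule.allowed_positions)
    )
    if not claims:
        return ConditionEvidence(qualified=False)
    first_date = claims[0].service_date

    inpatient_witness: list[Claim] | None = None
    if rule.min_inpatient_claims > 0:
        inpt = [c for c in claims if c.setting is Setting.INPATIENT]
        # distinct claim ids; claims are already unique per id
        if len(inpt) >= rule.min_inpatient_claims:
            inpatient_witness = inpt[: rule.min_inpatient_claims]

    outpatient_witness: list[Claim] | None = None
    if rule.min_outpatient_claims > 0:
        allowed = set(rule.outpatient_settings)
        outp = [
            c for c in claims
            if _effective_setting(c, emergency_as_outpatient) in allowed
            or c.setting.value in allowed
        ]
        if rule.min_outpatient_claims == 1:
            outpatient_witness = outp[:1] or None
        else:
            outpatient_witness = _greedy_chain(
                outp,
                rule.min_outpatient_claims,
                rule.outpatient_min_separation_days,
                rule.outpatient_max_span_days,
            )

    # earliest qualification wins; inpatient path first on ties
    candidates: list[tuple[dt.date, int, list[Claim], str]] = []
    if inpatient_witness:
        candidates.append(
            (inpatient_witness[-1].service_date, 0, inpatient_witness, "inpatient")
        )
    if outpatient_witness:
        candidates.append(
            (outpatient_witness[-1].service_date, 1, outpatient_witness, "outpatient")
        )
    if not candidates:
        return ConditionEvidence(qualified=False)
    candidates.sort(key=lambda t: (t[0], t[1]))
    qual_date, _, witness, path = candidates[0]
    return ConditionEvidence(
        qualified=True,
        path=path,
        qualifying_claim_ids=tuple(c.claim_id for c in witness),
        first_code_date=first_date,
        qualification_date=qual_date,
    )


def find_ph_index(
    patient_claims: Sequence[Claim],
    ph_rule: ConditionRule,
    registry: CodeSetRegistry,
    *,
    index_on: str = "first_claim",
    emergency_as_outpatient: bool = True,
) -> tuple[dt.date | None, ConditionEvidence]:
    """Index date (first PH-coded claim once the rule is confirmed) or None.

    The index may precede the qualification date when confirmation needs a
    second claim; ``index_on="confirmation"`` indexes on the latter instead.
    """
    evidence = evaluate_condition_rule(
        patient_claims, ph_rule, registry,
        emergency_as_outpatient=emergency_as_outpatient,
    )
    if not evidence.qualified:
        return None, evidence
    if index_on == "confirmation":
        return evidence.qualification_date, evidence
    return evidence.first_code_date, evidence


def check_baseline_lung_disease(
    patient_claims: Sequence[Claim],
    index_date: dt.date,
    config: AlgorithmConfig,
    registry: CodeSetRegistry,
) -> tuple[ConditionEvidence | None, ConditionEvidence | None]:
    """Evaluate COPD and ILD rules inside the baseline window
    [index - baseline_days, index + sequence_tolerance_days]; both are
    returned so combined COPD+ILD disease can be reported as its own
    subtype."""
    window = (
        index_date - dt.timedelta(days=config.baseline_days),
        index_date + dt.timedelta(days=config.sequence_tolerance_days),
    )
    out = []
    for rule in (config.lung_rule, config.ild_rule):
        if rule is None:
            out.append(None)
        else:
            out.append(
                evaluate_condition_rule(
                    patient_claims, rule, registry, window,
                    emergency_as_outpatient=config.emergency_as_outpatient,
                )
            )
    return out[0], out[1]


def _effective_exclusion_set(codeset: CodeSet, use_i27x: bool) -> CodeSet:
    """Drop I27.x entries from an exclusion set unless explicitly enabled
    (five-digit I27 children overlap Group 1/3 coding practice)."""
    if use_i27x:
        return codeset
    return codeset.restricted(
        lambda e: not (e.system is CodingSystem.ICD10CM and e.pattern.startswith("I27"))
    )


def apply_group_exclusions(
    patient_claims: Sequence[Claim],
    index_date: dt.date,
    config: AlgorithmConfig,
    registry: CodeSetRegistry,
) -> tuple[ExclusionHit, ...]:
    """Threshold-meeting exclusion sets; claims ON the index date never
    trigger in pre_index_only mode (strictly before)."""
    hits: list[ExclusionHit] = []
    if config.exclusion_window == "pre_index_only":
        def in_window(d: dt.date) -> bool:
            return d < index_date
    else:
        cap = (
            index_date + dt.timedelta(days=config.exclusion_post_days)
            if config.exclusion_post_days is not None
            else None
        )
        def in_window(d: dt.date) -> bool:
            return cap is None or d <= cap

    for rule in config.active_exclusion_rules():
        codeset = _effective_exclusion_set(registry[rule.codeset], config.use_i27x_exclusions)
        matching = _sorted_claims(
            c for c in patient_claims
            if in_window(c.service_date)
            and any(codeset.matches(dx) for dx in c.dx_codes)  # any position
        )
        if len(matching) >= rule.min_claims:
            hits.append(
                ExclusionHit(rule.codeset, tuple(c.claim_id for c in matching))
            )
    if config.proc_exclusion_prefixes:
        prefixes = tuple(p.replace(".", "").upper() for p in config.proc_exclusion_prefixes)
        matching = _sorted_claims(
            c for c in patient_claims
            if in_window(c.service_date)
            and any(pc.startswith(prefixes) for pc in c.proc_codes)
        )
        if matching:
            hits.append(
                ExclusionHit("procedure_exclusion", tuple(c.claim_id for c in matching))
            )
    return tuple(hits)


def _subtype(copd_ev: ConditionEvidence | None, ild_ev: ConditionEvidence | None) -> Subtype | None:
    copd = copd_ev is not None and copd_ev.qualified
    ild = ild_ev is not None and ild_ev.qualified
    if copd and ild:
        return Subtype.COPD_AND_ILD_PH
    if copd:
        return Subtype.COPD_PH
    if ild:
        return Subtype.ILD_PH
    return None


def evaluate_patient(
    patient: Patient,
    patient_claims: Sequence[Claim],
    config: AlgorithmConfig,
    registry: CodeSetRegistry,
) -> CohortResult:
    """Run the four algorithm components for one patient, in fixed order."""
    claims = _sorted_claims(patient_claims)
    index, ph_ev = find_ph_index(
        claims, config.ph_rule, registry,
        index_on=config.index_on,
        emergency_as_outpatient=config.emergency_as_outpatient,
    )
    if index is None:
        return CohortResult(patient.patient_id, Status.NOT_PH, ph_evidence=ph_ev)

    if patient.age_at(index) < config.min_age_at_index:
        return CohortResult(
            patient.patient_id, Status.EXCLUDED_AGE, index_date=index, ph_evidence=ph_ev
        )

    if config.require_enrollment_through_baseline:
        start = index - dt.timedelta(days=config.baseline_days)
        if not patient.enrolled_through(start, index):
            return CohortResult(
                patient.patient_id, Status.EXCLUDED_ENROLLMENT,
                index_date=index, ph_evidence=ph_ev,
            )

    copd_ev, ild_ev = check_baseline_lung_disease(claims, index, config, registry)
    subtype = _subtype(copd_ev, ild_ev)
    if subtype is None:
        # distinguish "never had qualifying lung disease" from "had it, but
        # not inside the baseline/sequence window"
        any_unrestricted = False
        for rule in (config.lung_rule, config.ild_rule):
            if rule is not None and evaluate_condition_rule(
                claims, rule, registry,
                emergency_as_outpatient=config.emergency_as_outpatient,
            ).qualified:
                any_unrestricted = True
                break
        status = (
            Status.EXCLUDED_SEQUENCE if any_unrestricted
            else Status.EXCLUDED_NO_LUNG_DISEASE
        )
        return CohortResult(
            patient.patient_id, status, index_date=index,
            ph_evidence=ph_ev, copd_evidence=copd_ev, ild_evidence=ild_ev,
        )

    hits = apply_group_exclusions(claims, index, config, registry)
    if hits:
        status = (
            Status.MULTI_GROUP if config.multi_group_mode == "separate_cohort"
            else Status.EXCLUDED_OTHER_GROUP
        )
        return CohortResult(
            patient.patient_id, status, index_date=index, subtype=subtype,
            exclusion_reasons=hits,
            ph_evidence=ph_ev, copd_evidence=copd_ev, ild_evidence=ild_ev,
        )

    return CohortResult(
        patient.patient_id, Status.INCLUDED, index_date=index, subtype=subtype,
        ph_evidence=ph_ev, copd_evidence=copd_ev, ild_evidence=ild_ev,
    )


def build_cohort(
    claims: Sequence[Claim],
    patients: Sequence[Patient],
    config: AlgorithmConfig,
    registry: CodeSetRegistry,
) -> dict[str, CohortResult]:
    """One CohortResult per input patient, keyed by patient id.

    Deterministic and independent of input claim order; configuration
    errors (unknown code sets) surface before any patient is processed."""
    config.validate_against(registry)
    by_patient: dict[str, list[Claim]] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)
    results: dict[str, CohortResult] = {}
    for p in sorted(patients, key=lambda p: p.patient_id):
        results[p.patient_id] = evaluate_patient(
            p, by_patient.get(p.patient_id, []), config, registry
        )
    return results


# --------------------------------------------------------------------------
# reporting

ATTRITION_ORDER = [
    ("total_patients", None),
    ("ph_confirmed", {Status.NOT_PH}),
    ("adult_at_index", {Status.NOT_PH, Status.EXCLUDED_AGE}),
    ("enrolled_through_baseline",
     {Status.NOT_PH, Status.EXCLUDED_AGE, Status.EXCLUDED_ENROLLMENT}),
    ("baseline_lung_disease",
     {Status.NOT_PH, Status.EXCLUDED_AGE, Status.EXCLUDED_ENROLLMENT,
      Status.EXCLUDED_NO_LUNG_DISEASE, Status.EXCLUDED_SEQUENCE}),
    ("no_other_group_exclusion",
     {Status.NOT_PH, Status.EXCLUDED_AGE, Status.EXCLUDED_ENROLLMENT,
      Status.EXCLUDED_NO_LUNG_DISEASE, Status.EXCLUDED_SEQUENCE,
      Status.EXCLUDED_OTHER_GROUP, Status.MULTI_GROUP}),
]


def attrition_table(results: Mapping[str, CohortResult]) -> list[tuple[str, int]]:
    """Sequential criterion survival counts, mirroring evaluation order."""
    rows = []
    for label, failed in ATTRITION_ORDER:
        if failed is None:
            rows.append((label, len(results)))
        else:
            rows.append((label, sum(1 for r in results.values() if r.status not in failed)))
    return rows


def results_to_rows(results: Mapping[str, CohortResult]) -> list[dict]:
    rows = []
    for pid in sorted(results):
        r = results[pid]
        rows.append({
            "patient_id": pid,
            "status": r.status.value,
            "index_date": r.index_date.isoformat() if r.index_date else "",
            "subtype": r.subtype.value if r.subtype else "",
            "exclusion_reasons": ";".join(h.codeset for h in r.exclusion_reasons),
            "lung_path": (r.copd_evidence.path if r.copd_evidence and r.copd_evidence.qualified
                          else r.ild_evidence.path if r.ild_evidence and r.ild_evidence.qualified
                          else "none"),
            "ph_path": r.ph_evidence.path if r.ph_evidence else "none",
            "ph_claims": ";".join(r.ph_evidence.qualifying_claim_ids) if r.ph_evidence else "",
            "lung_claims": ";".join(
                (r.copd_evidence.qualifying_claim_ids if r.copd_evidence else ())
                + (r.ild_evidence.qualifying_claim_ids if r.ild_evidence else ())
            ),
        })
    return rows


def trace_patient(
    patient_id: str,
    claims: Sequence[Claim],
    patients: Sequence[Patient],
    config: AlgorithmConfig,
    registry: CodeSetRegistry,
) -> str:
    """Human-readable criteria trace for one patient; stable across runs."""
    by_id = {p.patient_id: p for p in patients}
    if patient_id not in by_id:
        raise KeyError(f"unknown patient id {patient_id!r}")
    pclaims = _sorted_claims(c for c in claims if c.patient_id == patient_id)
    r = evaluate_patient(by_id[patient_id], pclaims, config, registry)
    lines = [f"patient {patient_id} under config {config.name!r}"]
    lines.append(f"  claims: {len(pclaims)}")
    for c in pclaims:
        dx = " ".join(f"{d.normalized}({d.system.value})" for d in c.dx_codes)
        lines.append(f"    {c.service_date} {c.setting.value:<10} {c.claim_id}: {dx}")

    def describe(tag: str, ev: ConditionEvidence | None) -> None:
        if ev is None:
            lines.append(f"  {tag}: not evaluated (no rule, or earlier criterion failed)")
        elif ev.qualified:
            lines.append(
                f"  {tag}: qualified via {ev.path} path on {ev.qualification_date} "
                f"(claims {', '.join(ev.qualifying_claim_ids)})"
            )
        else:
            lines.append(f"  {tag}: not qualified")

    describe("ph", r.ph_evidence)
    if r.index_date:
        lines.append(f"  index_date: {r.index_date}")
    describe("copd", r.copd_evidence)
    describe("ild", r.ild_evidence)
    for h in r.exclusion_reasons:
        lines.append(f"  exclusion {h.codeset}: claims {', '.join(h.claim_ids)}")
    if r.subtype:
        lines.append(f"  subtype: {r.subtype.value}")
    lines.append(f"  status: {r.status.value}")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# config file round-trip

_RULE_KEYS = {
    "codeset", "min_inpatient_claims", "min_outpatient_claims",
    "outpatient_min_separation_days", "outpatient_max_span_days",
    "allowed_positions", "outpatient_settings",
}
_CONFIG_KEYS = {
    "name", "lung_rule", "ild_rule", "ph_rule", "baseline_days",
    "require_enrollment_through_baseline", "min_age_at_index",
    "exclusion_rules", "exclusion_window", "exclusion_post_days",
    "multi_group_mode", "copd_only_mode", "use_i27x_exclusions",
    "sequence_tolerance_days", "index_on", "emergency_as_outpatient",
    "proc_exclusion_prefixes", "notes",
}


def _rule_to_dict(rule: ConditionRule | None) -> dict | None:
    if rule is None:
        return None
    return {
        "codeset": rule.codeset,
        "min_inpatient_claims": rule.min_inpatient_claims,
        "min_outpatient_claims": rule.min_outpatient_claims,
        "outpatient_min_separation_days": rule.outpatient_min_separation_days,
        "outpatient_max_span_days": rule.outpatient_max_span_days,
        "allowed_positions": rule.allowed_positions.value,
        "outpatient_settings": list(rule.outpatient_settings),
    }


def _rule_from_dict(d: dict | None, where: str) -> ConditionRule | None:
    if d is None:
        return None
    unknown = set(d) - _RULE_KEYS
    if unknown:
        raise ConfigError(f"{where}: unknown rule key(s) {sorted(unknown)}")
    d = dict(d)
    if "outpatient_settings" in d:
        d["outpatient_settings"] = tuple(d["outpatient_settings"])
    return ConditionRule(**d)


def config_to_dict(config: AlgorithmConfig) -> dict:
    return {
        "name": config.name,
        "lung_rule": _rule_to_dict(config.lung_rule),
        "ild_rule": _rule_to_dict(config.ild_rule),
        "ph_rule": _rule_to_dict(config.ph_rule),
        "baseline_days": config.baseline_days,
        "require_enrollment_through_baseline": config.require_enrollment_through_baseline,
        "min_age_at_index": config.min_age_at_index,
        "exclusion_rules": [
            {"codeset": r.codeset, "min_claims": r.min_claims}
            for r in config.exclusion_rules
        ],
        "exclusion_window": config.exclusion_window,
        "exclusion_post_days": config.exclusion_post_days,
        "multi_group_mode": config.multi_group_mode,
        "copd_only_mode": config.copd_only_mode,
        "use_i27x_exclusions": config.use_i27x_exclusions,
        "sequence_tolerance_days": config.sequence_tolerance_days,
        "index_on": config.index_on,
        "emergency_as_outpatient": config.emergency_as_outpatient,
        "proc_exclusion_prefixes": list(config.proc_exclusion_prefixes),
        "notes": config.notes,
    }


def config_from_dict(d: Mapping) -> AlgorithmConfig:
    unknown = set(d) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
    kw = dict(d)
    for key in ("lung_rule", "ild_rule", "ph_rule"):
        if key in kw:
            kw[key] = _rule_from_dict(kw[key], key)
            if key == "ph_rule" and kw[key] is None:
                raise ConfigError("ph_rule may not be null")
    if "exclusion_rules" in kw:
        kw["exclusion_rules"] = tuple(
            ExclusionRule(**r) for r in kw["exclusion_rules"]
        )
    if "proc_exclusion_prefixes" in kw:
        kw["proc_exclusion_prefixes"] = tuple(kw["proc_exclusion_prefixes"])
    return AlgorithmConfig(**{k: v for k, v in kw.items() if v is not None or k in
                              ("lung_rule", "ild_rule", "exclusion_post_days")})


def save_config(config: AlgorithmConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8"
    )


def load_config(path: str | Path) -> AlgorithmConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config file must be a mapping")
    return config_from_dict(data)
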