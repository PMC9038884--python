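"""Seeded, labeled synthetic-claims generator.

Real claims extracts for this phenotype are proprietary, so validation runs
on simulated multi-year claim histories.  The generator is deliberately a
*clean-skeleton-then-corrupt* design: each stratum first emits a claim
history that satisfies (or violates, per its label) the recommended
algorithm's criteria exactly, and noise is applied afterwards, so every
patient keeps an interpretable ground-truth label.  It emulates diagnosis
coding across the ICD-9-CM -> ICD-10-CM transition (2015-10-01), care
settings, and diagnosis positions; it does not attempt realistic
utilization intensity, comorbidity correlation, or calibrated prevalence.

Strata and their intended status under the recommended configuration:

========================  ============================
g3_copd / g3_ild / g3_both  included (copd_ph / ild_ph / copd_and_ild_ph)
group2_ph / group4_ph       excluded_other_group
multi_group_overlap         excluded_other_group
ph_before_lung              excluded_sequence
ph_no_lung                  excluded_no_lung_disease
lung_no_ph / clean_negative not_ph
========================  ============================
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .claims import (
    Claim,
    EnrollmentSpan,
    ICD10_TRANSITION,
    Patient,
    Setting,
    write_claims,
    write_enrollment,
)
from .codesets import CodeSet, CodeSetRegistry, CodingSystem, DxCode, default_registry
from .engine import Status

STRATA = (
    "g3_copd", "g3_ild", "g3_both", "group2_ph", "group4_ph",
    "lung_no_ph", "ph_no_lung", "ph_before_lung", "multi_group_overlap",
    "clean_negative",
)

EXPECTED_STATUS = {
    "g3_copd": Status.INCLUDED,
    "g3_ild": Status.INCLUDED,
    "g3_both": Status.INCLUDED,
    "group2_ph": Status.EXCLUDED_OTHER_GROUP,
    "group4_ph": Status.EXCLUDED_OTHER_GROUP,
    "multi_group_overlap": Status.EXCLUDED_OTHER_GROUP,
    "ph_before_lung": Status.EXCLUDED_SEQUENCE,
    "ph_no_lung": Status.EXCLUDED_NO_LUNG_DISEASE,
    "lung_no_ph": Status.NOT_PH,
    "clean_negative": Status.NOT_PH,
}

# benign filler codes; members of no built-in set
_BENIGN = {
    CodingSystem.ICD9CM: ("401.9", "250.00", "530.81"),
    CodingSystem.ICD10CM: ("I10", "E11.9", "K21.9"),
}


class SimulationSpecError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Per-patient corruption probabilities applied after the clean skeleton."""

    p_drop_confirmatory_claim: float = 0.0
    p_stray_exclusion_code: float = 0.0
    p_position_demotion: float = 0.0
    p_era_mismatch: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_drop_confirmatory_claim", "p_stray_exclusion_code",
            "p_position_demotion", "p_era_mismatch",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationSpecError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class StratumSpec:
    label: str
    n_patients: int
    era: str = "mixed"  # icd9 | icd10 | mixed
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.label not in STRATA:
            raise SimulationSpecError(
                f"unknown stratum {self.label!r}; known: {STRATA}"
            )
        if self.n_patients < 0:
            raise SimulationSpecError("n_patients must be >= 0")
        if self.era not in ("icd9", "icd10", "mixed"):
            raise SimulationSpecError(f"unknown era {self.era!r}")


@dataclass(frozen=True)
class TruthLabel:
    patient_id: str
    stratum: str
    expected_status: Status


# spacing the skeletons need around the index date (days)
_PRE_SPAN = 365   # lung-disease claims live inside this lookback
_POST_SPAN = 150  # confirmatory PH claim lives inside this follow-up


def _date_range_days(start: dt.date, end: dt.date) -> int:
    return (end - start).days


def _draw_day(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    """Uniform calendar day in [lo, hi]."""
    span = _date_range_days(lo, hi)
    return lo + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _system_for(date: dt.date, mismatch: bool) -> CodingSystem:
    natural = CodingSystem.ICD9CM if date < ICD10_TRANSITION else CodingSystem.ICD10CM
    if not mismatch:
        return natural
    return (
        CodingSystem.ICD10CM if natural is CodingSystem.ICD9CM else CodingSystem.ICD9CM
    )


def _draw_code(
    rng: np.random.Generator,
    codeset: CodeSet,
    date: dt.date,
    *,
    mismatch: bool = False,
    exclude_prefix: str | None = None,
) -> DxCode:
    system = _system_for(date, mismatch)
    pool = [
        e.pattern for e in codeset.entries
        if e.system is system
        and (exclude_prefix is None or not e.pattern.startswith(exclude_prefix))
    ]
    if not pool:  # set is single-system; fall back to the other era
        system = (
            CodingSystem.ICD9CM if system is CodingSystem.ICD10CM
            else CodingSystem.ICD10CM
        )
        pool = [
            e.pattern for e in codeset.entries
            if e.system is system
            and (exclude_prefix is None or not e.pattern.startswith(exclude_prefix))
        ]
    return DxCode(pool[int(rng.integers(0, len(pool)))], system)


def _benign(rng: np.random.Generator, date: dt.date) -> DxCode:
    system = _system_for(date, False)
    pool = _BENIGN[system]
    return DxCode(pool[int(rng.integers(0, len(pool)))], system)


class _PatientBuilder:
    """Accumulates one synthetic patient's claims with deterministic ids."""

    def __init__(self, rng: np.random.Generator, patient_id: str, noise: NoiseSpec):
        self.rng = rng
        self.patient_id = patient_id
        self.noise = noise
        self.claims: list[Claim] = []
        self._n = 0

    def add(
        self,
        date: dt.date,
        setting: Setting,
        codeset: CodeSet | None,
        *,
        demotable: bool = True,
        exclude_prefix: str | None = None,
    ) -> Claim:
        self._n += 1
        rng = self.rng
        if codeset is None:
            target = _benign(rng, date)
        else:
            mismatch = rng.random() < self.noise.p_era_mismatch
            target = _draw_code(
                rng, codeset, date, mismatch=mismatch, exclude_prefix=exclude_prefix
            )
        if codeset is not None and demotable and rng.random() < self.noise.p_position_demotion:
            dx = (_benign(rng, date), _benign(rng, date), target)  # position 3
        elif rng.random() < 0.5:
            dx = (target, _benign(rng, date))
        else:
            dx = (target,)
        claim = Claim(
            patient_id=self.patient_id,
            claim_id=f"{self.patient_id}-C{self._n:03d}",
            service_date=date,
            setting=setting,
            dx_codes=dx,
        )
        self.claims.append(claim)
        return claim


def _era_bounds(
    era: str, window: tuple[dt.date, dt.date]
) -> tuple[dt.date, dt.date]:
    """Feasible index-date range for a stratum era inside *window*."""
    lo = window[0] + dt.timedelta(days=_PRE_SPAN)
    hi = window[1] - dt.timedelta(days=_POST_SPAN)
    if era == "icd9":
        hi = min(hi, ICD10_TRANSITION - dt.timedelta(days=_POST_SPAN + 1))
    elif era == "icd10":
        lo = max(lo, ICD10_TRANSITION + dt.timedelta(days=_PRE_SPAN))
    if lo > hi:
        raise SimulationSpecError(
            f"date window {window[0]}..{window[1]} too short for era {era!r}: "
            f"needs {_PRE_SPAN} days of lookback and {_POST_SPAN} of follow-up"
        )
    return lo, hi


def _simulate_patient(
    rng: np.random.Generator,
    pid: str,
    stratum: StratumSpec,
    window: tuple[dt.date, dt.date],
    registry: CodeSetRegistry,
) -> list[Claim]:
    b = _PatientBuilder(rng, pid, stratum.noise)
    lo, hi = _era_bounds(stratum.era, window)
    index = _draw_day(rng, lo, hi)
    label = stratum.label

    def lung_pair(codeset_name: str, around: dt.date) -> None:
        # two outpatient claims >=1 day apart inside the lookback window
        d1 = _draw_day(rng, around - dt.timedelta(days=_PRE_SPAN),
                       around - dt.timedelta(days=40))
        d2 = _draw_day(rng, d1 + dt.timedelta(days=1),
                       around - dt.timedelta(days=10))
        cs = registry[codeset_name]
        b.add(d1, Setting.OUTPATIENT, cs)
        b.add(d2, Setting.OUTPATIENT, cs)

    def ph_pair(first: dt.date, confirm: bool = True) -> None:
        ph = registry["ph"]
        b.add(first, Setting.OUTPATIENT, ph, demotable=False)
        if confirm and not (rng.random() < stratum.noise.p_drop_confirmatory_claim):
            gap = int(rng.integers(30, 121))
            b.add(first + dt.timedelta(days=gap), Setting.OUTPATIENT, ph,
                  demotable=False)

    def stray_exclusion() -> None:
        if rng.random() < stratum.noise.p_stray_exclusion_code:
            group = ("excl_group1", "excl_group2", "excl_group4", "excl_group5")[
                int(rng.integers(0, 4))
            ]
            d = _draw_day(rng, index - dt.timedelta(days=_PRE_SPAN),
                          index - dt.timedelta(days=1))
            b.add(d, Setting.OUTPATIENT, registry[group], exclude_prefix="I27")

    if label == "g3_copd":
        lung_pair("copd", index)
        ph_pair(index)
    elif label == "g3_ild":
        lung_pair("ild", index)
        ph_pair(index)
    elif label == "g3_both":
        lung_pair("copd", index)
        lung_pair("ild", index)
        ph_pair(index)
    elif label in ("group2_ph", "group4_ph", "multi_group_overlap"):
        lung_pair("copd", index)
        ph_pair(index)
        groups = {"group2_ph": ("excl_group2",), "group4_ph": ("excl_group4",),
                  "multi_group_overlap": ("excl_group2", "excl_group4")}[label]
        for gname in groups:
            d = _draw_day(rng, index - dt.timedelta(days=300),
                          index - dt.timedelta(days=1))
            b.add(d, Setting.OUTPATIENT, registry[gname], demotable=False,
                  exclude_prefix="I27")
    elif label == "ph_before_lung":
        ph_pair(index)
        # lung disease only after the index -> sequence violation
        d1 = _draw_day(rng, index + dt.timedelta(days=1),
                       index + dt.timedelta(days=60))
        d2 = _draw_day(rng, d1 + dt.timedelta(days=1),
                       index + dt.timedelta(days=120))
        cs = registry["copd"]
        b.add(d1, Setting.OUTPATIENT, cs)
        b.add(d2, Setting.OUTPATIENT, cs)
    elif label == "ph_no_lung":
        ph_pair(index)
    elif label == "lung_no_ph":
        lung_pair("copd", index)
    elif label == "clean_negative":
        for _ in range(int(rng.integers(1, 4))):
            d = _draw_day(rng, index - dt.timedelta(days=_PRE_SPAN), index)
            b.add(d, Setting.OUTPATIENT, None)
    else:  # pragma: no cover - guarded by StratumSpec
        raise SimulationSpecError(f"unhandled stratum {label!r}")

    if label != "clean_negative":
        stray_exclusion()
    return b.claims


def simulate_population(
    spec: Sequence[StratumSpec],
    *,
    seed: int,
    date_window: tuple[dt.date, dt.date] = (dt.date(2013, 1, 1), dt.date(2018, 12, 31)),
    registry: CodeSetRegistry | None = None,
) -> tuple[list[Claim], list[Patient], list[TruthLabel]]:
    """Generate a labeled corpus; fully reproducible for a given (spec, seed)."""
    if registry is None:
        registry = default_registry()
    if date_window[1] <= date_window[0]:
        raise SimulationSpecError("empty date window")
    rng = np.random.default_rng(seed)
    claims: list[Claim] = []
    patients: list[Patient] = []
    labels: list[TruthLabel] = []
    counter = 0
    for stratum in spec:
        _era_bounds(stratum.era, date_window)  # validate before generating
        for _ in range(stratum.n_patients):
            counter += 1
            pid = f"P{counter:06d}"
            claims.extend(_simulate_patient(rng, pid, stratum, date_window, registry))
            birth_year = int(rng.integers(1935, 1971))
            patients.append(
                Patient(
                    pid, birth_year,
                    (EnrollmentSpan(pid, date_window[0], date_window[1]),),
                )
            )
            labels.append(TruthLabel(pid, stratum.label, EXPECTED_STATUS[stratum.label]))
    claims.sort(key=lambda c: (c.patient_id, c.service_date, c.claim_id))
    return claims, patients, labels


def write_truth(labels: Sequence[TruthLabel], path: str | Path) -> None:
    lines = ["patient_id,stratum,expected_status"]
    for t in sorted(labels, key=lambda t: t.patient_id):
        lines.append(f"{t.patient_id},{t.stratum},{t.expected_status.value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_truth(path: str | Path) -> list[TruthLabel]:
    labels = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header != ["patient_id", "stratum", "expected_status"]:
            raise SimulationSpecError(f"{path}: unexpected truth-file header {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, stratum, status = line.strip().split(",")
            labels.append(TruthLabel(pid, stratum, Status(status)))
    return labels


def write_population(
    out_dir: str | Path,
    claims: Sequence[Claim],
    patients: Sequence[Patient],
    labels: Sequence[TruthLabel],
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": out / "claims.csv",
        "enrollment": out / "enrollment.csv",
        "truth": out / "truth.csv",
    }
    write_claims(claims, paths["claims"])
    write_enrollment(patients, paths["enrollment"])
    write_truth(labels, paths["truth"])
    return paths


# --------------------------------------------------------------------------
# hand-specified single-patient micro-fixtures

FIXTURE_TAGS = (
    "ph_29day_gap", "ph_30day_gap", "baseline_boundary", "index_day_excl",
    "post_index_lung", "heresi_span_cap", "wu_copd_count",
    "medrek_primary_position", "hemnes_lung_separation", "sequence_reversed",
)


def make_fixture(tag: str) -> tuple[list[Claim], list[Patient]]:
    """Deterministic one-patient claim histories for boundary-condition
    tests (non-random by design)."""
    pid = "FX"
    D = dt.date
    I9, I10 = CodingSystem.ICD9CM, CodingSystem.ICD10CM

    def claim(cid, date, setting, *codes) -> Claim:
        system = I9 if date < ICD10_TRANSITION else I10
        return Claim(pid, cid, date, setting, tuple(DxCode(c, system) for c in codes))

    patient = Patient(pid, 1950, (EnrollmentSpan(pid, D(2012, 1, 1), D(2019, 12, 31)),))
    out = Setting.OUTPATIENT
    inp = Setting.INPATIENT

    if tag == "ph_29day_gap":
        claims = [
            claim("L1", D(2016, 1, 10), out, "J44.9"),
            claim("L2", D(2016, 3, 10), out, "J44.1"),
            claim("P1", D(2016, 6, 1), out, "I27.23"),
            claim("P2", D(2016, 6, 30), out, "I27.23"),  # 29 days later
        ]
    elif tag == "ph_30day_gap":
        claims = [
            claim("L1", D(2016, 1, 10), out, "J44.9"),
            claim("L2", D(2016, 3, 10), out, "J44.1"),
            claim("P1", D(2016, 6, 1), out, "I27.23"),
            claim("P2", D(2016, 7, 1), out, "I27.23"),  # exactly 30 days
        ]
    elif tag == "baseline_boundary":
        # earliest COPD claim exactly baseline_days=365 before the index
        claims = [
            claim("L1", D(2016, 6, 1), out, "J44.9"),  # index - 365
            claim("L2", D(2016, 7, 1), out, "J44.9"),
            claim("P1", D(2017, 6, 1), out, "I27.23"),
            claim("P2", D(2017, 7, 10), out, "I27.21"),
        ]
    elif tag == "index_day_excl":
        claims = [
            claim("L1", D(2016, 1, 10), out, "J44.9"),
            claim("L2", D(2016, 3, 10), out, "J44.1"),
            claim("P1", D(2016, 6, 1), out, "I27.23"),
            claim("X1", D(2016, 6, 1), out, "I50.3"),   # same-day workup code
            claim("P2", D(2016, 7, 15), out, "I27.23"),
        ]
    elif tag == "post_index_lung":
        # only lung-disease claims are ~30 days AFTER the PH index
        claims = [
            claim("P1", D(2014, 6, 1), out, "416.0"),
            claim("P2", D(2014, 7, 15), out, "416.8"),
            claim("L1", D(2014, 7, 1), out, "491.21"),
            claim("L2", D(2014, 7, 20), out, "496"),
        ]
    elif tag == "heresi_span_cap":
        # two PH claims 13 months apart: fine without a span cap,
        # fails a 12-month first-to-last cap
        claims = [
            claim("L1", D(2013, 6, 1), out, "491.21"),
            claim("L2", D(2013, 8, 1), out, "496"),
            claim("P1", D(2014, 1, 15), out, "416.0"),
            claim("P2", D(2015, 3, 1), out, "416.8"),  # 410 days later
        ]
    elif tag == "wu_copd_count":
        # two outpatient COPD claims: enough for the consensus rule,
        # one short of a three-outpatient-claim requirement
        claims = [
            claim("L1", D(2014, 1, 10), out, "491.21"),
            claim("L2", D(2014, 5, 10), out, "496"),
            claim("P1", D(2014, 10, 1), inp, "416.0"),
            claim("P2", D(2014, 12, 1), out, "416.8"),
            claim("P3", D(2015, 2, 1), out, "416.8"),
            claim("P4", D(2015, 4, 1), out, "416.9"),
        ]
    elif tag == "medrek_primary_position":
        # COPD only ever in the secondary position
        claims = [
            claim("L1", D(2014, 1, 10), out, "401.9", "491.21"),
            claim("L2", D(2014, 5, 10), out, "401.9", "496"),
            claim("P1", D(2014, 10, 1), inp, "416.0"),
            claim("P2", D(2014, 12, 1), out, "416.8"),
        ]
    elif tag == "hemnes_lung_separation":
        # two COPD claims 10 days apart: >=1-day separation passes,
        # >=30-day separation fails
        claims = [
            claim("L1", D(2016, 3, 1), out, "J44.9"),
            claim("L2", D(2016, 3, 11), out, "J44.1"),
            claim("P1", D(2016, 8, 1), out, "I27.23"),
            claim("P2", D(2016, 9, 15), out, "I27.23"),
        ]
    elif tag == "sequence_reversed":
        claims = [
            claim("P1", D(2015, 1, 5), out, "416.0"),
            claim("P2", D(2015, 3, 1), out, "416.8"),
            claim("L1", D(2016, 1, 10), out, "J44.9"),
            claim("L2", D(2016, 3, 10), out, "J44.1"),
        ]
    else:
        raise KeyError(f"unknown fixture tag {tag!r}; known: {FIXTURE_TAGS}")
    return claims, [patient]
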