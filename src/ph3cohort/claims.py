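"""Claims and enrollment data model with validated CSV readers/writers.

Two claim-file dialects are supported:

* ``long`` (canonical): one row per diagnosis, columns
  ``patient_id, claim_id, service_date, setting, dx_position, dx_code,
  dx_system, proc_code`` (last two optional).  Rows sharing a
  (patient_id, claim_id) pair form one claim; procedure-only rows may leave
  the dx fields empty.
* ``wide``: one row per claim with ``dx1..dxN`` columns.

When a row carries no explicit coding-system tag, the system is inferred
from the service date against the ICD-9 -> ICD-10-CM transition date
(2015-10-01 by default) and a warning is logged.  All window arithmetic in
this package is in whole calendar days; claims carry dates, not times.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .codesets import CodingSystem, DxCode, InvalidCodeError, normalize_code

log = logging.getLogger(__name__)

#: First service date coded in ICD-10-CM in US claims.
ICD10_TRANSITION = dt.date(2015, 10, 1)


class Setting(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    EMERGENCY = "emergency"


class ClaimsFileError(ValueError):
    """Schema or row-level failure while reading a claims/enrollment file."""


@dataclass(frozen=True)
class Claim:
    """One billed encounter line: ordered dx codes, 1-based positions."""

    patient_id: str
    claim_id: str
    service_date: dt.date
    setting: Setting
    dx_codes: tuple[DxCode, ...]
    proc_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "setting", Setting(self.setting))
        if not self.dx_codes and not self.proc_codes:
            raise ClaimsFileError(
                f"claim {self.claim_id!r}: no diagnosis or procedure codes"
            )

    def dx_at(self, position: int) -> DxCode | None:
        """Diagnosis at 1-based *position*, or None."""
        if 1 <= position <= len(self.dx_codes):
            return self.dx_codes[position - 1]
        return None


@dataclass(frozen=True)
class EnrollmentSpan:
    patient_id: str
    start_date: dt.date
    end_date: dt.date  # inclusive

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ClaimsFileError(
                f"enrollment span for {self.patient_id!r}: end "
                f"{self.end_date} before start {self.start_date}"
            )

    def covers(self, start: dt.date, end: dt.date) -> bool:
        return self.start_date <= start and end <= self.end_date

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day <= self.end_date


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_year: int
    enrollment: tuple[EnrollmentSpan, ...] = ()

    def age_at(self, day: dt.date) -> int:
        """Age in whole years; only birth year is known, so year arithmetic."""
        return day.year - self.birth_year

    def enrolled_through(self, start: dt.date, end: dt.date) -> bool:
        return any(s.covers(start, end) for s in self.enrollment)


def merge_spans(spans: Iterable[EnrollmentSpan]) -> tuple[EnrollmentSpan, ...]:
    """Merge overlapping or adjacent (gap <= 1 day) spans per patient.

    Idempotent and order-independent; result sorted by start date.
    """
    by_patient: dict[str, list[EnrollmentSpan]] = {}
    for s in spans:
        by_patient.setdefault(s.patient_id, []).append(s)
    out: list[EnrollmentSpan] = []
    for pid in sorted(by_patient):
        merged: list[EnrollmentSpan] = []
        for s in sorted(by_patient[pid], key=lambda x: (x.start_date, x.end_date)):
            if merged and s.start_date <= merged[-1].end_date + dt.timedelta(days=1):
                if s.end_date > merged[-1].end_date:
                    merged[-1] = replace(merged[-1], end_date=s.end_date)
            else:
                merged.append(s)
        out.extend(merged)
    return tuple(out)


def _parse_date(value, *, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise ClaimsFileError(f"{where}: unparseable ISO date {value!r}") from None


def infer_system(service_date: dt.date, transition: dt.date = ICD10_TRANSITION) -> CodingSystem:
    return CodingSystem.ICD9CM if service_date < transition else CodingSystem.ICD10CM


def _row_system(raw_system, service_date: dt.date, transition: dt.date, warned: list[bool]) -> CodingSystem:
    if raw_system is not None and str(raw_system).strip():
        return CodingSystem(str(raw_system).strip())
    if not warned[0]:
        log.warning(
            "claims file has no dx_system column/values; inferring coding "
            "system from service_date vs transition %s", transition
        )
        warned[0] = True
    return infer_system(service_date, transition)


def read_claims(
    path: str | Path,
    dialect: str = "long",
    *,
    transition_date: dt.date = ICD10_TRANSITION,
    max_row_errors: int = 0,
) -> list[Claim]:
    """Read a claims CSV; returns claims sorted (patient_id, date, claim_id).

    Row-level errors are collected; if more than *max_row_errors* occur the
    read aborts with a report listing the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "long":
        required = {"patient_id", "claim_id", "service_date", "setting", "dx_position", "dx_code"}
    elif dialect == "wide":
        required = {"patient_id", "claim_id", "service_date", "setting", "dx1"}
    else:
        raise ClaimsFileError(f"unknown claims dialect {dialect!r}")
    missing = required - set(df.columns)
    if missing:
        raise ClaimsFileError(f"{path}: missing required column(s) {sorted(missing)}")

    errors: list[str] = []
    warned = [False]
    # key -> (patient_id, date, setting, {position: DxCode}, [proc])
    grouped: dict[tuple[str, str], dict] = {}

    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            date = _parse_date(rec["service_date"], where=f"{path}:{idx}")
            try:
                setting = Setting(rec["setting"].strip().lower())
            except ValueError:
                raise ClaimsFileError(
                    f"{path}:{idx}: unknown setting {rec['setting']!r}"
                ) from None
            key = (rec["patient_id"], rec["claim_id"])
            entry = grouped.setdefault(
                key, {"date": date, "setting": setting, "dx": {}, "proc": []}
            )
            if dialect == "long":
                code = rec["dx_code"].strip()
                proc = rec.get("proc_code", "").strip()
                if code:
                    pos = int(rec["dx_position"])
                    system = _row_system(rec.get("dx_system"), date, transition_date, warned)
                    entry["dx"][pos] = DxCode(code, system)
                if proc:
                    entry["proc"].append(normalize_code(proc))
            else:
                system = _row_system(rec.get("dx_system"), date, transition_date, warned)
                pos = 0
                for col in df.columns:
                    if col.startswith("dx") and col[2:].isdigit():
                        code = rec[col].strip()
                        if code:
                            pos = int(col[2:])
                            entry["dx"][pos] = DxCode(code, system)
                for proc in rec.get("proc_codes", "").split(";"):
                    if proc.strip():
                        entry["proc"].append(normalize_code(proc))
        except (ClaimsFileError, InvalidCodeError, ValueError) as exc:
            errors.append(str(exc) if str(exc).startswith(str(path)) else f"{path}:{idx}: {exc}")
            if len(errors) > max_row_errors:
                raise ClaimsFileError(
                    f"{path}: {len(errors)} row error(s), aborting:\n  "
                    + "\n  ".join(errors)
                )

    claims = []
    for (pid, cid), entry in grouped.items():
        dx = tuple(entry["dx"][p] for p in sorted(entry["dx"]))
        claims.append(
            Claim(pid, cid, entry["date"], entry["setting"], dx, tuple(entry["proc"]))
        )
    claims.sort(key=lambda c: (c.patient_id, c.service_date, c.claim_id))
    return claims


def write_claims(claims: Sequence[Claim], path: str | Path) -> None:
    """Write the canonical long dialect; round-trips with read_claims."""
    rows = []
    for c in sorted(claims, key=lambda c: (c.patient_id, c.service_date, c.claim_id)):
        for pos, dx in enumerate(c.dx_codes, start=1):
            rows.append(
                (c.patient_id, c.claim_id, c.service_date.isoformat(),
                 c.setting.value, pos, dx.normalized, dx.system.value, "")
            )
        for proc in c.proc_codes:
            rows.append(
                (c.patient_id, c.claim_id, c.service_date.isoformat(),
                 c.setting.value, "", "", "", proc)
            )
    header = "patient_id,claim_id,service_date,setting,dx_position,dx_code,dx_system,proc_code"
    lines = [header] + [",".join(str(v) for v in r) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_enrollment(path: str | Path) -> list[Patient]:
    """Read patient/enrollment CSV (patient_id, birth_year, start_date,
    end_date); per-patient spans merged; deterministic order."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "birth_year", "start_date", "end_date"}
    missing = required - set(df.columns)
    if missing:
        raise ClaimsFileError(f"{path}: missing required column(s) {sorted(missing)}")
    spans: list[EnrollmentSpan] = []
    birth: dict[str, int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        pid = rec["patient_id"]
        start = _parse_date(rec["start_date"], where=f"{path}:{idx}")
        end = _parse_date(rec["end_date"], where=f"{path}:{idx}")
        try:
            spans.append(EnrollmentSpan(pid, start, end))
        except ClaimsFileError as exc:
            raise ClaimsFileError(f"{path}:{idx}: {exc}") from None
        by = int(rec["birth_year"])
        if birth.setdefault(pid, by) != by:
            raise ClaimsFileError(f"{path}:{idx}: conflicting birth_year for {pid!r}")
    merged = merge_spans(spans)
    patients = []
    for pid in sorted(birth):
        patients.append(
            Patient(pid, birth[pid], tuple(s for s in merged if s.patient_id == pid))
        )
    return patients


def write_enrollment(patients: Sequence[Patient], path: str | Path) -> None:
    lines = ["patient_id,birth_year,start_date,end_date"]
    for p in sorted(patients, key=lambda p: p.patient_id):
        for s in p.enrollment:
            lines.append(
                f"{p.patient_id},{p.birth_year},{s.start_date.isoformat()},{s.end_date.isoformat()}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class ValidationReport:
    """Per-issue-class counts with offending claim/patient ids.

    Reporting only: nothing is dropped."""

    out_of_enrollment: list[str] = field(default_factory=list)
    before_birth: list[str] = field(default_factory=list)
    era_mismatch: list[str] = field(default_factory=list)
    orphan_patient: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "out_of_enrollment": len(self.out_of_enrollment),
            "before_birth": len(self.before_birth),
            "era_mismatch": len(self.era_mismatch),
            "orphan_patient": len(self.orphan_patient),
        }

    @property
    def clean(self) -> bool:
        return all(v == 0 for v in self.counts().values())


def validate_claims(
    claims: Sequence[Claim],
    patients: Sequence[Patient],
    *,
    transition_date: dt.date = ICD10_TRANSITION,
) -> ValidationReport:
    """Flag claims outside enrollment, before birth, wrong-era codes, and
    claim rows whose patient has no enrollment record."""
    report = ValidationReport()
    by_id = {p.patient_id: p for p in patients}
    orphans: set[str] = set()
    for c in claims:
        p = by_id.get(c.patient_id)
        if p is None:
            orphans.add(c.patient_id)
            continue
        if not any(s.contains(c.service_date) for s in p.enrollment):
            report.out_of_enrollment.append(c.claim_id)
        if c.service_date.year < p.birth_year:
            report.before_birth.append(c.claim_id)
        expected = infer_system(c.service_date, transition_date)
        if any(dx.system is not expected for dx in c.dx_codes):
            report.era_mismatch.append(c.claim_id)
    report.orphan_patient = sorted(orphans)
    return report
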