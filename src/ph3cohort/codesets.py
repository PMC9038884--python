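"""Diagnosis code sets: normalization, matching, registry I/O.

Claims feeds disagree about dots and case ("J84.112" vs "j84112"); every
code is therefore normalized (uppercase, dot stripped, no zero padding) both
at registry construction and at claim ingest, so matching is a pure string
comparison.  Each code-set entry carries an explicit match mode: ``exact``
for fully specified codes and ``prefix`` for whole-family wildcards.

Matching is system-isolated: an ICD-9-CM code can only match ICD-9-CM
entries, an ICD-10-CM code only ICD-10-CM entries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from . import _table_codes


class CodingSystem(str, Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


class MatchMode(str, Enum):
    EXACT = "exact"
    PREFIX = "prefix"


class InvalidCodeError(ValueError):
    """Raised for empty/whitespace code strings or unknown system tags."""


class CodesetError(ValueError):
    """Registry/code-set construction or parse failure."""


class DuplicateEntryError(CodesetError):
    pass


class UnknownCodesetError(KeyError):
    pass


def normalize_code(raw: str, system: CodingSystem | str | None = None) -> str:
    """Canonicalize a diagnosis code: strip whitespace and dots, uppercase.

    No zero padding is applied (ICD-9-CM "496" stays three characters;
    padding would corrupt V/E codes).  Idempotent.
    """
    if raw is None:
        raise InvalidCodeError("code is None")
    stripped = str(raw).strip()
    if not stripped:
        raise InvalidCodeError("empty or whitespace-only code")
    return stripped.replace(".", "").upper()


def _coerce_system(system: CodingSystem | str) -> CodingSystem:
    try:
        return CodingSystem(system)
    except ValueError:
        raise InvalidCodeError(
            f"unknown coding system {system!r}; expected one of "
            f"{[s.value for s in CodingSystem]}"
        ) from None


@dataclass(frozen=True, eq=False)
class DxCode:
    """A diagnosis code as recorded on a claim, with its canonical form.

    Equality and hashing use (system, normalized): "J84.112" and "j84112"
    are the same code."""

    raw: str
    system: CodingSystem
    normalized: str = ""

    def __eq__(self, other) -> bool:
        if not isinstance(other, DxCode):
            return NotImplemented
        return self.system is other.system and self.normalized == other.normalized

    def __hash__(self) -> int:
        return hash((self.system, self.normalized))

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", _coerce_system(self.system))
        norm = normalize_code(self.raw, self.system)
        if self.normalized and self.normalized != norm:
            raise InvalidCodeError(
                f"normalized form {self.normalized!r} inconsistent with raw {self.raw!r}"
            )
        object.__setattr__(self, "normalized", norm)


@dataclass(frozen=True)
class CodeSetEntry:
    system: CodingSystem
    pattern: str  # stored normalized
    match_mode: MatchMode
    description: str = ""

    def matches(self, code: DxCode) -> bool:
        if code.system is not self.system:
            return False
        if self.match_mode is MatchMode.EXACT:
            return code.normalized == self.pattern
        return code.normalized.startswith(self.pattern)


@dataclass(frozen=True)
class CodeSet:
    """A named collection of diagnosis codes with per-entry match semantics."""

    name: str
    entries: tuple[CodeSetEntry, ...]
    description: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[CodingSystem, str]] = set()
        for e in self.entries:
            key = (e.system, e.pattern)
            if key in seen:
                raise DuplicateEntryError(
                    f"code set {self.name!r}: duplicate entry "
                    f"({e.system.value}, {e.pattern})"
                )
            seen.add(key)

    @classmethod
    def build(
        cls,
        name: str,
        entries: Iterable[tuple[str, str, str] | tuple[str, str, str, str]],
        description: str = "",
    ) -> "CodeSet":
        """Build from (system, pattern, mode[, description]) tuples; patterns
        are normalized here."""
        built = []
        for row in entries:
            system, pattern, mode = row[0], row[1], row[2]
            desc = row[3] if len(row) > 3 else ""
            try:
                mm = MatchMode(mode)
            except ValueError:
                raise CodesetError(
                    f"code set {name!r}: unknown match_mode {mode!r}"
                ) from None
            built.append(
                CodeSetEntry(_coerce_system(system), normalize_code(pattern), mm, desc)
            )
        return cls(name=name, entries=tuple(built), description=description)

    def matches(self, code: DxCode) -> bool:
        return any(e.matches(code) for e in self.entries)

    def restricted(self, keep) -> "CodeSet":
        """A copy keeping only entries for which ``keep(entry)`` is true."""
        return CodeSet(
            name=self.name,
            entries=tuple(e for e in self.entries if keep(e)),
            description=self.description,
        )


def code_matches(code: DxCode, codeset: CodeSet) -> bool:
    """True iff some entry of the code's own coding system matches it."""
    return codeset.matches(code)


@dataclass
class CodeSetRegistry:
    """Mapping of set name -> CodeSet, with a version tag for manifests."""

    sets: dict[str, CodeSet] = field(default_factory=dict)
    version: str = "custom"
    provenance: str = ""

    def __getitem__(self, name: str) -> CodeSet:
        try:
            return self.sets[name]
        except KeyError:
            raise UnknownCodesetError(
                f"no code set named {name!r}; available: {sorted(self.sets)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.sets))

    def names(self) -> list[str]:
        return sorted(self.sets)

    def matching_sets(self, code: DxCode, names: Iterable[str] | None = None) -> list[str]:
        """Names of the registered sets (optionally restricted) matching *code*."""
        pool = self.names() if names is None else list(names)
        return [n for n in pool if self[n].matches(code)]

    def add(self, codeset: CodeSet, replace: bool = False) -> None:
        if codeset.name in self.sets and not replace:
            raise CodesetError(f"code set {codeset.name!r} already registered")
        self.sets[codeset.name] = codeset

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name, system, pattern, mode, _ in self._sorted_rows():
            h.update(f"{name}|{system}|{pattern}|{mode}\n".encode())
        return h.hexdigest()[:16]

    def _sorted_rows(self) -> list[tuple[str, str, str, str, str]]:
        rows = []
        for name in sorted(self.sets):
            for e in self.sets[name].entries:
                rows.append((name, e.system.value, e.pattern, e.match_mode.value, e.description))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        return rows

    def export(self, path: str | Path) -> None:
        """Write the delimited registry format, deterministically sorted."""
        lines = ["set_name,system,code,match_mode,description"]
        for name, system, pattern, mode, desc in self._sorted_rows():
            desc = desc.replace(",", ";")
            lines.append(f"{name},{system},{pattern},{mode},{desc}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_codeset_registry(path: str | Path) -> CodeSetRegistry:
    """Load a registry from the delimited code-set format.

    Columns: set_name, system, code, match_mode, description (optional);
    '#' starts a comment line.  Patterns are normalized on load; duplicate
    (system, pattern) pairs within a set are rejected with the line number.
    """
    path = Path(path)
    by_set: dict[str, list[tuple[str, str, str, str]]] = {}
    seen: dict[str, set[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("set_name"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 4:
                raise CodesetError(
                    f"{path}:{lineno}: expected at least 4 columns "
                    "(set_name,system,code,match_mode)"
                )
            name, system, code, mode = parts[:4]
            desc = parts[4] if len(parts) > 4 else ""
            if mode not in (m.value for m in MatchMode):
                raise CodesetError(f"{path}:{lineno}: unknown match_mode {mode!r}")
            try:
                norm = normalize_code(code)
                _coerce_system(system)
            except InvalidCodeError as exc:
                raise CodesetError(f"{path}:{lineno}: {exc}") from None
            key = (system, norm)
            if key in seen.setdefault(name, set()):
                raise DuplicateEntryError(
                    f"{path}:{lineno}: duplicate entry ({system}, {code}) in set {name!r}"
                )
            seen[name].add(key)
            by_set.setdefault(name, []).append((system, code, mode, desc))
    reg = CodeSetRegistry(version=f"file:{path.name}", provenance=str(path))
    for name, rows in by_set.items():
        reg.add(CodeSet.build(name, rows))
    return reg


#: Names of the canonical built-in sets (the consensus code tables).
CANONICAL_SET_NAMES = tuple(_table_codes.CANONICAL_SETS)


def default_registry(variant: str = "default") -> CodeSetRegistry:
    """The built-in registry of consensus code sets for this phenotype.

    ``variant="default"`` stores three-character category parents in the PH
    set ("416", "I27") as exact entries, so the five-digit I27 children that
    designate other PH groups (I27.22, I27.24, I27.82) stay confined to the
    exclusion sets.  ``variant="broad"`` promotes those parents to prefix
    entries for sensitivity analyses.
    """
    if variant not in ("default", "broad"):
        raise CodesetError(f"unknown registry variant {variant!r}")
    reg = CodeSetRegistry(
        version=f"{_table_codes.REGISTRY_VERSION}-{variant}",
        provenance="built-in consensus code sets for Group 3 PH claims phenotyping",
    )
    for name, (entries, desc) in _table_codes.CANONICAL_SETS.items():
        rows = list(entries)
        if variant == "broad":
            rows = [
                (sys_, pat, _table_codes.P if pat.replace(".", "") in ("416", "I27") else mode)
                for sys_, pat, mode in rows
            ]
        reg.add(CodeSet.build(name, rows, description=desc))
    for name, entries in _table_codes.PRESET_SETS.items():
        reg.add(CodeSet.build(name, entries, description="study-preset support set"))
    return reg
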