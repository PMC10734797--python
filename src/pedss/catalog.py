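"""Symptom catalog: code -> symptom -> severity mappings that parameterize the cascade.

The proxy-EDSS cascade is driven by two kinds of configuration:

* a list of :class:`CodeEntry` rows mapping ICD-10-GM diagnosis codes,
  ATC prescription codes, German medical-aid (Hilfsmittel) codes, and OPS
  procedure codes to an MS-related symptom, its functional system, and a
  severity tier (mild / moderate / severe); and
* a :class:`SpecialCodeSet` of fixed, special-role codes (fampridine, gait
  disturbance, plegias, bed confinement, ambulation aids) that the cascade
  consults directly.

Because the full 69-symptom mapping is institution-specific, the catalog is
a first-class, user-suppliable input with a documented CSV/YAML schema.  The
shipped default (:func:`default_catalog`) contains every special-role code
plus a small set of exemplar symptom entries; severity tiers of exemplar
entries that have no published tier are placeholders for demonstration and
should be replaced for production use.
"""

from __future__ import annotations

import csv
import enum
import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "CodeSystem",
    "MatchMode",
    "FunctionalSystem",
    "Severity",
    "EvidenceKind",
    "CodeEntry",
    "SpecialCodeSet",
    "SymptomCatalog",
    "CatalogError",
    "InvalidCodeError",
    "normalize_code",
    "split_qualifier",
    "match_code",
    "load_catalog",
    "write_catalog",
    "default_catalog",
]


class CatalogError(ValueError):
    """Catalog schema, uniqueness, or cross-field validation failure."""


class InvalidCodeError(ValueError):
    """A raw code that is empty or unusable after normalization."""


class CodeSystem(str, enum.Enum):
    ICD10GM = "ICD10GM"
    ATC = "ATC"
    AID = "AID"
    OPS = "OPS"


class MatchMode(str, enum.Enum):
    EXACT = "exact"
    PREFIX = "prefix"


class FunctionalSystem(str, enum.Enum):
    VISUAL = "visual"
    BRAINSTEM = "brainstem"
    PYRAMIDAL = "pyramidal"
    CEREBELLAR = "cerebellar"
    SENSORY = "sensory"
    BOWEL_BLADDER = "bowel_bladder"
    CEREBRAL = "cerebral"
    AMBULATION = "ambulation"


class Severity(str, enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class EvidenceKind(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    MEDICATION = "medication"
    THERAPY = "therapy"


# German outpatient diagnosis qualifiers: G (gesichert/confirmed),
# V (Verdacht/suspected), A (Ausschluss/excluded), Z (Zustand nach/status post).
_QUALIFIER_MAP = {
    "G": "confirmed",
    "V": "suspected",
    "A": "excluded",
    "Z": "status_post",
}
_QUALIFIER_RE = re.compile(r"^(?P<code>.+?)[\s]+(?P<qual>[GVAZ])$")


def split_qualifier(raw: str) -> tuple[str, str | None]:
    """Split a trailing German outpatient qualifier letter off a raw code.

    Returns ``(code_text, qualifier)`` where qualifier is one of
    ``confirmed``/``suspected``/``excluded``/``status_post`` or ``None``
    when the raw string carries no qualifier suffix.
    """
    text = raw.strip()
    m = _QUALIFIER_RE.match(text.upper())
    if m:
        return m.group("code").strip(), _QUALIFIER_MAP[m.group("qual")]
    return text, None


def normalize_code(raw: str, code_system: CodeSystem | str) -> str:
    """Normalize a raw code: trim, uppercase, strip qualifier suffix, keep dots.

    Raises :class:`InvalidCodeError` if nothing remains after trimming.
    """
    CodeSystem(code_system)  # validate the system label
    if raw is None or not str(raw).strip():
        raise InvalidCodeError(f"empty code: {raw!r}")
    code, _ = split_qualifier(str(raw))
    code = code.upper().replace(" ", "")
    if not code:
        raise InvalidCodeError(f"code empty after normalization: {raw!r}")
    return code


@dataclass(frozen=True)
class CodeEntry:
    """One catalog row: a code mapped to a symptom at a severity tier."""

    code: str
    code_system: CodeSystem
    match_mode: MatchMode
    symptom_id: str
    functional_system: FunctionalSystem
    severity: Severity
    evidence_kind: EvidenceKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "code_system", CodeSystem(self.code_system))
        object.__setattr__(self, "match_mode", MatchMode(self.match_mode))
        object.__setattr__(
            self, "functional_system", FunctionalSystem(self.functional_system)
        )
        object.__setattr__(self, "severity", Severity(self.severity))
        object.__setattr__(self, "evidence_kind", EvidenceKind(self.evidence_kind))
        if not self.code or self.code != self.code.upper() or " " in self.code:
            raise CatalogError(
                f"code must be non-empty, uppercase, whitespace-free: {self.code!r}"
            )
        if not self.symptom_id:
            raise CatalogError("symptom_id must be non-empty")

    def matches(self, code: str) -> bool:
        if self.match_mode is MatchMode.EXACT:
            return code == self.code
        return code.startswith(self.code)

    @property
    def key(self) -> tuple[str, CodeSystem, EvidenceKind]:
        return (self.code, self.code_system, self.evidence_kind)


def _codeset(codes: Iterable[str]) -> frozenset[str]:
    return frozenset(str(c).strip().upper() for c in codes)


@dataclass(frozen=True)
class SpecialCodeSet:
    """Fixed special-role code sets consulted directly by the cascade.

    Aid codes are German Hilfsmittel product-group stems and match by
    prefix (e.g. the wheelchair stem ``18.50`` matches product ``18.50.04``).
    """

    fampridine_atc: frozenset[str] = field(default_factory=lambda: _codeset({"N07XX07"}))
    gait_disturbance_icd: frozenset[str] = field(
        default_factory=lambda: _codeset({"R26.0", "R26.1", "R26.2", "R26.8"})
    )
    paraplegia_icd: frozenset[str] = field(
        default_factory=lambda: _codeset({"G82.12", "G82.22", "G82.63", "M62.3"})
    )
    tetraplegia_icd: frozenset[str] = field(
        default_factory=lambda: _codeset({"G82.42", "G82.52"})
    )
    bed_confinement_icd: frozenset[str] = field(
        default_factory=lambda: _codeset({"R26.3"})
    )
    walking_stick_aid: frozenset[str] = field(
        default_factory=lambda: _codeset({"10.50.01"})
    )
    wheelchair_aid: frozenset[str] = field(
        default_factory=lambda: _codeset({"18.50", "18.51"})
    )
    chair_bed_aid: frozenset[str] = field(
        default_factory=lambda: _codeset({"19.40.01"})
    )

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, _codeset(getattr(self, name)))
            if not getattr(self, name):
                raise CatalogError(f"special code set {name} must be non-empty")

    def to_dict(self) -> dict[str, list[str]]:
        return {
            name: sorted(getattr(self, name)) for name in self.__dataclass_fields__
        }


@dataclass(frozen=True)
class SymptomCatalog:
    """A validated set of code entries plus the special-role code sets."""

    entries: tuple[CodeEntry, ...] = ()
    special: SpecialCodeSet = field(default_factory=SpecialCodeSet)
    name: str = "catalog"
    version: str = "0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        validate_entries(self.entries)

    def diagnosis_entries(self) -> tuple[CodeEntry, ...]:
        return tuple(
            e for e in self.entries if e.evidence_kind is EvidenceKind.DIAGNOSIS
        )

    def drug_entries(self) -> tuple[CodeEntry, ...]:
        """Medication and therapy rows ("drugs/therapies" in the cascade)."""
        return tuple(
            e for e in self.entries if e.evidence_kind is not EvidenceKind.DIAGNOSIS
        )

    def entries_by_severity(
        self, severity: Severity, evidence: EvidenceKind | None = None
    ) -> tuple[CodeEntry, ...]:
        out = [e for e in self.entries if e.severity is severity]
        if evidence is not None:
            out = [e for e in out if e.evidence_kind is evidence]
        return tuple(out)


def validate_entries(entries: Sequence[CodeEntry]) -> None:
    seen: dict[tuple, CodeEntry] = {}
    for i, e in enumerate(entries):
        if e.key in seen:
            raise CatalogError(
                f"duplicate catalog entry for (code={e.code}, system={e.code_system.value}, "
                f"kind={e.evidence_kind.value}) at row {i}"
            )
        seen[e.key] = e
        # cross-field plausibility: aids are never diagnosis evidence;
        # ICD diagnosis codes are never medication evidence
        if e.code_system is CodeSystem.AID and e.evidence_kind is EvidenceKind.DIAGNOSIS:
            raise CatalogError(
                f"row {i}: AID code {e.code} cannot carry diagnosis evidence"
            )
        if (
            e.code_system is CodeSystem.ICD10GM
            and e.evidence_kind is EvidenceKind.MEDICATION
        ):
            raise CatalogError(
                f"row {i}: ICD-10-GM code {e.code} cannot carry medication evidence"
            )


def match_code(
    catalog: SymptomCatalog, code: str, code_system: CodeSystem | str
) -> list[CodeEntry]:
    """All entries matching a normalized code in the given code system.

    Exact-mode entries must equal the query; prefix-mode entries must be a
    prefix of it.  Order: entry code length descending, then lexicographic,
    then evidence kind — deterministic for any catalog.
    """
    system = CodeSystem(code_system)
    hits = [
        e for e in catalog.entries if e.code_system is system and e.matches(code)
    ]
    hits.sort(key=lambda e: (-len(e.code), e.code, e.evidence_kind.value))
    return hits


_CSV_COLUMNS = [
    "code",
    "code_system",
    "match_mode",
    "symptom_id",
    "functional_system",
    "severity",
    "evidence_kind",
]


def _entry_from_row(row: dict, where: str) -> CodeEntry:
    missing = [c for c in _CSV_COLUMNS if not str(row.get(c, "") or "").strip()]
    if missing:
        raise CatalogError(f"{where}: missing field(s) {missing}")
    try:
        return CodeEntry(
            code=normalize_code(row["code"], row["code_system"].strip()),
            code_system=row["code_system"].strip(),
            match_mode=row["match_mode"].strip(),
            symptom_id=row["symptom_id"].strip(),
            functional_system=row["functional_system"].strip(),
            severity=row["severity"].strip(),
            evidence_kind=row["evidence_kind"].strip(),
        )
    except (ValueError, KeyError) as exc:
        raise CatalogError(f"{where}: {exc}") from exc


def load_catalog(path: str | Path, fmt: str | None = None) -> SymptomCatalog:
    """Load and validate a catalog from a CSV or YAML file.

    ``fmt`` is ``"csv"`` or ``"yaml"``; inferred from the suffix when omitted.
    CSV files hold entry rows only (the Table-1 special set is used); YAML
    documents hold ``entries:``, an optional ``special:`` section overriding
    individual special code sets, and optional ``name``/``version``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "yaml" if path.suffix.lower() in {".yml", ".yaml"} else "csv"
    text = path.read_text(encoding="utf-8")
    if fmt == "csv":
        return _catalog_from_csv(text, name=path.stem)
    if fmt == "yaml":
        return _catalog_from_yaml(text, default_name=path.stem)
    raise CatalogError(f"unknown catalog format {fmt!r} (expected csv or yaml)")


def _catalog_from_csv(text: str, name: str) -> SymptomCatalog:
    reader = csv.DictReader(_io.StringIO(text))
    if reader.fieldnames is None or set(_CSV_COLUMNS) - set(reader.fieldnames):
        raise CatalogError(
            f"catalog CSV must have columns {_CSV_COLUMNS}; got {reader.fieldnames}"
        )
    entries = [
        _entry_from_row(row, f"row {i + 2}") for i, row in enumerate(reader)
    ]
    return SymptomCatalog(entries=tuple(entries), name=name)


def _catalog_from_yaml(text: str, default_name: str) -> SymptomCatalog:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CatalogError(f"catalog YAML parse failure: {exc}") from exc
    if not isinstance(doc, dict):
        raise CatalogError("catalog YAML must be a mapping")
    entries = tuple(
        _entry_from_row(row, f"entries[{i}]")
        for i, row in enumerate(doc.get("entries") or [])
    )
    special_doc = doc.get("special") or {}
    known = set(SpecialCodeSet.__dataclass_fields__)
    unknown = set(special_doc) - known
    if unknown:
        raise CatalogError(f"unknown special code set(s): {sorted(unknown)}")
    special = SpecialCodeSet(**{k: frozenset(v) for k, v in special_doc.items()})
    return SymptomCatalog(
        entries=entries,
        special=special,
        name=str(doc.get("name", default_name)),
        version=str(doc.get("version", "0")),
    )


def write_catalog(catalog: SymptomCatalog, path: str | Path, fmt: str | None = None) -> None:
    """Serialize a catalog so that ``load_catalog`` round-trips it."""
    path = Path(path)
    if fmt is None:
        fmt = "yaml" if path.suffix.lower() in {".yml", ".yaml"} else "csv"
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for e in catalog.entries:
                writer.writerow(
                    {
                        "code": e.code,
                        "code_system": e.code_system.value,
                        "match_mode": e.match_mode.value,
                        "symptom_id": e.symptom_id,
                        "functional_system": e.functional_system.value,
                        "severity": e.severity.value,
                        "evidence_kind": e.evidence_kind.value,
                    }
                )
    elif fmt == "yaml":
        doc = {
            "name": catalog.name,
            "version": catalog.version,
            "entries": [
                {
                    "code": e.code,
                    "code_system": e.code_system.value,
                    "match_mode": e.match_mode.value,
                    "symptom_id": e.symptom_id,
                    "functional_system": e.functional_system.value,
                    "severity": e.severity.value,
                    "evidence_kind": e.evidence_kind.value,
                }
                for e in catalog.entries
            ],
            "special": catalog.special.to_dict(),
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    else:
        raise CatalogError(f"unknown catalog format {fmt!r} (expected csv or yaml)")


def _E(code, system, mode, symptom, fs, sev, kind) -> CodeEntry:
    return CodeEntry(code, system, mode, symptom, fs, sev, kind)


def default_catalog() -> SymptomCatalog:
    """The shipped default catalog.

    Contains the full special-role set plus exemplar symptom entries:
    the oculomotor exemplars H49/H51/H53.278/H55 and a small demonstration
    set spanning every functional system and severity tier, including the
    spasticity escalation pattern (diagnosis row at mild, associated
    medication at moderate, interventional therapy at severe).

    Severity tiers of entries without a published tier are PLACEHOLDERS:
    replace them with an institution-curated mapping for real analyses.
    """
    ICD, ATC, OPS = CodeSystem.ICD10GM, CodeSystem.ATC, CodeSystem.OPS
    P = MatchMode.PREFIX
    DX, MED, THER = EvidenceKind.DIAGNOSIS, EvidenceKind.MEDICATION, EvidenceKind.THERAPY
    FS = FunctionalSystem
    entries = (
        # oculomotor exemplars (brainstem/visual descriptors)
        _E("H55", ICD, P, "nystagmus", FS.BRAINSTEM, Severity.MILD, DX),
        _E("H49", ICD, P, "extraocular_impairment", FS.BRAINSTEM, Severity.MODERATE, DX),
        _E("H51", ICD, P, "extraocular_impairment", FS.BRAINSTEM, Severity.MODERATE, DX),
        _E("H53.278", ICD, P, "extraocular_impairment", FS.BRAINSTEM, Severity.MODERATE, DX),
        # placeholder-tier demonstration entries, one per functional system
        _E("R20.2", ICD, P, "paresthesia", FS.SENSORY, Severity.MILD, DX),
        _E("R25.1", ICD, P, "tremor", FS.CEREBELLAR, Severity.MILD, DX),
        _E("G93.3", ICD, P, "fatigue", FS.CEREBRAL, Severity.MILD, DX),
        _E("R25.2", ICD, P, "spasticity", FS.PYRAMIDAL, Severity.MILD, DX),
        _E("R27.0", ICD, P, "ataxia", FS.CEREBELLAR, Severity.MODERATE, DX),
        _E("N39.4", ICD, P, "bladder_dysfunction", FS.BOWEL_BLADDER, Severity.MODERATE, DX),
        _E("F32", ICD, P, "depression", FS.CEREBRAL, Severity.MODERATE, DX),
        _E("H81.4", ICD, P, "vertigo", FS.BRAINSTEM, Severity.MODERATE, DX),
        _E("H54.0", ICD, P, "blindness", FS.VISUAL, Severity.SEVERE, DX),
        _E("R47.0", ICD, P, "aphasia", FS.CEREBRAL, Severity.SEVERE, DX),
        # drugs/therapies associated with symptoms (escalation pattern)
        _E("N04BB01", ATC, P, "fatigue", FS.CEREBRAL, Severity.MILD, MED),
        _E("M03BX01", ATC, P, "spasticity", FS.PYRAMIDAL, Severity.MODERATE, MED),
        _E("G04BD04", ATC, P, "bladder_dysfunction", FS.BOWEL_BLADDER, Severity.MODERATE, MED),
        _E("N02BG10", ATC, P, "spasticity", FS.PYRAMIDAL, Severity.SEVERE, MED),
        _E("8-010", OPS, P, "spasticity", FS.PYRAMIDAL, Severity.SEVERE, THER),
    )
    return SymptomCatalog(entries=entries, special=SpecialCodeSet(), name="default", version="1")
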