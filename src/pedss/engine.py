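"""Proxy-EDSS engine: windowed claims aggregation and the 10-step rule cascade.

The engine turns one patient's dated claims events around an index date into
a :class:`SymptomProfile` (qualified symptom diagnoses per severity tier,
distinct symptom-associated drugs/therapies per tier, and special-role flags)
and applies a top-down rule cascade that assigns a proxy disability step 0-9:

=====  =============================================================
step   condition (first match from the top wins)
=====  =============================================================
9      bed-confinement diagnosis, patient alive at period end
8      chair/special-bed aid, or tetraplegia diagnosis
7      wheelchair aid, or paraplegia diagnosis
6      walking-stick aid
5      >=1 severe symptom dx, or >=1 severe-associated drug, or
       >=4 moderate symptom dx, or fampridine with >=1 moderate/severe dx
4      >=3 moderate symptom dx, or >=3 moderate-associated drugs, or
       gait-disturbance dx, or fampridine with no moderate/severe dx
3      1-2 moderate symptom dx or 1-2 moderate-associated drugs,
       no fampridine
2      >=2 mild symptom dx, no fampridine
1      1 mild symptom dx or >=1 mild-associated drug, no fampridine
0      no qualifying symptom evidence at all
=====  =============================================================

A symptom diagnosis "qualifies" with at least one inpatient diagnosis or two
confirmed outpatient diagnoses on distinct service dates (the German claims
validation convention).  Prescriptions and aid deliveries qualify from a
single event.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import (
    CatalogError,
    CodeSystem,
    Severity,
    SymptomCatalog,
)

__all__ = [
    "Setting",
    "Qualifier",
    "ClaimEvent",
    "AssessmentWindow",
    "SymptomProfile",
    "PedssResult",
    "CoverageInterval",
    "CohortParams",
    "select_window_events",
    "qualify_diagnosis",
    "build_profile",
    "compute_pedss",
    "compute_pedss_batch",
    "select_cohort",
    "code_in_set",
]


class Setting(str, enum.Enum):
    INPATIENT_DX = "inpatient_dx"
    OUTPATIENT_DX = "outpatient_dx"
    PRESCRIPTION = "prescription"
    AID = "aid"
    PROCEDURE = "procedure"


class Qualifier(str, enum.Enum):
    CONFIRMED = "confirmed"
    SUSPECTED = "suspected"
    EXCLUDED = "excluded"
    STATUS_POST = "status_post"
    NONE = "none"


@dataclass(frozen=True)
class ClaimEvent:
    """One dated, coded healthcare record (diagnosis, prescription, or aid)."""

    patient_id: str
    date: dt.date
    code_system: CodeSystem
    code: str
    setting: Setting
    qualifier: Qualifier = Qualifier.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "code_system", CodeSystem(self.code_system))
        object.__setattr__(self, "setting", Setting(self.setting))
        object.__setattr__(self, "qualifier", Qualifier(self.qualifier))
        if not isinstance(self.date, dt.date) or isinstance(self.date, dt.datetime):
            raise ValueError(f"date must be a datetime.date, got {self.date!r}")
        # diagnosis confirmation qualifiers exist only for outpatient diagnoses
        if self.setting is not Setting.OUTPATIENT_DX and self.qualifier is not Qualifier.NONE:
            raise ValueError(
                f"qualifier {self.qualifier.value!r} is only meaningful for "
                f"outpatient diagnoses (setting={self.setting.value})"
            )


@dataclass(frozen=True)
class AssessmentWindow:
    """Symmetric day window around an index date, inclusive on both ends."""

    index_date: dt.date
    days_before: int = 90
    days_after: int = 90

    def __post_init__(self) -> None:
        if self.days_before < 0 or self.days_after < 0:
            raise ValueError("window extents must be non-negative")

    @property
    def start(self) -> dt.date:
        return self.index_date - dt.timedelta(days=self.days_before)

    @property
    def end(self) -> dt.date:
        return self.index_date + dt.timedelta(days=self.days_after)

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


@dataclass
class SymptomProfile:
    """Per-window evidence aggregate consumed by the cascade.

    A symptom id appears in at most one of the three diagnosis sets — at the
    highest severity for which its diagnosis evidence qualifies.  Gait
    disturbance is tracked as its own flag and never enters the moderate set.
    """

    mild_dx_symptoms: frozenset[str] = frozenset()
    moderate_dx_symptoms: frozenset[str] = frozenset()
    severe_dx_symptoms: frozenset[str] = frozenset()
    mild_drug_count: int = 0
    moderate_drug_count: int = 0
    severe_drug_count: int = 0
    fampridine: bool = False
    gait_disturbance_dx: bool = False
    walking_stick: bool = False
    wheelchair: bool = False
    paraplegia_dx: bool = False
    tetraplegia_dx: bool = False
    chair_bed: bool = False
    bed_confinement_dx: bool = False
    alive_at_period_end: bool = True

    def __post_init__(self) -> None:
        for name in ("mild_drug_count", "moderate_drug_count", "severe_drug_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PedssResult:
    patient_id: str
    index_date: dt.date
    pedss: int
    fired_step: int
    fired_clause: str

    def __post_init__(self) -> None:
        if not (0 <= self.pedss <= 9) or self.fired_step != self.pedss:
            raise ValueError("pedss must be in 0..9 with fired_step == pedss")


@dataclass(frozen=True)
class CoverageInterval:
    patient_id: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("coverage start must be <= end")


def code_in_set(code: str, code_set: Iterable[str], prefix: bool = True) -> bool:
    """Membership with product-group/stem semantics (prefix match by default)."""
    if prefix:
        return any(code.startswith(c) for c in code_set)
    return code in set(code_set)


def select_window_events(
    events: Sequence[ClaimEvent], window: AssessmentWindow
) -> list[ClaimEvent]:
    """Events inside the assessment window, original order preserved."""
    return [e for e in events if window.contains(e.date)]


def qualify_diagnosis(
    events: Sequence[ClaimEvent],
    entry_codes: Iterable[str],
    *,
    require_distinct_quarters: bool = False,
) -> bool:
    """Diagnosis validation rule over windowed events.

    True iff the code set is supported by >=1 inpatient diagnosis, or by >=2
    confirmed outpatient diagnoses on distinct service dates (optionally
    distinct calendar quarters with ``require_distinct_quarters``).
    """
    codes = set(entry_codes)
    outpatient_dates: set[dt.date] = set()
    for e in events:
        if e.code_system is not CodeSystem.ICD10GM:
            continue
        if not code_in_set(e.code, codes):
            continue
        if e.setting is Setting.INPATIENT_DX:
            return True
        if e.setting is Setting.OUTPATIENT_DX and e.qualifier is Qualifier.CONFIRMED:
            outpatient_dates.add(e.date)
    if require_distinct_quarters:
        quarters = {(d.year, (d.month - 1) // 3) for d in outpatient_dates}
        return len(quarters) >= 2
    return len(outpatient_dates) >= 2


_SEVERITY_ORDER = (Severity.SEVERE, Severity.MODERATE, Severity.MILD)


def build_profile(
    events: Sequence[ClaimEvent],
    catalog: SymptomCatalog,
    window: AssessmentWindow,
    alive_at_period_end: bool = True,
    *,
    require_distinct_quarters: bool = False,
) -> SymptomProfile:
    """Aggregate one patient's events in the window into a SymptomProfile."""
    if not isinstance(catalog, SymptomCatalog):
        raise CatalogError("build_profile requires a validated SymptomCatalog")
    windowed = select_window_events(events, window)

    # qualified diagnosis evidence per (symptom, severity)
    dx_codes: dict[tuple[str, Severity], set[str]] = {}
    for entry in catalog.diagnosis_entries():
        dx_codes.setdefault((entry.symptom_id, entry.severity), set()).add(entry.code)
    qualified: dict[str, set[Severity]] = {}
    for (symptom, severity), codes in dx_codes.items():
        if qualify_diagnosis(
            windowed, codes, require_distinct_quarters=require_distinct_quarters
        ):
            qualified.setdefault(symptom, set()).add(severity)

    # each symptom counts once, at its highest qualified severity
    by_severity: dict[Severity, set[str]] = {s: set() for s in Severity}
    for symptom, sevs in qualified.items():
        top = next(s for s in _SEVERITY_ORDER if s in sevs)
        by_severity[top].add(symptom)

    # distinct symptom-associated drug/therapy codes per severity
    drug_entries = catalog.drug_entries()
    drug_codes: dict[Severity, set[str]] = {s: set() for s in Severity}
    for e in windowed:
        if e.setting not in (Setting.PRESCRIPTION, Setting.PROCEDURE):
            continue
        for entry in drug_entries:
            if entry.code_system is e.code_system and entry.matches(e.code):
                drug_codes[entry.severity].add(entry.code)

    sp = catalog.special
    fampridine = any(
        e.code_system is CodeSystem.ATC
        and e.setting is Setting.PRESCRIPTION
        and code_in_set(e.code, sp.fampridine_atc)
        for e in windowed
    )
    aids = [e.code for e in windowed if e.setting is Setting.AID]

    def any_aid(stems: frozenset[str]) -> bool:
        return any(code_in_set(c, stems) for c in aids)

    def qdx(codes: frozenset[str]) -> bool:
        return qualify_diagnosis(
            windowed, codes, require_distinct_quarters=require_distinct_quarters
        )

    return SymptomProfile(
        mild_dx_symptoms=frozenset(by_severity[Severity.MILD]),
        moderate_dx_symptoms=frozenset(by_severity[Severity.MODERATE]),
        severe_dx_symptoms=frozenset(by_severity[Severity.SEVERE]),
        mild_drug_count=len(drug_codes[Severity.MILD]),
        moderate_drug_count=len(drug_codes[Severity.MODERATE]),
        severe_drug_count=len(drug_codes[Severity.SEVERE]),
        fampridine=fampridine,
        gait_disturbance_dx=qdx(sp.gait_disturbance_icd),
        walking_stick=any_aid(sp.walking_stick_aid),
        wheelchair=any_aid(sp.wheelchair_aid),
        paraplegia_dx=qdx(sp.paraplegia_icd),
        tetraplegia_dx=qdx(sp.tetraplegia_icd),
        chair_bed=any_aid(sp.chair_bed_aid),
        bed_confinement_dx=qdx(sp.bed_confinement_icd),
        alive_at_period_end=alive_at_period_end,
    )


def compute_pedss(profile: SymptomProfile, patient_id: str = "", index_date: dt.date | None = None) -> PedssResult:
    """Apply the cascade top-down; the highest satisfied step wins."""
    p = profile
    n_mild = len(p.mild_dx_symptoms)
    n_mod = len(p.moderate_dx_symptoms)
    n_sev = len(p.severe_dx_symptoms)
    idx = index_date or dt.date(1970, 1, 1)

    def result(step: int, clause: str) -> PedssResult:
        return PedssResult(patient_id, idx, step, step, clause)

    if p.bed_confinement_dx and p.alive_at_period_end:
        return result(9, "bed-confinement diagnosis, alive at period end")
    if p.chair_bed or p.tetraplegia_dx:
        return result(8, "chair/special-bed aid or tetraplegia diagnosis")
    if p.wheelchair or p.paraplegia_dx:
        return result(7, "wheelchair aid or paraplegia diagnosis")
    if p.walking_stick:
        return result(6, "walking-stick aid")
    if (
        n_sev >= 1
        or p.severe_drug_count >= 1
        or n_mod >= 4
        or (p.fampridine and (n_mod >= 1 or n_sev >= 1))
    ):
        return result(
            5,
            "severe symptom dx/drug, >=4 moderate dx, or fampridine with moderate/severe dx",
        )
    if (
        n_mod >= 3
        or p.moderate_drug_count >= 3
        or p.gait_disturbance_dx
        or (p.fampridine and n_mod == 0 and n_sev == 0)
    ):
        return result(
            4,
            ">=3 moderate dx/drugs, gait disturbance, or fampridine without moderate/severe dx",
        )
    if (1 <= n_mod <= 2 or 1 <= p.moderate_drug_count <= 2) and not p.fampridine:
        return result(3, "1-2 moderate symptom dx or drugs")
    if n_mild >= 2 and not p.fampridine:
        return result(2, ">=2 mild symptom dx")
    if (n_mild == 1 or p.mild_drug_count >= 1) and not p.fampridine:
        return result(1, "1 mild symptom dx or >=1 mild-associated drug")
    return result(0, "no qualifying symptom evidence")


def _covers(intervals: Sequence[CoverageInterval], start: dt.date, end: dt.date) -> bool:
    """Whether merged coverage intervals contain [start, end] without gaps.

    Adjacent intervals (next start <= current end + 1 day) are merged.
    """
    ivs = sorted(((iv.start, iv.end) for iv in intervals), key=lambda t: t[0])
    cursor = None
    for s, e in ivs:
        if cursor is None:
            if s > start:
                continue
            if e >= start:
                cursor = e
        elif s <= cursor + dt.timedelta(days=1):
            cursor = max(cursor, e)
        else:
            break
        if cursor is not None and cursor >= end:
            return True
    return cursor is not None and cursor >= end


@dataclass(frozen=True)
class FlaggedIndex:
    patient_id: str
    index_date: dt.date
    reason: str


def compute_pedss_batch(
    events_by_patient: Mapping[str, Sequence[ClaimEvent]],
    index_dates: Mapping[str, Sequence[dt.date]],
    catalog: SymptomCatalog,
    *,
    days_before: int = 90,
    days_after: int = 90,
    coverage: Mapping[str, Sequence[CoverageInterval]] | None = None,
    deaths: Mapping[str, dt.date] | None = None,
    study_end: dt.date | None = None,
    require_distinct_quarters: bool = False,
) -> tuple[list[PedssResult], list[FlaggedIndex]]:
    """One proxy-EDSS result per (patient, index date); coverage-gapped index
    dates are flagged with a reason instead of being silently dropped.

    ``alive_at_period_end`` is derived from the deaths table against
    ``study_end`` (no death record, or death after study end, counts as alive).
    """
    deaths = deaths or {}
    results: list[PedssResult] = []
    flagged: list[FlaggedIndex] = []
    for patient_id in sorted(index_dates):
        events = list(events_by_patient.get(patient_id, ()))
        death = deaths.get(patient_id)
        alive = death is None or (study_end is not None and death > study_end)
        for index_date in sorted(index_dates[patient_id]):
            window = AssessmentWindow(index_date, days_before, days_after)
            if coverage is not None:
                ivs = coverage.get(patient_id, ())
                if not _covers(ivs, window.start, window.end):
                    flagged.append(
                        FlaggedIndex(
                            patient_id,
                            index_date,
                            f"insurance coverage does not span {window.start}..{window.end}",
                        )
                    )
                    continue
            profile = build_profile(
                events,
                catalog,
                window,
                alive_at_period_end=alive,
                require_distinct_quarters=require_distinct_quarters,
            )
            results.append(compute_pedss(profile, patient_id, index_date))
    return results, flagged


# -- cohort selection ---------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the claims-cohort selection procedure.

    The default inclusion period, baseline/follow-up lengths, and exclusion
    code stems mirror a 12-month-baseline / 12-month-follow-up incident-MS
    design; exclusion code lists are configurable stems (pregnancy chapter
    ``O``; other demyelinating disease ``G36``/``G37``).
    """

    inclusion_start: dt.date = dt.date(2016, 7, 1)
    inclusion_end: dt.date = dt.date(2017, 6, 30)
    study_end: dt.date = dt.date(2018, 6, 30)
    baseline_days: int = 365
    followup_days: int = 365
    min_age: int = 18
    ms_icd_prefix: str = "G35"
    pregnancy_icd: frozenset[str] = frozenset({"O"})
    demyelinating_icd: frozenset[str] = frozenset({"G36", "G37"})

    def __post_init__(self) -> None:
        if not (self.inclusion_start <= self.inclusion_end <= self.study_end):
            raise ValueError(
                "require inclusion_start <= inclusion_end <= study_end"
            )
        if self.baseline_days <= 0 or self.followup_days <= 0:
            raise ValueError("baseline/follow-up lengths must be positive")


_COHORT_FILTERS = (
    "ms_case_rule",
    "no_index_date",
    "not_adult",
    "coverage_gap",
    "exclusion_diagnosis",
    "died_in_followup",
)


def select_cohort(
    demographics: Mapping[str, int],
    events_by_patient: Mapping[str, Sequence[ClaimEvent]],
    coverage: Mapping[str, Sequence[CoverageInterval]],
    params: CohortParams = CohortParams(),
    deaths: Mapping[str, dt.date] | None = None,
) -> tuple[list[tuple[str, dt.date]], dict[str, int]]:
    """Sequential cohort filters; returns (cohort, attrition).

    ``demographics`` maps patient_id -> birth year.  Filters, in order:
    (1) MS case rule: >=1 inpatient or >=2 confirmed outpatient MS diagnoses
    (distinct dates) in the inclusion period; (2) index = date of first MS
    diagnosis event in the period; (3) adult at index; (4) continuous
    insurance from baseline start through study end (a death-truncated
    coverage end is tolerated — such patients fall to filter 6);
    (5) no pregnancy-related or other-demyelinating-disease diagnosis from
    baseline start through study end; (6) alive through follow-up.
    """
    deaths = deaths or {}
    attrition = {name: 0 for name in _COHORT_FILTERS}
    cohort: list[tuple[str, dt.date]] = []

    for patient_id in sorted(demographics):
        events = list(events_by_patient.get(patient_id, ()))
        in_period = [
            e
            for e in events
            if params.inclusion_start <= e.date <= params.inclusion_end
        ]
        if not qualify_diagnosis(in_period, {params.ms_icd_prefix}):
            attrition["ms_case_rule"] += 1
            continue

        ms_dates = sorted(
            e.date
            for e in in_period
            if e.code_system is CodeSystem.ICD10GM
            and code_in_set(e.code, {params.ms_icd_prefix})
            and (
                e.setting is Setting.INPATIENT_DX
                or (
                    e.setting is Setting.OUTPATIENT_DX
                    and e.qualifier is Qualifier.CONFIRMED
                )
            )
        )
        if not ms_dates:
            attrition["no_index_date"] += 1
            continue
        index_date = ms_dates[0]

        birth_year = demographics[patient_id]
        if index_date.year - birth_year < params.min_age:
            attrition["not_adult"] += 1
            continue

        death = deaths.get(patient_id)
        cov_start = index_date - dt.timedelta(days=params.baseline_days)
        cov_end = params.study_end
        if death is not None and death < cov_end:
            cov_end = death  # death-truncated coverage tolerated here
        if not _covers(list(coverage.get(patient_id, ())), cov_start, cov_end):
            attrition["coverage_gap"] += 1
            continue

        exclusion_codes = params.pregnancy_icd | params.demyelinating_icd
        has_exclusion = any(
            e.code_system is CodeSystem.ICD10GM
            and e.setting in (Setting.INPATIENT_DX, Setting.OUTPATIENT_DX)
            and code_in_set(e.code, exclusion_codes)
            and cov_start <= e.date <= params.study_end
            for e in events
        )
        if has_exclusion:
            attrition["exclusion_diagnosis"] += 1
            continue

        if death is not None and death <= index_date + dt.timedelta(
            days=params.followup_days
        ):
            attrition["died_in_followup"] += 1
            continue

        cohort.append((patient_id, index_date))
    return cohort, attrition
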