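"""Synthetic linked cohorts: latent disability trajectories plus claims events.

Real validation data for a claims-based disability proxy is a private linkage
of insurance claims with clinic records, so this module generates the same
structure synthetically: each patient carries a latent true disability step
(0-9) at each measurement date, a symptom burden consistent with that step,
and a canonical ambulation state (walking stick at 6, wheelchair at 7,
chair/bed at 8, bed confinement at 9).  Claims events are then emitted from
the latent state through severity-dependent capture probabilities: severe
indicators and reimbursed aids are captured often, mild symptoms rarely —
the mechanism that makes claims-based proxies underestimate mild disability.

Defaults are anchored to the published validation cohort where values are
printed: the initial-step distribution follows the validation cohort's index
EDSS categories, wheelchair capture is 0.86, walking-stick capture 0.22, and
measurements per patient run 1-18 with mean about 6.  Per-severity diagnosis
capture rates are plausible, tunable values (no published per-severity rates
exist).

At capture probability 1 the emitted events are exactly the canonical
evidence for each step, and the engine recovers the latent step for every
measurement — the generator's round-trip contract.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import (
    CatalogError,
    CodeEntry,
    CodeSystem,
    EvidenceKind,
    Severity,
    SymptomCatalog,
)
from .engine import ClaimEvent, Qualifier, Setting

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "canonical_events_for_step",
    "generate_cohort",
]

# initial-step probabilities for steps 0..9: the validation cohort's index
# EDSS category distribution (18/23/27/11/4/9/7/1 % for steps 1..>=8)
_DEFAULT_STEP_DIST = (0.0, 0.18, 0.23, 0.27, 0.11, 0.04, 0.09, 0.07, 0.01, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    ``dx_capture``/``drug_emission`` give the probability that a latent
    symptom of a given severity leaves a diagnosis / an associated
    prescription in claims; ``aid_capture`` the probability that a required
    ambulation aid appears as a claims aid delivery.
    """

    n_patients: int = 100
    seed: int = 0
    edss_distribution: tuple[float, ...] = _DEFAULT_STEP_DIST
    measures_min: int = 1
    measures_max: int = 18
    measures_mean: float = 6.2
    dx_capture: dict[Severity, float] = field(
        default_factory=lambda: {
            Severity.MILD: 0.25,
            Severity.MODERATE: 0.45,
            Severity.SEVERE: 0.85,
        }
    )
    drug_emission: dict[Severity, float] = field(
        default_factory=lambda: {
            Severity.MILD: 0.20,
            Severity.MODERATE: 0.30,
            Severity.SEVERE: 0.50,
        }
    )
    aid_capture: dict[str, float] = field(
        default_factory=lambda: {
            "walking_stick": 0.22,
            "wheelchair": 0.86,
            "chair_bed": 0.85,
        }
    )
    outpatient_confirmed_prob: float = 0.9
    inpatient_dx_prob: float = 0.3
    window_jitter_days: int = 60
    start_date: dt.date = dt.date(2016, 1, 1)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        dist = np.asarray(self.edss_distribution, dtype=float)
        if dist.shape != (10,) or (dist < 0).any() or not np.isclose(dist.sum(), 1.0):
            raise ValueError(
                "edss_distribution must be 10 non-negative probabilities summing to 1"
            )
        probs = (
            list(self.dx_capture.values())
            + list(self.drug_emission.values())
            + list(self.aid_capture.values())
            + [self.outpatient_confirmed_prob, self.inpatient_dx_prob]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all capture/emission probabilities must be in [0, 1]")
        if not 1 <= self.measures_min <= self.measures_max:
            raise ValueError("require 1 <= measures_min <= measures_max")
        if self.window_jitter_days < 0 or self.window_jitter_days > 90:
            raise ValueError("window_jitter_days must be in 0..90")

    def at_full_capture(self) -> "GeneratorConfig":
        """Copy with every capture/emission probability set to 1 (round-trip
        conditions)."""
        return replace(
            self,
            dx_capture={s: 1.0 for s in Severity},
            drug_emission={s: 1.0 for s in Severity},
            aid_capture={k: 1.0 for k in self.aid_capture},
            outpatient_confirmed_prob=1.0,
        )


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated tables in the engine's input schema (+ latent truth)."""

    measures: pd.DataFrame  # patient_id, date, score, true_step
    events: pd.DataFrame  # patient_id, date, code_system, code, setting, qualifier
    coverage: pd.DataFrame  # patient_id, start, end
    deaths: pd.DataFrame  # patient_id, date


def _tier_symptoms(catalog: SymptomCatalog, severity: Severity) -> list[tuple[str, str]]:
    """Distinct (symptom_id, representative diagnosis code) at a severity,
    deterministic order."""
    seen: dict[str, str] = {}
    for e in sorted(
        catalog.entries_by_severity(severity, EvidenceKind.DIAGNOSIS),
        key=lambda e: (e.symptom_id, e.code),
    ):
        seen.setdefault(e.symptom_id, e.code)
    return sorted(seen.items())


def _tier_drugs(catalog: SymptomCatalog, severity: Severity) -> list[CodeEntry]:
    return sorted(
        (e for e in catalog.drug_entries() if e.severity is severity),
        key=lambda e: e.code,
    )


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise CatalogError(message)


def _inpatient(pid: str, date: dt.date, code: str) -> ClaimEvent:
    return ClaimEvent(pid, date, CodeSystem.ICD10GM, code, Setting.INPATIENT_DX)


def _aid(pid: str, date: dt.date, stem: str) -> ClaimEvent:
    # emit a concrete product code under the product-group stem
    return ClaimEvent(pid, date, CodeSystem.AID, stem + ".01", Setting.AID)


def canonical_events_for_step(
    step: int,
    index_date: dt.date,
    catalog: SymptomCatalog,
    patient_id: str = "synthetic",
) -> list[ClaimEvent]:
    """Minimal, deterministic event set that the engine maps back to ``step``.

    Diagnoses are emitted as single inpatient events (which always qualify);
    aids and prescriptions as single events.  The catalog must provide at
    least two mild, four moderate, and one severe diagnosis symptom plus the
    special code sets.
    """
    if step not in range(10):
        raise ValueError(f"step must be in 0..9, got {step!r}")
    sp = catalog.special
    mild = _tier_symptoms(catalog, Severity.MILD)
    moderate = _tier_symptoms(catalog, Severity.MODERATE)
    severe = _tier_symptoms(catalog, Severity.SEVERE)
    d = index_date
    pid = patient_id

    if step == 0:
        return []
    if step == 1:
        _require(len(mild) >= 1, "catalog lacks a mild diagnosis symptom")
        return [_inpatient(pid, d, mild[0][1])]
    if step == 2:
        _require(len(mild) >= 2, "catalog lacks two mild diagnosis symptoms")
        return [_inpatient(pid, d, code) for _, code in mild[:2]]
    if step == 3:
        _require(len(moderate) >= 1, "catalog lacks a moderate diagnosis symptom")
        return [_inpatient(pid, d, moderate[0][1])]
    if step == 4:
        # fampridine with no moderate/severe diagnoses
        return [
            ClaimEvent(
                pid, d, CodeSystem.ATC, sorted(sp.fampridine_atc)[0], Setting.PRESCRIPTION
            )
        ]
    if step == 5:
        _require(len(severe) >= 1, "catalog lacks a severe diagnosis symptom")
        return [_inpatient(pid, d, severe[0][1])]
    if step == 6:
        return [_aid(pid, d, sorted(sp.walking_stick_aid)[0])]
    if step == 7:
        return [_aid(pid, d, sorted(sp.wheelchair_aid)[0])]
    if step == 8:
        return [_aid(pid, d, sorted(sp.chair_bed_aid)[0])]
    return [_inpatient(pid, d, sorted(sp.bed_confinement_icd)[0])]


# latent symptom burden per step: (n_mild, n_moderate, n_severe, flags...)
# chosen so that full-capture emission reproduces the step exactly under the
# cascade (extras never cross a step boundary)


def _latent_burden(step: int, rng: np.random.Generator) -> dict:
    b = {
        "mild": 0,
        "moderate": 0,
        "severe": 0,
        "fampridine": False,
        "gait": False,
        "aid": None,
        "bed_confinement": False,
    }
    if step == 0:
        return b
    if step == 1:
        b["mild"] = 1
    elif step == 2:
        b["mild"] = 2 + int(rng.integers(0, 2))
    elif step == 3:
        b["moderate"] = 1 + int(rng.integers(0, 2))
        b["mild"] = int(rng.integers(0, 3))
    elif step == 4:
        route = rng.choice(["gait", "three_moderate", "fampridine"], p=[0.5, 0.3, 0.2])
        if route == "gait":
            b["gait"] = True
            b["moderate"] = int(rng.integers(0, 3))
            b["mild"] = int(rng.integers(0, 3))
        elif route == "three_moderate":
            b["moderate"] = 3
            b["mild"] = int(rng.integers(0, 3))
        else:
            b["fampridine"] = True
            b["mild"] = int(rng.integers(0, 3))
    elif step == 5:
        route = rng.choice(["severe", "four_moderate", "famp_moderate"], p=[0.5, 0.3, 0.2])
        if route == "severe":
            b["severe"] = 1
            b["moderate"] = int(rng.integers(0, 3))
        elif route == "four_moderate":
            b["moderate"] = 4
        else:
            b["fampridine"] = True
            b["moderate"] = 1 + int(rng.integers(0, 2))
    else:
        # ambulation-dominated steps carry an underlying symptom burden that
        # can never exceed step 5 on its own
        b["mild"] = int(rng.integers(0, 3))
        b["moderate"] = int(rng.integers(0, 3))
        b["severe"] = int(rng.integers(0, 2))
        if step == 6:
            b["aid"] = "walking_stick"
        elif step == 7:
            b["aid"] = "wheelchair"
        elif step == 8:
            b["aid"] = "chair_bed"
        else:
            b["bed_confinement"] = True
    return b


_SEV_KEY = {"mild": Severity.MILD, "moderate": Severity.MODERATE, "severe": Severity.SEVERE}
_AID_STEM_FIELD = {
    "walking_stick": "walking_stick_aid",
    "wheelchair": "wheelchair_aid",
    "chair_bed": "chair_bed_aid",
}


def _jitter(rng: np.random.Generator, index_date: dt.date, days: int) -> dt.date:
    if days == 0:
        return index_date
    return index_date + dt.timedelta(days=int(rng.integers(-days, days + 1)))


def _emit_dx(
    pid: str,
    code: str,
    index_date: dt.date,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[ClaimEvent]:
    """Emit qualifying-or-not diagnosis evidence for one captured symptom."""
    if rng.random() < cfg.inpatient_dx_prob:
        return [_inpatient(pid, _jitter(rng, index_date, cfg.window_jitter_days), code)]
    # outpatient route: two service contacts on distinct dates, each
    # independently carrying a confirmed qualifier or not
    d1 = _jitter(rng, index_date, cfg.window_jitter_days)
    d2 = d1 + dt.timedelta(days=1) if d1 < index_date else d1 - dt.timedelta(days=1)
    events = []
    for d in (d1, d2):
        q = (
            Qualifier.CONFIRMED
            if rng.random() < cfg.outpatient_confirmed_prob
            else Qualifier.SUSPECTED
        )
        events.append(
            ClaimEvent(pid, d, CodeSystem.ICD10GM, code, Setting.OUTPATIENT_DX, q)
        )
    return events


def _emit_measurement_events(
    pid: str,
    step: int,
    index_date: dt.date,
    catalog: SymptomCatalog,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[ClaimEvent]:
    burden = _latent_burden(step, rng)
    sp = catalog.special
    events: list[ClaimEvent] = []

    for key in ("mild", "moderate", "severe"):
        sev = _SEV_KEY[key]
        symptoms = _tier_symptoms(catalog, sev)
        n = burden[key]
        _require(
            len(symptoms) >= n,
            f"catalog lacks {n} distinct {key} diagnosis symptoms",
        )
        chosen = rng.choice(len(symptoms), size=n, replace=False) if n else []
        for i in chosen:
            symptom_id, code = symptoms[int(i)]
            if rng.random() < cfg.dx_capture[sev]:
                events.extend(_emit_dx(pid, code, index_date, cfg, rng))
            # associated drug/therapy emission, tied to the same severity
            drugs = [e for e in _tier_drugs(catalog, sev) if e.symptom_id == symptom_id]
            if not drugs:
                drugs = _tier_drugs(catalog, sev)
            if drugs and rng.random() < cfg.drug_emission[sev]:
                entry = drugs[0]
                setting = (
                    Setting.PRESCRIPTION
                    if entry.evidence_kind is EvidenceKind.MEDICATION
                    else Setting.PROCEDURE
                )
                events.append(
                    ClaimEvent(
                        pid,
                        _jitter(rng, index_date, cfg.window_jitter_days),
                        entry.code_system,
                        entry.code,
                        setting,
                    )
                )

    if burden["fampridine"]:
        events.append(
            ClaimEvent(
                pid,
                _jitter(rng, index_date, cfg.window_jitter_days),
                CodeSystem.ATC,
                sorted(sp.fampridine_atc)[0],
                Setting.PRESCRIPTION,
            )
        )
    if burden["gait"] and rng.random() < cfg.dx_capture[Severity.MODERATE]:
        events.extend(
            _emit_dx(pid, sorted(sp.gait_disturbance_icd)[0], index_date, cfg, rng)
        )
    if burden["aid"] is not None:
        if rng.random() < cfg.aid_capture[burden["aid"]]:
            stem = sorted(getattr(sp, _AID_STEM_FIELD[burden["aid"]]))[0]
            events.append(
                _aid(pid, _jitter(rng, index_date, cfg.window_jitter_days), stem)
            )
    if burden["bed_confinement"] and rng.random() < cfg.dx_capture[Severity.SEVERE]:
        events.extend(
            _emit_dx(pid, sorted(sp.bed_confinement_icd)[0], index_date, cfg, rng)
        )
    return events


def _score_for_step(step: int, rng: np.random.Generator) -> float:
    """A clinician EDSS value on the half-point grid that rescales to ``step``."""
    if step == 0:
        return 0.0
    if step <= 7:
        return step + 0.5 * int(rng.integers(0, 2))
    return float(step) + 0.5 * int(rng.integers(0, 2))  # 8.0/8.5 or 9.0/9.5


def _n_measures(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    n = 1 + rng.poisson(max(cfg.measures_mean - 1.0, 0.0))
    return int(np.clip(n, cfg.measures_min, cfg.measures_max))


def generate_cohort(
    config: GeneratorConfig, catalog: SymptomCatalog
) -> SyntheticCohort:
    """Generate a linked synthetic cohort, fully reproducible from the seed.

    Measurement dates within a patient are spaced by more than two window
    widths so each measurement's emitted events fall in exactly one
    assessment window.
    """
    rng = np.random.default_rng(config.seed)
    steps_support = np.arange(10)
    measures_rows = []
    all_events: list[ClaimEvent] = []
    coverage_rows = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        n_meas = _n_measures(config, rng)
        first = config.start_date + dt.timedelta(days=int(rng.integers(0, 366)))
        step = int(rng.choice(steps_support, p=config.edss_distribution))
        lo = 0 if step == 0 else 1
        date = first
        dates: list[dt.date] = []
        for k in range(n_meas):
            if k > 0:
                # persistence-dominated random walk on the latent step
                move = int(rng.choice([-1, 0, 0, 0, 0, 1]))
                step = int(np.clip(step + move, lo, 9))
                date = date + dt.timedelta(days=200 + int(rng.integers(0, 61)))
            dates.append(date)
            measures_rows.append(
                {
                    "patient_id": pid,
                    "date": date,
                    "score": _score_for_step(step, rng),
                    "true_step": step,
                }
            )
            all_events.extend(
                _emit_measurement_events(pid, step, date, catalog, config, rng)
            )
        coverage_rows.append(
            {
                "patient_id": pid,
                "start": min(dates) - dt.timedelta(days=180),
                "end": max(dates) + dt.timedelta(days=180),
            }
        )

    measures = pd.DataFrame(
        measures_rows, columns=["patient_id", "date", "score", "true_step"]
    )
    events = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "date": e.date,
                "code_system": e.code_system.value,
                "code": e.code,
                "setting": e.setting.value,
                "qualifier": e.qualifier.value,
            }
            for e in all_events
        ],
        columns=["patient_id", "date", "code_system", "code", "setting", "qualifier"],
    )
    coverage = pd.DataFrame(coverage_rows, columns=["patient_id", "start", "end"])
    deaths = pd.DataFrame(columns=["patient_id", "date"])
    return SyntheticCohort(measures, events, coverage, deaths)
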