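"""Windowing, diagnosis qualification, profile building, and the cascade."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedss.catalog import CodeSystem, SymptomCatalog
from pedss.engine import (
    CohortParams,
    CoverageInterval,
    Qualifier,
    Setting,
    SymptomProfile,
    build_profile,
    compute_pedss,
    compute_pedss_batch,
    qualify_diagnosis,
    select_cohort,
    select_window_events,
)

from conftest import INDEX, ev, outpatient_pair


class TestWindowing:
    def test_boundaries_inclusive(self, window):
        inside = [
            ev("H55", date=INDEX - dt.timedelta(days=90)),
            ev("H55", date=INDEX + dt.timedelta(days=90)),
        ]
        outside = [
            ev("H55", date=INDEX - dt.timedelta(days=91)),
            ev("H55", date=INDEX + dt.timedelta(days=91)),
        ]
        assert select_window_events(inside + outside, window) == inside

    def test_empty_input(self, window):
        assert select_window_events([], window) == []

    def test_order_preserved(self, window):
        events = [ev("H55"), ev("H49"), ev("R27.0")]
        assert select_window_events(events, window) == events

    def test_outside_events_never_influence_profile(self, catalog, window):
        """Perturbation: any event beyond the window leaves the profile alone."""
        base = [ev("H54.0")]
        far = ev("18.50.01", CodeSystem.AID, Setting.AID,
                 date=INDEX + dt.timedelta(days=120))
        p1 = build_profile(base, catalog, window)
        p2 = build_profile(base + [far], catalog, window)
        assert p1 == p2


class TestQualifyDiagnosis:
    def test_one_inpatient_qualifies(self):
        assert qualify_diagnosis([ev("G82.12")], {"G82.12"})

    def test_two_confirmed_outpatient_distinct_dates_qualify(self):
        assert qualify_diagnosis(outpatient_pair("R26.0"), {"R26.0"})

    def test_same_date_outpatient_pair_does_not_qualify(self):
        events = [
            ev("R26.0", setting=Setting.OUTPATIENT_DX, qualifier=Qualifier.CONFIRMED),
            ev("R26.0", setting=Setting.OUTPATIENT_DX, qualifier=Qualifier.CONFIRMED),
        ]
        assert not qualify_diagnosis(events, {"R26.0"})

    def test_confirmed_plus_suspected_does_not_qualify(self):
        events = [
            ev("R26.0", setting=Setting.OUTPATIENT_DX, qualifier=Qualifier.CONFIRMED),
            ev("R26.0", setting=Setting.OUTPATIENT_DX, qualifier=Qualifier.SUSPECTED,
               date=INDEX + dt.timedelta(days=5)),
        ]
        assert not qualify_diagnosis(events, {"R26.0"})

    def test_distinct_quarter_variant_is_stricter(self):
        same_quarter = outpatient_pair("G35", date=dt.date(2017, 4, 2))
        assert qualify_diagnosis(same_quarter, {"G35"})
        assert not qualify_diagnosis(
            same_quarter, {"G35"}, require_distinct_quarters=True
        )


class TestBuildProfile:
    def test_single_aid_event_sets_wheelchair(self, catalog, window):
        prof = build_profile(
            [ev("18.51.02", CodeSystem.AID, Setting.AID)], catalog, window
        )
        assert prof.wheelchair and not prof.walking_stick

    def test_fampridine_prescription_only(self, catalog, window):
        prof = build_profile(
            [ev("N07XX07", CodeSystem.ATC, Setting.PRESCRIPTION)], catalog, window
        )
        assert prof.fampridine
        assert not (prof.mild_dx_symptoms | prof.moderate_dx_symptoms
                    | prof.severe_dx_symptoms)

    def test_inpatient_tetraplegia_flag(self, catalog, window):
        prof = build_profile([ev("G82.42")], catalog, window)
        assert prof.tetraplegia_dx and not prof.paraplegia_dx

    def test_gait_disturbance_needs_qualified_diagnosis(self, catalog, window):
        one = [ev("R26.0", setting=Setting.OUTPATIENT_DX, qualifier=Qualifier.CONFIRMED)]
        assert not build_profile(one, catalog, window).gait_disturbance_dx
        assert build_profile(
            outpatient_pair("R26.0"), catalog, window
        ).gait_disturbance_dx

    def test_symptom_counted_once_at_highest_severity(self, catalog, window):
        """Spasticity with mild-tier dx evidence and a severe-tier association
        must not appear in two severity sets."""
        # same symptom id at two diagnosis tiers
        from pedss.catalog import CodeEntry
        cat = SymptomCatalog(
            entries=(
                CodeEntry("R25.2", "ICD10GM", "prefix", "spasticity",
                          "pyramidal", "mild", "diagnosis"),
                CodeEntry("G82.10", "ICD10GM", "exact", "spasticity",
                          "pyramidal", "severe", "diagnosis"),
            ),
        )
        prof = build_profile([ev("R25.2"), ev("G82.10")], cat, window)
        assert prof.severe_dx_symptoms == {"spasticity"}
        assert not prof.mild_dx_symptoms

    def test_distinct_drug_codes_counted_once_each(self, catalog, window):
        events = [
            ev("M03BX01", CodeSystem.ATC, Setting.PRESCRIPTION),
            ev("M03BX01", CodeSystem.ATC, Setting.PRESCRIPTION,
               date=INDEX + dt.timedelta(days=3)),
            ev("G04BD04", CodeSystem.ATC, Setting.PRESCRIPTION),
        ]
        prof = build_profile(events, catalog, window)
        assert prof.moderate_drug_count == 2

    def test_unvalidated_catalog_rejected(self, window):
        with pytest.raises(Exception):
            build_profile([], object(), window)


def oracle_pedss(p: SymptomProfile) -> int:
    """Independent oracle: evaluate every step predicate on its own and take
    the maximum satisfied step (0 if none)."""
    n_mild, n_mod, n_sev = (
        len(p.mild_dx_symptoms), len(p.moderate_dx_symptoms), len(p.severe_dx_symptoms)
    )
    preds = {
        9: p.bed_confinement_dx and p.alive_at_period_end,
        8: p.chair_bed or p.tetraplegia_dx,
        7: p.wheelchair or p.paraplegia_dx,
        6: p.walking_stick,
        5: n_sev >= 1 or p.severe_drug_count >= 1 or n_mod >= 4
           or (p.fampridine and (n_mod >= 1 or n_sev >= 1)),
        4: n_mod >= 3 or p.moderate_drug_count >= 3 or p.gait_disturbance_dx
           or (p.fampridine and n_mod == 0 and n_sev == 0),
        3: (1 <= n_mod <= 2 or 1 <= p.moderate_drug_count <= 2) and not p.fampridine,
        2: n_mild >= 2 and not p.fampridine,
        1: (n_mild == 1 or p.mild_drug_count >= 1) and not p.fampridine,
    }
    satisfied = [s for s, ok in preds.items() if ok]
    return max(satisfied) if satisfied else 0


MILD_SETS = [frozenset(f"m{i}" for i in range(k)) for k in range(6)]
MOD_SETS = [frozenset(f"o{i}" for i in range(k)) for k in range(6)]
SEV_SETS = [frozenset(f"v{i}" for i in range(k)) for k in range(6)]

profile_strategy = st.builds(
    SymptomProfile,
    mild_dx_symptoms=st.sampled_from(MILD_SETS),
    moderate_dx_symptoms=st.sampled_from(MOD_SETS),
    severe_dx_symptoms=st.sampled_from(SEV_SETS),
    mild_drug_count=st.integers(0, 4),
    moderate_drug_count=st.integers(0, 4),
    severe_drug_count=st.integers(0, 4),
    fampridine=st.booleans(),
    gait_disturbance_dx=st.booleans(),
    walking_stick=st.booleans(),
    wheelchair=st.booleans(),
    paraplegia_dx=st.booleans(),
    tetraplegia_dx=st.booleans(),
    chair_bed=st.booleans(),
    bed_confinement_dx=st.booleans(),
    alive_at_period_end=st.booleans(),
)


class TestCascade:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            (SymptomProfile(), 0),
            (SymptomProfile(fampridine=True), 4),
            (SymptomProfile(wheelchair=True, tetraplegia_dx=True), 8),
            (SymptomProfile(moderate_dx_symptoms=MOD_SETS[4]), 5),
            (SymptomProfile(moderate_dx_symptoms=MOD_SETS[3]), 4),
            (SymptomProfile(moderate_dx_symptoms=MOD_SETS[2]), 3),
            (SymptomProfile(mild_dx_symptoms=MILD_SETS[2]), 2),
            (SymptomProfile(mild_dx_symptoms=MILD_SETS[2], fampridine=True), 4),
            (SymptomProfile(mild_dx_symptoms=MILD_SETS[1]), 1),
            (SymptomProfile(mild_drug_count=2), 1),
            (SymptomProfile(severe_drug_count=1), 5),
            (SymptomProfile(gait_disturbance_dx=True), 4),
            (SymptomProfile(walking_stick=True), 6),
            (SymptomProfile(bed_confinement_dx=True), 9),
            (SymptomProfile(bed_confinement_dx=True, alive_at_period_end=False), 0),
            (SymptomProfile(fampridine=True, moderate_dx_symptoms=MOD_SETS[1]), 5),
        ],
    )
    def test_step_assignments(self, profile, expected):
        result = compute_pedss(profile)
        assert result.pedss == expected == result.fired_step
        assert result.fired_clause

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(profile=profile_strategy)
    def test_cascade_equals_max_over_predicates(self, profile):
        assert compute_pedss(profile).pedss == oracle_pedss(profile)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(profile=profile_strategy)
    def test_aid_monotonicity(self, profile):
        """Adding a wheelchair never drops below 7; chair/bed never below 8
        (alive, no bed confinement)."""
        import dataclasses

        alive = dataclasses.replace(
            profile, alive_at_period_end=True, bed_confinement_dx=False
        )
        with_wc = dataclasses.replace(alive, wheelchair=True)
        with_cb = dataclasses.replace(alive, chair_bed=True)
        assert compute_pedss(with_wc).pedss >= 7
        assert compute_pedss(with_cb).pedss >= 8
        assert compute_pedss(with_wc).pedss >= compute_pedss(alive).pedss

    def test_determinism_including_clause(self):
        p = SymptomProfile(moderate_dx_symptoms=MOD_SETS[2], fampridine=True)
        r1 = compute_pedss(p, "x", INDEX)
        r2 = compute_pedss(p, "x", INDEX)
        assert r1 == r2


class TestBatch:
    def test_two_index_dates_independent(self, catalog):
        d1, d2 = dt.date(2016, 3, 1), dt.date(2017, 3, 1)
        events = {
            "p1": [
                ev("18.51.02", CodeSystem.AID, Setting.AID, date=d1),
                ev("N07XX07", CodeSystem.ATC, Setting.PRESCRIPTION, date=d2),
            ]
        }
        results, flagged = compute_pedss_batch(events, {"p1": [d1, d2]}, catalog)
        assert [r.pedss for r in results] == [7, 4]
        assert not flagged

    def test_insufficient_coverage_flagged_not_dropped(self, catalog):
        coverage = {
            "p1": [CoverageInterval("p1", INDEX - dt.timedelta(days=30),
                                    INDEX + dt.timedelta(days=400))]
        }
        results, flagged = compute_pedss_batch(
            {"p1": []}, {"p1": [INDEX]}, catalog, coverage=coverage
        )
        assert results == []
        assert len(flagged) == 1 and "coverage" in flagged[0].reason

    def test_adjacent_coverage_intervals_merge(self, catalog):
        coverage = {
            "p1": [
                CoverageInterval("p1", INDEX - dt.timedelta(days=400), INDEX),
                CoverageInterval("p1", INDEX + dt.timedelta(days=1),
                                 INDEX + dt.timedelta(days=400)),
            ]
        }
        results, flagged = compute_pedss_batch(
            {"p1": []}, {"p1": [INDEX]}, catalog, coverage=coverage
        )
        assert len(results) == 1 and not flagged

    def test_death_before_study_end_blocks_step_9(self, catalog):
        events = {"p1": [ev("R26.3")], "p2": [ev("R26.3", patient_id="p2")]}
        results, _ = compute_pedss_batch(
            events,
            {"p1": [INDEX], "p2": [INDEX]},
            catalog,
            deaths={"p1": dt.date(2017, 12, 1)},
            study_end=dt.date(2018, 6, 30),
        )
        by_id = {r.patient_id: r.pedss for r in results}
        assert by_id["p1"] == 0 and by_id["p2"] == 9

    def test_empty_input(self, catalog):
        assert compute_pedss_batch({}, {}, catalog) == ([], [])


class TestSelectCohort:
    params = CohortParams()

    def _full_coverage(self, pid):
        return [CoverageInterval(pid, dt.date(2015, 1, 1), dt.date(2019, 1, 1))]

    def test_qualifying_patient_included(self):
        events = {"p1": outpatient_pair("G35.1", date=dt.date(2016, 9, 1))}
        cohort, attrition = select_cohort(
            {"p1": 1970}, events, {"p1": self._full_coverage("p1")}, self.params
        )
        assert cohort == [("p1", dt.date(2016, 9, 1))]
        assert sum(attrition.values()) == 0

    def test_single_suspected_outpatient_excluded_at_case_rule(self):
        events = {
            "p1": [ev("G35", setting=Setting.OUTPATIENT_DX,
                      qualifier=Qualifier.SUSPECTED, date=dt.date(2016, 9, 1))]
        }
        cohort, attrition = select_cohort(
            {"p1": 1970}, events, {"p1": self._full_coverage("p1")}, self.params
        )
        assert cohort == [] and attrition["ms_case_rule"] == 1

    def test_death_in_followup_excluded_at_final_filter(self):
        index = dt.date(2016, 9, 1)
        events = {"p1": outpatient_pair("G35.1", date=index)}
        coverage = {"p1": [CoverageInterval("p1", dt.date(2015, 1, 1),
                                            dt.date(2017, 3, 1))]}
        cohort, attrition = select_cohort(
            {"p1": 1970}, events, coverage, self.params,
            deaths={"p1": dt.date(2017, 3, 1)},  # ~6 months post-index
        )
        assert cohort == [] and attrition["died_in_followup"] == 1

    def test_minor_excluded(self):
        events = {"p1": outpatient_pair("G35.1", date=dt.date(2016, 9, 1))}
        cohort, attrition = select_cohort(
            {"p1": 2005}, events, {"p1": self._full_coverage("p1")}, self.params
        )
        assert cohort == [] and attrition["not_adult"] == 1

    def test_pregnancy_code_excluded(self):
        events = {
            "p1": outpatient_pair("G35.1", date=dt.date(2016, 9, 1))
            + [ev("O24.4", date=dt.date(2017, 1, 1))]
        }
        cohort, attrition = select_cohort(
            {"p1": 1970}, events, {"p1": self._full_coverage("p1")}, self.params
        )
        assert cohort == [] and attrition["exclusion_diagnosis"] == 1

    def test_coverage_gap_excluded(self):
        events = {"p1": outpatient_pair("G35.1", date=dt.date(2016, 9, 1))}
        coverage = {"p1": [CoverageInterval("p1", dt.date(2016, 1, 1),
                                            dt.date(2017, 1, 1))]}
        cohort, attrition = select_cohort({"p1": 1970}, events, coverage, self.params)
        assert cohort == [] and attrition["coverage_gap"] == 1

    def test_inconsistent_period_parameters_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(inclusion_start=dt.date(2018, 1, 1),
                         inclusion_end=dt.date(2017, 1, 1))
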