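"""Tests for new-user cohort construction: washout, eligibility, follow-up."""

import datetime as dt

import pytest

from dkaval.claims_model import ClaimsDatabase
from dkaval.cohort_builder import (
    CohortConfig,
    build_cohort,
    check_eligibility,
    compute_followup,
    find_qualifying_fills,
    age_in_years,
)
from dkaval.synthetic_data import SimulationConfig, generate_population, paper_fixture

D = dt.date
CFG = CohortConfig()


class TestQualifyingFills:
    def test_single_fill_qualifies_vacuously(self):
        fills = [(D(2000, 5, 1), "antipsychotic", 30)]
        out = find_qualifying_fills(fills, CFG)
        assert out == [(D(2000, 5, 1), "antipsychotic", "antipsychotic")]

    def test_fill_200_days_after_prior_does_not_qualify(self):
        fills = [
            (D(2000, 1, 1), "antidepressant", 30),
            (D(2000, 7, 19), "antipsychotic", 30),  # 200 days later
        ]
        out = find_qualifying_fills(fills, CFG)
        assert [f[0] for f in out] == [D(2000, 1, 1)]

    def test_fill_400_days_after_prior_qualifies(self):
        fills = [
            (D(2000, 1, 1), "adhd_drug", 30),
            (D(2001, 2, 4), "antipsychotic", 30),  # 400 days later
        ]
        out = find_qualifying_fills(fills, CFG)
        assert [f[0] for f in out] == [D(2000, 1, 1), D(2001, 2, 4)]

    def test_control_class_maps_to_control_group(self):
        fills = [(D(2000, 5, 1), "benzodiazepine", 30)]
        assert find_qualifying_fills(fills, CFG)[0][2] == "control"

    def test_other_class_never_qualifies(self):
        fills = [(D(2000, 5, 1), "other", 30)]
        assert find_qualifying_fills(fills, CFG) == []

    def test_90day_clause_toggle(self):
        # a non-study fill 120 days prior breaks the literal 90-day clause
        fills = [
            (D(2000, 1, 1), "other", 30),
            (D(2000, 4, 30), "antipsychotic", 30),
        ]
        assert len(find_qualifying_fills(fills, CFG)) == 1
        strict = CohortConfig(require_90day_free=True)
        assert find_qualifying_fills(fills, strict) == []


class TestEligibility:
    def test_clean_fixture_member_is_eligible(self):
        db, _ = paper_fixture()
        qdate = db.pharmacy[db.pharmacy["person_id"] == "F01"]["fill_date"].min()
        result = check_eligibility("F01", qdate, db, CFG)
        assert result.eligible and result.failed_criteria == []

    def test_failures_are_named_and_exhaustive(self):
        db, truth = generate_population(
            SimulationConfig(n_persons=200, seed=3, ineligible_fraction=0.4)
        )
        fills = db.pharmacy.groupby("person_id")["fill_date"].min()
        by_mode = dict(
            zip(truth.ineligible["person_id"], truth.ineligible["violated_criterion"])
        )
        expected_failure = {
            "washout_violation": None,  # fails washout, not eligibility
            "age": "age",
            "recent_hospitalization": "recent_hospitalization",
            "baseline_diabetes": "dx_diabetes",
            "enrollment_gap": "enrollment_gap",
        }
        checked = set()
        for pid, mode in by_mode.items():
            want = expected_failure[mode]
            if want is None:
                continue
            result = check_eligibility(pid, fills[pid], db, CFG)
            assert want in result.failed_criteria, (pid, mode, result.failed_criteria)
            checked.add(mode)
        assert checked >= {"age", "recent_hospitalization", "baseline_diabetes"}

    def test_age_25_fails_age_criterion(self):
        db, _ = paper_fixture()
        # shift the qualifying date far enough that F01 (11 at entry) is 25
        qdate = db.pharmacy[db.pharmacy["person_id"] == "F01"]["fill_date"].min()
        late = qdate + dt.timedelta(days=15 * 365)
        result = check_eligibility("F01", late, db, CFG)
        assert "age" in result.failed_criteria

    def test_missing_person_raises(self):
        db, _ = paper_fixture()
        with pytest.raises(Exception, match="GHOST"):
            check_eligibility("GHOST", D(2000, 1, 1), db, CFG)


class TestFollowup:
    def _single_person_db(self, death=None, enroll_end=D(2007, 12, 31)):
        import pandas as pd
        from dkaval.claims_model import (
            PERSON_COLUMNS, ENROLLMENT_COLUMNS, PHARMACY_COLUMNS,
            ENCOUNTER_COLUMNS, DEATH_COLUMNS,
        )

        persons = pd.DataFrame(
            [{"person_id": "A", "birth_date": D(1990, 6, 15), "gender": "male",
              "race": "caucasian", "urban": True, "adhd_dx": False}],
            columns=PERSON_COLUMNS,
        )
        enrollment = pd.DataFrame(
            [{"person_id": "A", "start_date": D(1999, 1, 1), "end_date": enroll_end}],
            columns=ENROLLMENT_COLUMNS,
        )
        pharmacy = pd.DataFrame(
            [{"person_id": "A", "fill_date": D(2000, 6, 1),
              "drug_class": "antipsychotic", "days_supply": 30}],
            columns=PHARMACY_COLUMNS,
        )
        deaths = pd.DataFrame(
            [] if death is None else [{"person_id": "A", "death_date": death}],
            columns=DEATH_COLUMNS,
        )
        return ClaimsDatabase(
            persons=persons, enrollment=enrollment, pharmacy=pharmacy,
            encounters=pd.DataFrame(columns=ENCOUNTER_COLUMNS), deaths=deaths,
        )

    def test_death_terminates_first(self):
        db = self._single_person_db(death=D(2000, 9, 9))
        end, reason = compute_followup("A", D(2000, 6, 1), db, CFG)
        assert (end, reason) == (D(2000, 9, 9), "death")

    def test_use_lapse_365_days_after_last_supply_day(self):
        db = self._single_person_db()
        end, reason = compute_followup("A", D(2000, 6, 1), db, CFG)
        # last covered day = 2000-06-30; + 365 days = 2001-06-30
        assert (end, reason) == (D(2001, 6, 30), "use_lapse")

    def test_disenrollment_caps_followup(self):
        db = self._single_person_db(enroll_end=D(2000, 8, 1))
        end, reason = compute_followup("A", D(2000, 6, 1), db, CFG)
        assert (end, reason) == (D(2000, 8, 1), "disenrollment")

    def test_tie_precedence_death_over_disenrollment(self):
        db = self._single_person_db(death=D(2000, 8, 1), enroll_end=D(2000, 8, 1))
        _, reason = compute_followup("A", D(2000, 6, 1), db, CFG)
        assert reason == "death"

    def test_followup_never_passes_25th_birthday(self):
        db = self._single_person_db()
        db.persons.loc[0, "birth_date"] = D(1976, 6, 15)  # turns 25 during use window
        end, reason = compute_followup("A", D(2000, 6, 1), db, CFG)
        assert (end, reason) == (D(2001, 6, 14), "age_25")


class TestBuildCohort:
    def test_fixture_cohort_contains_all_30_case_persons(self):
        db, _ = paper_fixture()
        members = build_cohort(db)
        assert sorted(m.person_id for m in members) == sorted(db.persons["person_id"])

    def test_no_fills_means_empty_cohort(self):
        db = ClaimsDatabase.empty()
        assert build_cohort(db) == []

    def test_members_sorted_by_person_id(self):
        db, _ = generate_population(SimulationConfig(n_persons=50, seed=5))
        members = build_cohort(db)
        ids = [m.person_id for m in members]
        assert ids == sorted(ids)

    def test_washout_holds_by_brute_force_rescan(self):
        """Independent re-scan: no member has a study-drug fill in the 365
        days before qualification, and no inpatient stay overlapping the
        prior 30 days."""
        for seed in (0, 1, 2):
            db, _ = generate_population(SimulationConfig(n_persons=150, seed=seed))
            members = build_cohort(db)
            assert members, "generator should yield eligible members"
            for m in members:
                q = m.qualifying_fill_date
                fills = db.pharmacy[db.pharmacy["person_id"] == m.person_id]
                for row in fills.itertuples(index=False):
                    if row.drug_class == "other":
                        continue
                    gap = (q - row.fill_date).days
                    assert not (1 <= gap <= 365), (m.person_id, row.fill_date)
                enc = db.encounters[
                    (db.encounters["person_id"] == m.person_id)
                    & (db.encounters["setting"] == "inpatient")
                ]
                for row in enc.itertuples(index=False):
                    overlap = row.start_date <= q - dt.timedelta(days=1) and (
                        row.end_date >= q - dt.timedelta(days=30)
                    )
                    assert not overlap, (m.person_id, row.start_date)

    def test_followup_respects_death_and_birthday(self):
        db, _ = generate_population(SimulationConfig(n_persons=200, seed=11))
        birth = dict(zip(db.persons["person_id"], db.persons["birth_date"]))
        deaths = dict(zip(db.deaths["person_id"], db.deaths["death_date"]))
        for m in build_cohort(db):
            assert m.followup_start == m.qualifying_fill_date + dt.timedelta(days=1)
            assert m.followup_start <= m.followup_end
            assert age_in_years(birth[m.person_id], m.followup_end) <= 24
            if m.person_id in deaths:
                assert m.followup_end <= deaths[m.person_id]

    def test_locality_claims_after_followup_end_change_nothing(self):
        db, _ = paper_fixture()
        before = build_cohort(db)
        member = before[0]
        # add an outpatient claim well after this member's follow-up end
        late = member.followup_end + dt.timedelta(days=100)
        db.encounters.loc[len(db.encounters)] = {
            "encounter_id": 99999,
            "person_id": member.person_id,
            "setting": "outpatient",
            "start_date": late,
            "end_date": late,
            "dx_codes": (("V22.1", "icd9"),),
        }
        after = build_cohort(db)
        assert [m for m in after if m.person_id == member.person_id][0] == member
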