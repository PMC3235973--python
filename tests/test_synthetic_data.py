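"""Tests for the synthetic claims generator and the packaged fixture."""

import numpy as np
import pytest
from scipy.stats import binom

from dkaval.adjudicator import adjudicate_all, meets_acidosis
from dkaval.cohort_builder import build_cohort
from dkaval.case_finder import find_potential_cases
from dkaval.pipeline import run_validation
from dkaval.synthetic_data import (
    SimulationConfig,
    generate_abstractions,
    generate_population,
    paper_fixture,
)


class TestGeneratePopulation:
    def test_same_seed_identical_outputs(self, tmp_path):
        from dkaval.claims_model import write_claims_db

        cfg = SimulationConfig(n_persons=80, seed=42)
        db1, truth1 = generate_population(cfg)
        db2, truth2 = generate_population(cfg)
        assert db1.equals(db2)
        assert truth1.cases.equals(truth2.cases)
        assert truth1.ineligible.equals(truth2.ineligible)
        # byte-identical on disk
        write_claims_db(db1, tmp_path / "a")
        write_claims_db(db2, tmp_path / "b")
        for name in ("persons", "pharmacy", "encounters"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
                tmp_path / "b" / f"{name}.csv"
            ).read_bytes()

    def test_zero_persons_gives_empty_tables(self):
        db, truth = generate_population(SimulationConfig(n_persons=0))
        assert all(len(t) == 0 for t in db.tables().values())
        assert len(truth.cases) == 0 and len(truth.ineligible) == 0

    def test_database_passes_integrity_checks(self):
        db, _ = generate_population(SimulationConfig(n_persons=100, seed=9))
        db.validate()

    def test_every_person_has_enrollment(self):
        db, _ = generate_population(SimulationConfig(n_persons=100, seed=9))
        assert set(db.persons["person_id"]) == set(db.enrollment["person_id"])

    def test_flagged_cases_carry_inpatient_dka_encounter(self):
        db, truth = generate_population(SimulationConfig(n_persons=150, seed=4))
        from dkaval.case_finder import DKA_CODES
        from dkaval.claims_model import any_code_matches

        inpatient = db.encounters[db.encounters["setting"] == "inpatient"]
        for row in truth.cases.itertuples(index=False):
            mine = inpatient[inpatient["person_id"] == row.person_id]
            assert any(
                any_code_matches(dx, DKA_CODES) for dx in mine["dx_codes"]
            ), row.person_id

    def test_truth_fraction_is_binomial_at_true_ppv(self):
        """Over several seeds, the confirmed-truth fraction stays inside a
        99.9% binomial band around true_ppv (distributional oracle)."""
        p = 0.85
        total_true = total = 0
        for seed in range(10):
            _, truth = generate_population(
                SimulationConfig(n_persons=200, true_ppv=p, seed=seed)
            )
            total += len(truth.cases)
            total_true += int(truth.cases["is_true_dka"].sum())
        lo, hi = binom.ppf([0.0005, 0.9995], total, p)
        assert lo <= total_true <= hi

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(true_ppv=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(age_range=(3, 24))
        with pytest.raises(ValueError):
            SimulationConfig(
                false_positive_mode_weights={"hyperglycemia_no_acidosis": 0.5}
            )

    def test_ineligible_persons_are_not_in_cohort(self):
        db, truth = generate_population(
            SimulationConfig(n_persons=150, seed=13, ineligible_fraction=0.3)
        )
        member_ids = {m.person_id for m in build_cohort(db)}
        assert member_ids.isdisjoint(set(truth.ineligible["person_id"]))


class TestGenerateAbstractions:
    def test_truth_consistency_under_adjudication(self):
        """With the default separated lab distributions, the deterministic
        rule confirms exactly the truth-labelled cases."""
        cfg = SimulationConfig(
            n_persons=300,
            seed=21,
            true_ppv=0.8,
            false_positive_mode_weights={
                "hyperglycemia_no_acidosis": 0.7,
                "coding_error": 0.3,
            },
        )
        _, truth = generate_population(cfg)
        records = generate_abstractions(truth, cfg)
        adjudicated, _ = adjudicate_all(records)
        labels = dict(zip(truth.cases["person_id"], truth.cases["is_true_dka"]))
        for row in adjudicated.itertuples(index=False):
            assert row.confirmed == labels[row.person_id]

    def test_false_mode_lab_patterns(self):
        cfg = SimulationConfig(
            n_persons=400,
            seed=8,
            true_ppv=0.5,
            false_positive_mode_weights={
                "hyperglycemia_no_acidosis": 0.5,
                "coding_error": 0.5,
            },
            unabstractable_fraction=0.0,
        )
        _, truth = generate_population(cfg)
        records = {r.person_id: r for r in generate_abstractions(truth, cfg)}
        for row in truth.cases.itertuples(index=False):
            rec = records[row.person_id]
            if row.is_true_dka:
                assert rec.glucose_mg_dl > 250 and meets_acidosis(rec)
            elif row.error_mode == "hyperglycemia_no_acidosis":
                assert rec.glucose_mg_dl > 250 and not meets_acidosis(rec)
            else:
                assert rec.glucose_mg_dl <= 250

    def test_unabstractable_fraction_roughly_respected(self):
        cfg = SimulationConfig(n_persons=400, seed=3, unabstractable_fraction=0.1)
        _, truth = generate_population(cfg)
        records = generate_abstractions(truth, cfg)
        frac = np.mean([not r.complete for r in records])
        assert 0.02 <= frac <= 0.25

    def test_parameter_recovery_small(self):
        """Pipeline PPV estimate tracks the generating true_ppv."""
        cfg = SimulationConfig(n_persons=800, seed=17, true_ppv=0.85)
        db, truth = generate_population(cfg)
        records = generate_abstractions(truth, cfg)
        result = run_validation(db, records, with_strata=False)
        assert result.overall.ppv == pytest.approx(0.85, abs=0.06)


class TestPaperFixture:
    def test_counts(self, fixture_db_and_abstractions):
        db, records = fixture_db_and_abstractions
        assert len(db.persons) == 30
        statuses = [r.abstraction_status for r in records]
        assert statuses.count("record_not_located") == 2
        assert statuses.count("facility_refused") == 1
        assert statuses.count("complete") == 27

    def test_all_strata_margins_hold_simultaneously(self, fixture_pipeline):
        by = {(r.rule, r.label): (r.x, r.n) for r in fixture_pipeline.strata}
        assert by[("exposure", "antipsychotic")] == (5, 6)
        assert by[("exposure", "control")] == (19, 21)
        assert by[("age", "upper (11-24 years)")] == (17, 17)
        assert by[("age", "lower (<=10 years)")] == (7, 10)
        assert by[("gender", "male")] == (14, 14)
        assert by[("gender", "female")] == (10, 13)
        assert by[("adhd", "yes")] == (12, 15)
        assert by[("adhd", "no")] == (12, 12)

    def test_deterministic(self):
        db1, rec1 = paper_fixture()
        db2, rec2 = paper_fixture()
        assert db1.equals(db2) and rec1 == rec2
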