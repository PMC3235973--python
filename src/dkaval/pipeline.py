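"""End-to-end composition: claims → cohort → cases → adjudication → PPV."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .adjudicator import AbstractedRecord, adjudicate_all
from .case_finder import CaseFinderConfig, PotentialCase, find_potential_cases
from .claims_model import ClaimsDatabase
from .cohort_builder import CohortConfig, build_cohort
from .validation_stats import StratumResult, compute_ppv, stratified_ppv

__all__ = ["PipelineResult", "run_validation"]


@dataclasses.dataclass
class PipelineResult:
    cases: list[PotentialCase]
    adjudicated: pd.DataFrame
    not_abstractable: list[str]
    overall: StratumResult
    strata: list[StratumResult]

    @property
    def n_potential(self) -> int:
        return len(self.cases)

    @property
    def n_adjudicated(self) -> int:
        return int(len(self.adjudicated))

    @property
    def n_confirmed(self) -> int:
        return int(self.adjudicated["confirmed"].sum())


def run_validation(
    db: ClaimsDatabase,
    abstractions: Sequence[AbstractedRecord],
    cohort_config: CohortConfig | None = None,
    case_config: CaseFinderConfig | None = None,
    policy: str = "strict",
    with_strata: bool = True,
) -> PipelineResult:
    """Run the whole validation pipeline on one claims database.

    Only abstraction records whose person was actually flagged by the
    computer case definition enter the adjudicated set, so the PPV
    denominator is exactly the abstractable flagged cases.
    """
    cohort = build_cohort(db, cohort_config)
    cases = find_potential_cases(cohort, db, case_config)
    flagged_ids = {c.person_id for c in cases}
    flagged_records = [r for r in abstractions if r.person_id in flagged_ids]
    adjudicated, skipped = adjudicate_all(flagged_records, policy=policy)
    overall = compute_ppv(adjudicated)
    strata = stratified_ppv(adjudicated) if with_strata else []
    return PipelineResult(
        cases=cases,
        adjudicated=adjudicated,
        not_abstractable=skipped,
        overall=overall,
        strata=strata,
    )
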