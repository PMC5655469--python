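"""End-to-end orchestration: inputs → cohort simulation → burden tables."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .burden import build_burden_tables
from .health_states import NonOAPainCurve, PainModelParams, UtilityTable
from .microsim import NO_OA, OA, CohortResult, ModelTables, simulate_cohort
from .strata import STRATA, Stratum
from .tables import LifeTable, PopulationCounts, PrevalenceTable

CohortResults = dict[tuple[Stratum, str], CohortResult]


@dataclass(frozen=True)
class PipelineInputs:
    """Everything one burden run needs, with the simulation settings."""

    utilities: UtilityTable
    life_table: LifeTable
    pain_curve: NonOAPainCurve
    prevalence: PrevalenceTable
    population: PopulationCounts
    pain_params: PainModelParams = field(default_factory=PainModelParams)
    n_per_stratum: int = 2000
    seed: int = 0

    @property
    def tables(self) -> ModelTables:
        return ModelTables(
            utilities=self.utilities, life_table=self.life_table, pain_curve=self.pain_curve
        )

    def with_(self, **changes) -> "PipelineInputs":
        return replace(self, **changes)


def simulate_all_cohorts(
    inputs: PipelineInputs,
    statuses: tuple[str, ...] = (OA, NO_OA),
    moderate_share: float | None = None,
    n: int | None = None,
) -> CohortResults:
    """Simulate the requested cohorts for all 36 entry strata.

    Each cohort starts at its band's midpoint age.  Restricting ``statuses``
    lets sensitivity analyses re-run only the cohorts a parameter touches.
    """
    n_sim = inputs.n_per_stratum if n is None else n
    results: CohortResults = {}
    for stratum in STRATA:
        for status in statuses:
            results[(stratum, status)] = simulate_cohort(
                stratum, status, n_sim, inputs.tables, inputs.pain_params,
                seed=inputs.seed, moderate_share=moderate_share,
            )
    return results


def run_burden(
    inputs: PipelineInputs, cohort_results: CohortResults | None = None
) -> tuple[CohortResults, pd.DataFrame]:
    """Simulate (if needed) and build the stratified burden table."""
    if cohort_results is None:
        cohort_results = simulate_all_cohorts(inputs)
    burden = build_burden_tables(cohort_results, inputs.prevalence, inputs.population)
    return cohort_results, burden


def cohort_results_frame(results: CohortResults) -> pd.DataFrame:
    """Tidy frame of per-cohort Monte Carlo summaries."""
    rows = [
        {
            "ethnicity": s.ethnicity, "sex": s.sex, "age_band": s.age_band,
            "oa_status": status, "n": r.n_simulated,
            "mean_qalys": r.mean_qalys, "se_qalys": r.se_qalys,
        }
        for (s, status), r in sorted(
            results.items(), key=lambda kv: (STRATA.index(kv[0][0]), kv[0][1])
        )
    ]
    return pd.DataFrame(rows)
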