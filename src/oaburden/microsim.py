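"""Annual-cycle Monte Carlo microsimulation of individual life histories.

Each simulated individual starts at a given age with or without knee OA and
passes through annual cycles until death or the life-table closure age.  In
every cycle the pain level is resolved (for OA: the WOMAC score progresses
and is categorised; for non-OA: a level drawn once per 5-year band from the
background pain curve), the age- and pain-specific utility is accrued for
the year begun, and death is applied at year end using the annualised
life-table probability.  QALYs lived are the sum of the per-year utilities;
no discounting or half-cycle correction is applied.

Randomness is organised so that cohorts sharing a master seed share common
random numbers: every cohort draws its mortality uniforms, baseline WOMAC
scores, annual increments and per-band pain uniforms in a fixed order from
a stream keyed only by (seed, stratum, start age).  OA and no-OA cohorts,
and sensitivity-analysis re-runs with different pain-split parameters,
therefore see identical underlying noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ParameterError
from .health_states import (
    NonOAPainCurve,
    PainLevel,
    PainModelParams,
    UtilityTable,
    categorize_pain_array,
    levels_from_uniforms,
)
from .strata import MODEL_END_AGE, Stratum, band_for_age, stratum_index
from .tables import LifeTable

OA = "oa"
NO_OA = "no_oa"
OA_STATUSES = (OA, NO_OA)


@dataclass(frozen=True)
class ModelTables:
    """Bundle of the lookup tables a simulation run needs."""

    utilities: UtilityTable
    life_table: LifeTable
    pain_curve: NonOAPainCurve


@dataclass(frozen=True)
class CohortResult:
    """Monte Carlo summary for one simulated cohort."""

    stratum: Stratum
    oa_status: str
    n_simulated: int
    mean_qalys: float
    se_qalys: float


def annual_mortality(p5: float) -> float:
    """Annualise a 5-year death probability assuming a constant hazard.

    Returns ``1 - (1 - p5)**(1/5)``, the one-year probability whose 5-fold
    compounding reproduces ``p5``.
    """
    arr = np.asarray(p5, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise DomainError(f"5-year death probability {p5} outside [0, 1]")
    out = 1.0 - (1.0 - arr) ** 0.2
    return float(out) if arr.ndim == 0 else out


def annual_death_probability(
    life_table: LifeTable, ethnicity: str, sex: str, age: int
) -> float:
    """Annualised death probability for the year begun at ``age``.

    Death is certain for the year whose end would reach the closure age, so
    survival hits exactly zero there and lifetimes are bounded.
    """
    if age + 1 >= life_table.closure_age:
        return 1.0
    return annual_mortality(life_table.p5(ethnicity, sex, age))


def _cohort_rng(seed: int, stratum: Stratum, start_age: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), stratum_index(stratum), int(start_age)])
    )


def _band_sequence(start_age: int, closure_age: int) -> list[int]:
    """Starting ages of the 5-year bands visited from start to closure."""
    first = 40 + 5 * ((start_age - 40) // 5)
    return list(range(first, closure_age, 5))


def simulate_cohort_qalys(
    stratum: Stratum,
    oa_status: str,
    n: int,
    tables: ModelTables,
    params: PainModelParams,
    seed: int,
    start_age: int | None = None,
    moderate_share: float | None = None,
    return_years: bool = False,
):
    """Simulate ``n`` individuals and return their per-person QALYs lived.

    Vectorised over individuals; the annual cycle follows
    :func:`simulate_individual` exactly.  ``moderate_share`` overrides the
    pain curve's moderate/severe split (used by sensitivity analyses) while
    leaving all random draws unchanged, giving common random numbers.

    With ``return_years`` also returns each individual's integer years lived.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if oa_status not in OA_STATUSES:
        raise ParameterError(f"oa_status must be one of {OA_STATUSES}")
    if start_age is None:
        start_age = stratum.midpoint_age
    if not 40 <= start_age <= MODEL_END_AGE:
        raise DomainError(f"start_age {start_age} outside [40, {MODEL_END_AGE}]")

    life = tables.life_table
    curve = tables.pain_curve
    m_share = curve.moderate_share if moderate_share is None else float(moderate_share)
    closure = life.closure_age
    years = closure - start_age
    eth, sex = stratum.ethnicity, stratum.sex

    rng = _cohort_rng(seed, stratum, start_age)
    # Fixed draw order, independent of oa_status, so paired cohorts share noise.
    u_death = rng.random((years, n))
    womac = np.clip(
        rng.normal(params.init_mean, params.init_sd, size=n), params.floor, params.ceiling
    )
    increments = rng.normal(
        params.annual_increment_mean, params.annual_increment_sd, size=(years, n)
    )
    band_starts = _band_sequence(start_age, closure)
    u_pain = rng.random((len(band_starts), n))
    band_row = {a: i for i, a in enumerate(band_starts)}

    is_oa = oa_status == OA
    qalys = np.zeros(n)
    years_lived = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    non_oa_levels = np.zeros(n, dtype=np.int8)
    current_band = None

    for t in range(years):
        age = start_age + t
        band_age = 40 + 5 * ((age - 40) // 5)
        if band_age != current_band:
            current_band = band_age
            band_label = band_for_age(min(age, MODEL_END_AGE))
            util_vec = tables.utilities.band_values(band_label)
            if not is_oa:
                p_pain = curve.p_for_age(age)
                non_oa_levels = levels_from_uniforms(u_pain[band_row[band_age]], p_pain, m_share)
        levels = categorize_pain_array(womac) if is_oa else non_oa_levels
        qalys[alive] += util_vec[levels[alive]]
        years_lived[alive] += 1
        q = annual_death_probability(life, eth, sex, age)
        alive &= u_death[t] >= q
        if not alive.any():
            break
        if is_oa:
            womac = np.clip(womac + increments[t], params.floor, params.ceiling)

    if return_years:
        return qalys, years_lived
    return qalys


def simulate_cohort(
    stratum: Stratum,
    oa_status: str,
    n: int,
    tables: ModelTables,
    params: PainModelParams,
    seed: int,
    start_age: int | None = None,
    moderate_share: float | None = None,
) -> CohortResult:
    """Simulate a cohort and summarise mean QALYs with its Monte Carlo SE."""
    qalys = simulate_cohort_qalys(
        stratum, oa_status, n, tables, params, seed,
        start_age=start_age, moderate_share=moderate_share,
    )
    mean = float(np.mean(qalys))
    se = float(np.std(qalys, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return CohortResult(
        stratum=stratum, oa_status=oa_status, n_simulated=n, mean_qalys=mean, se_qalys=se
    )


def simulate_individual(
    start_age: int,
    stratum: Stratum,
    oa_status: str,
    tables: ModelTables,
    params: PainModelParams,
    rng: int | np.random.Generator,
) -> float:
    """Simulate a single life history and return the QALYs lived.

    Scalar reference implementation of the annual cycle; the vectorised
    cohort simulator follows the same accounting.
    """
    if oa_status not in OA_STATUSES:
        raise ParameterError(f"oa_status must be one of {OA_STATUSES}")
    if not 40 <= start_age <= MODEL_END_AGE:
        raise DomainError(f"start_age {start_age} outside [40, {MODEL_END_AGE}]")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    life = tables.life_table
    curve = tables.pain_curve
    is_oa = oa_status == OA
    womac = float(
        np.clip(gen.normal(params.init_mean, params.init_sd), params.floor, params.ceiling)
    )
    qalys = 0.0
    current_band = None
    level = PainLevel.NONE
    first_year = True
    for age in range(start_age, life.closure_age):
        band_age = 40 + 5 * ((age - 40) // 5)
        if is_oa:
            if not first_year:
                step = gen.normal(params.annual_increment_mean, params.annual_increment_sd)
                womac = float(np.clip(womac + step, params.floor, params.ceiling))
            level = PainLevel(int(categorize_pain_array(np.array(womac))))
        elif band_age != current_band:
            p = curve.p_for_age(age)
            level = PainLevel(int(levels_from_uniforms(
                np.array(gen.random()), p, curve.moderate_share
            )))
        current_band = band_age
        first_year = False
        qalys += tables.utilities.lookup(age, level)
        if gen.random() < annual_death_probability(life, stratum.ethnicity, stratum.sex, age):
            break
    return qalys


def qale_closed_form(
    start_age: int,
    stratum: Stratum,
    pain_levels,
    tables: ModelTables,
) -> float:
    """Quality-adjusted life expectancy for a deterministic pain trajectory.

    Computes Σ_t S(t)·u(age_t, level_t), with S(t) the survival to the start
    of year t compounded from the annualised life-table probabilities.  This
    is the exact expectation of the simulator's QALYs whenever the pain
    trajectory is deterministic, and serves as its analytic oracle.

    ``pain_levels`` may be a single :class:`PainLevel`, a sequence indexed
    by year offset, or a callable ``age -> PainLevel``.
    """
    if callable(pain_levels):
        level_at = pain_levels
    elif isinstance(pain_levels, PainLevel):
        level_at = lambda age: pain_levels  # noqa: E731
    else:
        seq = list(pain_levels)
        level_at = lambda age: seq[age - start_age]  # noqa: E731

    life = tables.life_table
    survival = 1.0
    total = 0.0
    for age in range(start_age, life.closure_age):
        u = tables.utilities.lookup(age, level_at(age))
        total += survival * u
        q = annual_death_probability(life, stratum.ethnicity, stratum.sex, age)
        survival *= 1.0 - q
    return total


def expected_qale(
    start_age: int,
    stratum: Stratum,
    utility_for_age,
    tables: ModelTables,
) -> float:
    """Σ_t S(t)·ū(age_t) for an arbitrary per-age expected utility ū."""
    life = tables.life_table
    survival = 1.0
    total = 0.0
    for age in range(start_age, life.closure_age):
        total += survival * float(utility_for_age(age))
        q = annual_death_probability(life, stratum.ethnicity, stratum.sex, age)
        survival *= 1.0 - q
    return total
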