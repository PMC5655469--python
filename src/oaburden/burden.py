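"""Lifetime QALY-loss accounting, stratified and totalled.

Converts per-cohort quality-adjusted life expectancies (QALE) into the
burden quantities of interest:

* the counterfactual QALE a knee-OA sub-population would have had without
  the disease, computed by weighting no-OA QALE over the OA population's
  age distribution;
* per-person QALY loss (counterfactual minus OA QALE);
* population QALY loss (per-person loss × prevalent cases); and
* the proportion of disease-free QALE lost.

Results are emitted per (ethnicity × sex × age band) stratum with group
totals and a grand total, mirroring the standard published layout of
burden-of-disease tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import (
    AlignmentError,
    CompletenessError,
    DegenerateDistributionError,
    DomainError,
)
from .microsim import NO_OA, OA, CohortResult
from .strata import AGE_BANDS, GROUPS, STRATA, Stratum, group_label
from .tables import PopulationCounts, PrevalenceTable

TOTAL = "total"


@dataclass(frozen=True)
class BurdenResult:
    """Burden quantities for one stratum or aggregate row."""

    ethnicity: str
    sex: str
    age_band: str  # "total" for aggregate rows
    qale_no_oa: float
    qale_oa: float
    qale_counterfactual: float
    per_person_loss: float
    n_with_oa: float
    population_loss: float

    @property
    def proportion_lost(self) -> float:
        return proportion_lost(self.per_person_loss, self.qale_counterfactual)


def oa_age_distribution(
    prevalence: PrevalenceTable,
    population: PopulationCounts,
    ethnicity: str,
    sex: str,
) -> dict[str, float]:
    """Age distribution of prevalent knee-OA cases within one sex×ethnicity group.

    weight(band) ∝ prevalence(band) × population(band); weights sum to 1.
    """
    raw = {}
    for band in AGE_BANDS:
        s = Stratum(band, sex, ethnicity)
        raw[band] = prevalence.prevalence(s) * population.count(s)
    total = sum(raw.values())
    if total <= 0:
        raise DegenerateDistributionError(
            f"no prevalent cases in group ({ethnicity}, {sex}); cannot form age weights"
        )
    return {band: v / total for band, v in raw.items()}


def counterfactual_qale(
    qale_no_oa_by_band: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """No-OA QALE weighted over the OA population's age distribution."""
    if set(weights) - set(qale_no_oa_by_band):
        missing = sorted(set(weights) - set(qale_no_oa_by_band))
        raise AlignmentError(f"no-OA QALE missing for weighted bands: {missing}")
    return sum(w * qale_no_oa_by_band[band] for band, w in weights.items())


def per_person_loss(qale_counterfactual: float, qale_oa: float) -> float:
    """QALYs lost per person with knee OA: counterfactual minus OA QALE."""
    return qale_counterfactual - qale_oa


def population_loss(per_person: float, prevalence: float, count: float) -> float:
    """Total QALYs lost in a stratum: per-person loss × prevalent cases."""
    if not 0.0 <= prevalence <= 1.0:
        raise DomainError(f"prevalence {prevalence} outside [0, 1]")
    if count < 0:
        raise DomainError(f"count {count} must be non-negative")
    return per_person * prevalence * count


def proportion_lost(per_person: float, qale_counterfactual: float) -> float:
    """Share of disease-free QALE lost to knee OA."""
    if qale_counterfactual <= 0:
        raise DomainError("counterfactual QALE must be positive")
    return per_person / qale_counterfactual


def _mean_qalys(entry) -> float:
    return entry.mean_qalys if isinstance(entry, CohortResult) else float(entry)


def build_burden_tables(
    cohort_results: Mapping[tuple[Stratum, str], CohortResult | float],
    prevalence: PrevalenceTable,
    population: PopulationCounts,
) -> pd.DataFrame:
    """Assemble the full stratified burden table with totals.

    ``cohort_results`` maps ``(stratum, oa_status)`` to a cohort summary (or
    a bare mean-QALE float) for all 36 strata and both cohorts.  Returns a
    tidy frame with one row per stratum, one total row per ethnicity×sex
    group, and a grand-total row.

    Group-total conventions: the no-OA QALE column is weighted by the whole
    group population; the OA and counterfactual columns are weighted by the
    OA population's age distribution, so the per-person-loss column equals
    counterfactual minus OA QALE at every level of aggregation.
    """
    missing = [
        (s, status)
        for s in STRATA
        for status in (OA, NO_OA)
        if (s, status) not in cohort_results
    ]
    if missing:
        names = [f"({s.ethnicity}, {s.sex}, {s.age_band}, {status})" for s, status in missing]
        raise CompletenessError(f"cohort results missing for: {', '.join(names)}")

    rows: list[BurdenResult] = []
    grand = {"pop": 0.0, "n_oa": 0.0, "no_oa_w": 0.0, "oa_w": 0.0, "cf_w": 0.0, "loss": 0.0}

    for eth, sex in GROUPS:
        weights = oa_age_distribution(prevalence, population, eth, sex)
        qale_no = {}
        qale_oa = {}
        for band in AGE_BANDS:
            s = Stratum(band, sex, eth)
            qale_no[band] = _mean_qalys(cohort_results[(s, NO_OA)])
            qale_oa[band] = _mean_qalys(cohort_results[(s, OA)])
            n_oa = prevalence.prevalence(s) * population.count(s)
            loss = per_person_loss(qale_no[band], qale_oa[band])
            rows.append(
                BurdenResult(
                    ethnicity=eth, sex=sex, age_band=band,
                    qale_no_oa=qale_no[band], qale_oa=qale_oa[band],
                    qale_counterfactual=qale_no[band],
                    per_person_loss=loss, n_with_oa=n_oa,
                    population_loss=loss * n_oa,
                )
            )

        group_n = sum(
            population.count(Stratum(b, sex, eth)) for b in AGE_BANDS
        )
        group_no = sum(
            qale_no[b] * population.count(Stratum(b, sex, eth)) for b in AGE_BANDS
        ) / group_n
        group_oa_qale = sum(weights[b] * qale_oa[b] for b in AGE_BANDS)
        group_cf = counterfactual_qale(qale_no, weights)
        group_n_oa = sum(
            prevalence.prevalence(Stratum(b, sex, eth)) * population.count(Stratum(b, sex, eth))
            for b in AGE_BANDS
        )
        group_loss = per_person_loss(group_cf, group_oa_qale)
        rows.append(
            BurdenResult(
                ethnicity=eth, sex=sex, age_band=TOTAL,
                qale_no_oa=group_no, qale_oa=group_oa_qale,
                qale_counterfactual=group_cf,
                per_person_loss=group_loss, n_with_oa=group_n_oa,
                population_loss=group_loss * group_n_oa,
            )
        )
        grand["pop"] += group_n
        grand["n_oa"] += group_n_oa
        grand["no_oa_w"] += group_no * group_n
        grand["oa_w"] += group_oa_qale * group_n_oa
        grand["cf_w"] += group_cf * group_n_oa
        grand["loss"] += group_loss * group_n_oa

    total_cf = grand["cf_w"] / grand["n_oa"]
    total_oa = grand["oa_w"] / grand["n_oa"]
    rows.append(
        BurdenResult(
            ethnicity="all", sex="all", age_band=TOTAL,
            qale_no_oa=grand["no_oa_w"] / grand["pop"],
            qale_oa=total_oa,
            qale_counterfactual=total_cf,
            per_person_loss=per_person_loss(total_cf, total_oa),
            n_with_oa=grand["n_oa"],
            population_loss=grand["loss"],
        )
    )

    frame = pd.DataFrame([r.__dict__ for r in rows])
    frame["proportion_lost"] = frame["per_person_loss"] / frame["qale_counterfactual"]
    return frame


def group_losses(burden: pd.DataFrame) -> dict[str, float]:
    """Per-person losses for the four group totals plus overall, keyed flat."""
    out = {}
    for eth, sex in GROUPS:
        row = burden[
            (burden.ethnicity == eth) & (burden.sex == sex) & (burden.age_band == TOTAL)
        ]
        out[group_label(eth, sex)] = float(row.per_person_loss.iloc[0])
    total = burden[(burden.ethnicity == "all") & (burden.age_band == TOTAL)]
    out["overall"] = float(total.per_person_loss.iloc[0])
    return out
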