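"""Probabilistic sensitivity analysis over the background-pain split and
prevalence adjustment.

The base case assumes 90% of people in pain not caused by knee OA are in
moderate (vs severe) pain.  The PSA redraws that share from a uniform prior
(default U(0.80, 1.00)) and re-runs the burden pipeline per draw, holding
all Monte Carlo noise fixed (common random numbers) so the resulting spread
reflects parameter uncertainty only.  Uncertainty intervals are empirical
quantiles of the per-draw per-person losses (linear interpolation of order
statistics).  A second lever switches the prevalence surface between the
PPV-adjusted base case and the raw self-report series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import group_losses
from .errors import ParameterError
from .microsim import NO_OA, OA
from .pipeline import PipelineInputs, run_burden, simulate_all_cohorts
from .strata import GROUPS, group_label
from .tables import GroupKey

PREVALENCE_MODES = ("ppv_adjusted", "unadjusted", "sample_both")

DEFAULT_PPV = 0.9


@dataclass(frozen=True)
class PSAConfig:
    """Settings for the probabilistic sensitivity analysis."""

    moderate_share_prior: tuple[float, float] = (0.80, 1.00)
    n_draws: int = 500
    prevalence_mode: str = "ppv_adjusted"
    ppv: float | dict[GroupKey, float] = DEFAULT_PPV
    seed: int = 0
    interval_level: float = 0.95
    n_per_stratum: int | None = None  # defaults to the pipeline's cohort size

    def __post_init__(self) -> None:
        lo, hi = self.moderate_share_prior
        if not 0.0 <= lo <= hi <= 1.0:
            raise ParameterError(f"prior bounds ({lo}, {hi}) must satisfy 0 <= lo <= hi <= 1")
        if self.n_draws < 2:
            raise ParameterError(f"n_draws must be >= 2, got {self.n_draws}")
        if not 0.0 < self.interval_level < 1.0:
            raise ParameterError(f"interval_level must be in (0, 1), got {self.interval_level}")
        if self.prevalence_mode not in PREVALENCE_MODES:
            raise ParameterError(f"prevalence_mode must be one of {PREVALENCE_MODES}")


@dataclass(frozen=True)
class PSAResult:
    """Per-draw losses, base-case point estimates and uncertainty intervals."""

    draws: pd.DataFrame  # columns: draw, moderate_share, prevalence_adjusted, loss_<group>
    point: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    level: float

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "point": self.point[g],
                "lower": self.intervals[g][0],
                "upper": self.intervals[g][1],
                "level": self.level,
            }
            for g in self.point
        ]
        return pd.DataFrame(rows)


def empirical_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Central empirical interval by linear interpolation of order statistics."""
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(draws, dtype=float), [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _prevalence_for(inputs: PipelineInputs, adjusted: bool, ppv) -> "PipelineInputs":
    prev = inputs.prevalence if adjusted else inputs.prevalence.to_unadjusted(ppv)
    return inputs.with_(prevalence=prev)


def run_psa(config: PSAConfig, inputs: PipelineInputs) -> PSAResult:
    """Run the PSA and summarise per-person losses per group and overall.

    The OA cohorts do not depend on the background-pain split, so they are
    simulated once; each draw re-simulates only the no-OA cohorts at the
    sampled moderate share, reusing the same random streams.
    """
    n = config.n_per_stratum or inputs.n_per_stratum
    sim_inputs = inputs.with_(n_per_stratum=n)

    oa_results = simulate_all_cohorts(sim_inputs, statuses=(OA,))

    def losses_at(share: float | None, adjusted: bool) -> dict[str, float]:
        no_oa = simulate_all_cohorts(sim_inputs, statuses=(NO_OA,), moderate_share=share)
        run = _prevalence_for(sim_inputs, adjusted, config.ppv)
        _, burden = run_burden(run, cohort_results={**oa_results, **no_oa})
        return group_losses(burden)

    base_adjusted = config.prevalence_mode != "unadjusted"
    point = losses_at(None, base_adjusted)

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 271828]))
    lo, hi = config.moderate_share_prior
    shares = rng.uniform(lo, hi, size=config.n_draws)
    if config.prevalence_mode == "sample_both":
        adjusted_flags = rng.random(config.n_draws) < 0.5
    else:
        adjusted_flags = np.full(config.n_draws, base_adjusted)

    records = []
    for d, (share, adj) in enumerate(zip(shares, adjusted_flags, strict=True)):
        losses = losses_at(float(share), bool(adj))
        rec = {"draw": d, "moderate_share": float(share), "prevalence_adjusted": bool(adj)}
        rec.update({f"loss_{g}": v for g, v in losses.items()})
        records.append(rec)
    draws = pd.DataFrame(records)

    groups = [group_label(e, s) for e, s in GROUPS] + ["overall"]
    intervals = {
        g: empirical_interval(draws[f"loss_{g}"].to_numpy(), config.interval_level)
        for g in groups
    }
    return PSAResult(draws=draws, point=point, intervals=intervals, level=config.interval_level)


def compare_prevalence_modes(
    inputs: PipelineInputs, ppv: float | dict[GroupKey, float] = DEFAULT_PPV
) -> dict[str, pd.DataFrame]:
    """Burden tables under PPV-adjusted versus raw self-report prevalence.

    Both runs share cohort simulations (prevalence only enters the
    weighting), so differences isolate the prevalence assumption.
    """
    cohorts = simulate_all_cohorts(inputs)
    _, adjusted = run_burden(inputs, cohort_results=cohorts)
    _, unadjusted = run_burden(
        _prevalence_for(inputs, adjusted=False, ppv=ppv), cohort_results=cohorts
    )
    return {"ppv_adjusted": adjusted, "unadjusted": unadjusted}
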