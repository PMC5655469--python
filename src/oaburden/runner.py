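"""Configured end-to-end runs with file outputs and reproducibility metadata."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import __version__
from .burden import TOTAL
from .config import RunConfig
from .health_states import NonOAPainCurve, PainModelParams, TransformParams, UtilityTable, transform_value_set
from .io import (
    LIFE_TABLE_SCHEMA,
    PAIN_CURVE_SCHEMA,
    POPULATION_SCHEMA,
    PREVALENCE_SCHEMA,
    UTILITY_SCHEMA,
    read_table,
    write_table,
)
from .pipeline import PipelineInputs, cohort_results_frame, run_burden
from .psa import PSAConfig, run_psa
from .synthetic import (
    generate_life_table,
    generate_pain_curve,
    generate_population_counts,
    load_fixture_tables,
)
from .tables import LifeTable, PopulationCounts, PrevalenceTable

log = logging.getLogger("oaburden")

STAGES = ("generate", "simulate", "burden", "psa")


def build_inputs(config: RunConfig) -> PipelineInputs:
    """Resolve a config into in-memory pipeline inputs.

    File paths win over generators; the packaged fixture tables supply the
    utilities and (unless overridden) the prevalence surface.
    """
    fixture_util, fixture_prev = load_fixture_tables()
    syn = config.synthetic

    if config.inputs.utilities is not None:
        utilities = UtilityTable.from_frame(
            read_table(config.inputs.utilities, UTILITY_SCHEMA)
        )
    else:
        utilities = fixture_util
    if config.valuation.value_set == "transformed":
        utilities = transform_value_set(
            utilities, TransformParams(exponent=config.valuation.exponent)
        )

    if config.inputs.life_table is not None:
        life = LifeTable.from_frame(read_table(config.inputs.life_table, LIFE_TABLE_SCHEMA))
    else:
        life = generate_life_table(
            gompertz_level=syn.level_map(),
            gompertz_shape=syn.gompertz_shape,
            closure_age=syn.closure_age,
            seed=config.seed,
        )

    if config.inputs.population is not None:
        population = PopulationCounts.from_frame(
            read_table(config.inputs.population, POPULATION_SCHEMA)
        )
    else:
        population = generate_population_counts(
            total=syn.total_population,
            age_decay=syn.age_decay,
            sex_split=syn.female_share,
            maori_share=syn.maori_share,
            seed=config.seed,
        )

    if config.inputs.prevalence is not None:
        prevalence = PrevalenceTable.from_frame(
            read_table(config.inputs.prevalence, PREVALENCE_SCHEMA)
        )
    elif syn.prevalence_base is not None:
        from .synthetic import generate_prevalence

        prevalence = generate_prevalence(
            base=syn.prevalence_base, slope=syn.prevalence_slope, seed=config.seed
        )
    else:
        prevalence = fixture_prev

    if config.inputs.pain_curve is not None:
        curve = NonOAPainCurve.from_frame(
            read_table(config.inputs.pain_curve, PAIN_CURVE_SCHEMA),
            moderate_share=syn.moderate_share,
        )
    else:
        curve = generate_pain_curve(
            p_floor=syn.pain_floor,
            p_ceiling=syn.pain_ceiling,
            midpoint_age=syn.pain_midpoint_age,
            scale=syn.pain_scale,
            moderate_share=syn.moderate_share,
            seed=config.seed,
        )

    params = PainModelParams(
        init_mean=config.pain_model.init_mean,
        init_sd=config.pain_model.init_sd,
        annual_increment_mean=config.pain_model.annual_increment_mean,
        annual_increment_sd=config.pain_model.annual_increment_sd,
    )
    return PipelineInputs(
        utilities=utilities,
        life_table=life,
        pain_curve=curve,
        prevalence=prevalence,
        population=population,
        pain_params=params,
        n_per_stratum=config.simulation.n_per_stratum,
        seed=config.seed,
    )


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict[str, Path]:
    """Run the requested stages end to end and write all artefacts.

    Returns a mapping of artefact name to written path.  Output bytes are a
    pure function of the configuration (and hence the master seed): metadata
    records the seed, config hash and package version but no wall-clock
    values.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    inputs = build_inputs(config)

    def emit(name: str, frame) -> None:
        path = out / f"{name}.csv"
        write_table(frame, path)
        written[name] = path

    t0 = time.perf_counter()
    if "generate" in stages:
        emit("life_table", inputs.life_table.to_frame())
        emit("population", inputs.population.to_frame())
        emit("prevalence", inputs.prevalence.to_frame())
        emit("pain_curve", inputs.pain_curve.to_frame())
        emit("utilities", inputs.utilities.to_frame())
        log.info("generate: wrote input tables in %.2fs", time.perf_counter() - t0)

    cohort_results = None
    if {"simulate", "burden", "psa"} & set(stages):
        t = time.perf_counter()
        cohort_results, burden = run_burden(inputs)
        log.info(
            "simulate: 72 cohorts × n=%d in %.2fs",
            inputs.n_per_stratum, time.perf_counter() - t,
        )
        if "simulate" in stages:
            emit("cohort_results", cohort_results_frame(cohort_results))
        if {"burden", "psa"} & set(stages):
            emit("burden_by_stratum", burden[burden.age_band != TOTAL])
            emit("burden_summary", burden[burden.age_band == TOTAL])

    if "psa" in stages and config.psa.run:
        t = time.perf_counter()
        psa_cfg = PSAConfig(
            moderate_share_prior=(config.psa.prior_low, config.psa.prior_high),
            n_draws=config.psa.n_draws,
            prevalence_mode=config.psa.prevalence_mode,
            ppv=config.psa.ppv,
            seed=config.seed,
            interval_level=config.psa.interval_level,
            n_per_stratum=config.psa.n_per_stratum,
        )
        result = run_psa(psa_cfg, inputs)
        emit("psa_draws", result.draws)
        emit("psa_summary", result.summary_frame())
        log.info("psa: %d draws in %.2fs", config.psa.n_draws, time.perf_counter() - t)

    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "stages": sorted(set(stages)),
        "n_per_stratum": inputs.n_per_stratum,
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written["run_metadata"] = meta_path
    return written
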