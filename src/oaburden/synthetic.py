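"""Synthetic generators for externally sourced inputs, plus packaged fixtures.

The burden analysis needs four stratified inputs that originate outside the
model: a national life table, census-like population counts, a knee-OA
prevalence surface, and the age profile of pain not caused by knee OA.  The
utility and prevalence tables are shipped as packaged CSV fixtures; the
generators here emulate the remaining inputs with the statistical structure
the analysis assumes -- Gompertz mortality rising with age, geometrically
thinning population counts, prevalence increasing with age, and a logistic
in-age pain curve.

Generation is deterministic given its parameters; the ``seed`` arguments
exist so every generator shares the package-wide reproducibility contract
and can be extended with stochastic perturbation without changing call
sites.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError
from .health_states import NonOAPainCurve, UtilityTable
from .strata import (
    AGE_BANDS,
    DEFAULT_CLOSURE_AGE,
    ETHNICITIES,
    SEXES,
    STRATA,
    band_start,
    closure_band,
    extended_bands,
)
from .tables import GroupKey, LifeTable, PopulationCounts, PrevalenceTable

#: Gompertz hazard scale at age 0, per (ethnicity, sex).  Chosen so remaining
#: life expectancy at age 40 lands in a plausible national-life-table range,
#: with female mortality below male and Māori mortality above non-Māori.
DEFAULT_GOMPERTZ_LEVELS: dict[GroupKey, float] = {
    ("non_maori", "male"): 4.5e-5,
    ("non_maori", "female"): 3.0e-5,
    ("maori", "male"): 8.0e-5,
    ("maori", "female"): 5.5e-5,
}

#: Per-year log-hazard slope; ~9%/year hazard growth is typical of adult
#: all-cause mortality.
DEFAULT_GOMPERTZ_SHAPE = 0.09


def _gompertz_p5(level: float, shape: float, start_age: int) -> float:
    """Probability of death within [a, a+5) under hazard h(t) = level·e^{shape·t}."""
    cum = (level / shape) * (np.exp(shape * (start_age + 5)) - np.exp(shape * start_age))
    return float(1.0 - np.exp(-cum))


def generate_life_table(
    gompertz_level: float | dict[GroupKey, float] | None = None,
    gompertz_shape: float = DEFAULT_GOMPERTZ_SHAPE,
    closure_age: int = DEFAULT_CLOSURE_AGE,
    seed: int | None = None,
) -> LifeTable:
    """Build a stratified 5-year life table from a Gompertz hazard.

    The 5-year death probability for the band starting at age ``a`` is
    ``1 - exp(-∫_a^{a+5} level·e^{shape·t} dt)``; the open closure band is
    forced to probability 1 so simulated lifetimes are finite.

    ``gompertz_level`` may be a single scale shared by all four
    sex × ethnicity groups or a mapping ``(ethnicity, sex) -> scale``.
    """
    if gompertz_level is None:
        gompertz_level = dict(DEFAULT_GOMPERTZ_LEVELS)
    if gompertz_shape <= 0:
        raise ParameterError(f"gompertz_shape must be positive, got {gompertz_shape}")
    if closure_age < 85:
        raise ParameterError(f"closure_age must be >= 85, got {closure_age}")

    levels: dict[GroupKey, float]
    if isinstance(gompertz_level, dict):
        levels = {k: float(v) for k, v in gompertz_level.items()}
    else:
        levels = {(e, s): float(gompertz_level) for e in ETHNICITIES for s in SEXES}
    for key, lv in levels.items():
        if lv <= 0:
            raise ParameterError(f"gompertz_level for {key} must be positive, got {lv}")

    bands = extended_bands(closure_age)
    entries: dict[tuple[str, str, str], float] = {}
    for eth in ETHNICITIES:
        for sex in SEXES:
            lv = levels[(eth, sex)]
            for band in bands[:-1]:
                p5 = min(1.0, _gompertz_p5(lv, gompertz_shape, band_start(band)))
                entries[(eth, sex, band)] = p5
            entries[(eth, sex, closure_band(closure_age))] = 1.0
    table = LifeTable(entries=entries, closure_age=closure_age)
    table.validate()
    return table


def generate_population_counts(
    total: int,
    age_decay: float = 0.85,
    sex_split: float = 0.51,
    maori_share: float = 0.11,
    seed: int | None = None,
) -> PopulationCounts:
    """Census-like counts per stratum.

    Band weights follow a geometric profile ``age_decay**k`` over the nine
    entry bands (k = 0 at 40–44), crossed with a female share ``sex_split``
    and a Māori share ``maori_share``.  Expected fractional counts are
    rounded half-to-even, so the grand total matches ``total`` up to
    rounding.
    """
    if total <= 0:
        raise ParameterError(f"total must be positive, got {total}")
    for name, v in (("age_decay", age_decay), ("sex_split", sex_split),
                    ("maori_share", maori_share)):
        if not 0.0 <= v <= 1.0 + 1e-12 and name != "age_decay":
            raise ParameterError(f"{name} must be in [0, 1], got {v}")
    if age_decay <= 0:
        raise ParameterError(f"age_decay must be positive, got {age_decay}")

    band_w = np.array([age_decay**k for k in range(len(AGE_BANDS))])
    band_w /= band_w.sum()
    sex_w = {"female": sex_split, "male": 1.0 - sex_split}
    eth_w = {"maori": maori_share, "non_maori": 1.0 - maori_share}

    counts = {
        s: int(round(total * band_w[AGE_BANDS.index(s.age_band)] * sex_w[s.sex]
                     * eth_w[s.ethnicity]))
        for s in STRATA
    }
    return PopulationCounts(counts=counts)


def generate_prevalence(
    base: float,
    slope: float = 1.45,
    seed: int | None = None,
) -> PrevalenceTable:
    """Knee-OA prevalence rising multiplicatively with age.

    Band k (k = 0 at 40–44) gets prevalence ``base * slope**k`` clipped to
    [0, 1], identical across sex and ethnicity.  With slope >= 1 the surface
    is non-decreasing in age, matching the qualitative shape of
    self-reported OA prevalence.
    """
    if not 0.0 <= base <= 1.0:
        raise ParameterError(f"base prevalence must be in [0, 1], got {base}")
    if slope < 0:
        raise ParameterError(f"slope must be non-negative, got {slope}")
    values = {
        s: float(np.clip(base * slope ** AGE_BANDS.index(s.age_band), 0.0, 1.0))
        for s in STRATA
    }
    return PrevalenceTable(values=values, adjusted=True)


def generate_pain_curve(
    p_floor: float = 0.25,
    p_ceiling: float = 0.65,
    midpoint_age: float = 62.0,
    scale: float = 10.0,
    moderate_share: float = 0.90,
    seed: int | None = None,
) -> NonOAPainCurve:
    """Logistic-in-age share of the non-OA population in any pain.

    The share rises from ``p_floor`` towards ``p_ceiling`` with age,
    evaluated at each band's midpoint:
    ``p(a) = p_floor + (p_ceiling - p_floor) · logistic((a - midpoint)/scale)``.
    Defaults give a deliberately high general-population pain prevalence
    (roughly a third of 40-year-olds rising towards two thirds at 84).
    """
    if not 0.0 <= p_floor <= p_ceiling <= 1.0:
        raise ParameterError("need 0 <= p_floor <= p_ceiling <= 1")
    if scale <= 0:
        raise ParameterError(f"scale must be positive, got {scale}")
    p = {}
    for band in AGE_BANDS:
        a = band_start(band) + 2
        p[band] = p_floor + (p_ceiling - p_floor) / (1.0 + np.exp(-(a - midpoint_age) / scale))
    return NonOAPainCurve(p_in_pain=p, moderate_share=moderate_share)


# ---------------------------------------------------------------------------
# Packaged fixtures: published utility and prevalence tables

UTILITY_FIXTURE = "table1_utilities.csv"
PREVALENCE_FIXTURE = "table2_prevalence.csv"

#: SHA-256 checksums of the packaged fixture files, frozen at packaging time.
FIXTURE_SHA256 = {
    UTILITY_FIXTURE: "028b742c009529d63cb0faf438114929c59e5eb0ee505f3e75d5f0979fc12497",
    PREVALENCE_FIXTURE: "25a14205014c4ba5a4191f9581b36cfba1a91867f7ed6903bf128eacfb6bdd5e",
}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("oaburden.data").joinpath(name)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError:
        raise IntegrityError(f"packaged fixture {name!r} is missing") from None
    digest = hashlib.sha256(raw).hexdigest()
    expected = FIXTURE_SHA256[name]
    if digest != expected:
        raise IntegrityError(
            f"fixture {name!r} failed its integrity check: "
            f"sha256 {digest} != expected {expected}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), encoding="utf-8-sig")


def load_fixture_tables() -> tuple[UtilityTable, PrevalenceTable]:
    """Load the packaged utility and prevalence tables.

    Returns the age × pain-level VAS utility table and the PPV-adjusted
    knee-OA prevalence surface for New Zealand, exactly as published.
    Fixture bytes are checked against frozen SHA-256 digests.
    """
    util = UtilityTable.from_frame(_read_fixture(UTILITY_FIXTURE), value_set="vas")
    prev = PrevalenceTable.from_frame(_read_fixture(PREVALENCE_FIXTURE), adjusted=True)
    return util, prev
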