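"""Pain states and health-related quality of life.

Knee pain is carried as a WOMAC pain score on 0-100 (100 = worst).  Scores
are collapsed into three severity levels -- no pain (WOMAC < 1), moderate
(1-70), severe (> 70) -- and each (5-year age band, level) pair maps to an
EQ-5D utility on the dead = 0 ... perfect health = 1 scale.  Two valuations
are supported: the VAS-elicited value set, and a power-transformed variant
approximating trade-off (standard-gamble) valuations.

People without knee osteoarthritis are not pain-free: an age-specific share
of them is in pain from other causes, split between moderate and severe
pain (default 90% / 10%).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, TableLookupError
from .strata import AGE_BANDS, MODEL_END_AGE, band_for_age, normalize_band


class PainLevel(enum.IntEnum):
    """Three-level pain severity, ordered none < moderate < severe."""

    NONE = 0
    MODERATE = 1
    SEVERE = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "PainLevel":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown pain level {label!r}") from None


#: WOMAC cut points: scores < 1 are "no pain", scores > 70 are "severe".
WOMAC_NO_PAIN_BELOW = 1.0
WOMAC_SEVERE_ABOVE = 70.0


@dataclass(frozen=True)
class PainModelParams:
    """WOMAC initialisation and annual-progression parameters.

    Defaults describe a mild-to-moderate knee-OA cohort: initial score
    Normal(30, 15) and a slow upward drift of Normal(0.5, 5) points per
    year, clamped to the 0-100 instrument range.
    """

    init_mean: float = 30.0
    init_sd: float = 15.0
    annual_increment_mean: float = 0.5
    annual_increment_sd: float = 5.0
    floor: float = 0.0
    ceiling: float = 100.0

    def __post_init__(self) -> None:
        if self.init_sd < 0 or self.annual_increment_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        if not self.floor < self.ceiling:
            raise ParameterError("floor must be below ceiling")


@dataclass(frozen=True)
class TransformParams:
    """Power-transform parameters: u' = 1 - (1 - u)**exponent.

    exponent = 1 is the identity; exponent > 1 compresses utilities toward
    1, approximating trade-off-elicited (standard-gamble-like) values from
    VAS values, which narrows the gaps between pain states.
    """

    exponent: float = 1.61

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ParameterError(f"exponent must be positive, got {self.exponent}")


def categorize_pain(womac: float) -> PainLevel:
    """Collapse a WOMAC pain score into the three-level severity state.

    Scores below 1 are no pain, 1-70 inclusive moderate, above 70 severe.
    """
    if not 0.0 <= womac <= 100.0:
        raise DomainError(f"WOMAC score {womac} outside [0, 100]")
    if womac < WOMAC_NO_PAIN_BELOW:
        return PainLevel.NONE
    if womac <= WOMAC_SEVERE_ABOVE:
        return PainLevel.MODERATE
    return PainLevel.SEVERE


def categorize_pain_array(womac: np.ndarray) -> np.ndarray:
    """Vectorised :func:`categorize_pain`; returns int codes."""
    w = np.asarray(womac)
    if np.any((w < 0) | (w > 100)):
        raise DomainError("WOMAC scores outside [0, 100]")
    out = np.full(w.shape, int(PainLevel.MODERATE), dtype=np.int8)
    out[w < WOMAC_NO_PAIN_BELOW] = int(PainLevel.NONE)
    out[w > WOMAC_SEVERE_ABOVE] = int(PainLevel.SEVERE)
    return out


@dataclass(frozen=True)
class UtilityTable:
    """Age-band × pain-level health-state utilities for one value set.

    ``values`` maps ``(age_band, PainLevel)`` to a utility in [0, 1].  The
    table covers the nine entry bands; lookups for ages beyond 84 reuse the
    80–84 row (last observation carried forward), since simulated
    individuals outlive the oldest tabulated band.
    """

    values: dict[tuple[str, PainLevel], float]
    value_set: str = "vas"

    def __post_init__(self) -> None:
        norm = {(normalize_band(b), PainLevel(lv)): float(u) for (b, lv), u in self.values.items()}
        object.__setattr__(self, "values", norm)
        self.validate()

    def validate(self) -> None:
        for (band, level), u in self.values.items():
            if not 0.0 <= u <= 1.0:
                raise ParameterError(f"utility {u} for ({band}, {level.label}) outside [0, 1]")
        for band in AGE_BANDS:
            triple = self.band_values(band)
            if not (triple[0] >= triple[1] >= triple[2]):
                raise ParameterError(
                    f"utility ordering violated in band {band}: "
                    f"none={triple[0]}, moderate={triple[1]}, severe={triple[2]}"
                )

    def band_values(self, age_band: str) -> np.ndarray:
        """Utilities (none, moderate, severe) for one band as a vector."""
        band = normalize_band(age_band)
        try:
            return np.array([self.values[(band, lv)] for lv in PainLevel])
        except KeyError:
            raise TableLookupError(f"utility table has no row for band {band!r}") from None

    def lookup(self, age: float, level: PainLevel) -> float:
        """Utility for a given exact age and pain level.

        Ages 85+ use the 80–84 row; ages below 40 are out of range.
        """
        if age < 40:
            raise DomainError(f"age {age} below modelled range")
        band = band_for_age(min(age, MODEL_END_AGE))
        return self.values[(band, PainLevel(level))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_band": b, "level": lv.label, "value": self.values[(b, lv)],
             "value_set": self.value_set}
            for b in AGE_BANDS
            for lv in PainLevel
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_set: str | None = None) -> "UtilityTable":
        values = {
            (normalize_band(r.age_band), PainLevel.from_label(r.level)): float(r.value)
            for r in frame.itertuples()
        }
        vs = value_set if value_set is not None else str(frame["value_set"].iloc[0])
        return cls(values=values, value_set=vs)


def lookup_utility(age: float, level: PainLevel, table: UtilityTable) -> float:
    """Utility for (age, pain level) under the table's value set."""
    return table.lookup(age, level)


def transform_value_set(table: UtilityTable, params: TransformParams) -> UtilityTable:
    """Apply the power transform u' = 1 - (1 - u)**exponent cell-wise.

    Preserves the none >= moderate >= severe ordering (the map is
    monotone increasing in u) and tags the result ``value_set="transformed"``.
    """
    if table.value_set != "vas":
        raise ParameterError(f"expected a VAS-valued table, got value_set={table.value_set!r}")
    if params.exponent == 1.0:
        new = dict(table.values)  # exact identity, no float round-trip
    else:
        new = {k: 1.0 - (1.0 - u) ** params.exponent for k, u in table.values.items()}
    return UtilityTable(values=new, value_set="transformed")


def draw_initial_pain(
    n: int, params: PainModelParams, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw baseline WOMAC scores: Normal(init_mean, init_sd) clamped to range."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.normal(params.init_mean, params.init_sd, size=n)
    return np.clip(draws, params.floor, params.ceiling)


def progress_pain(
    womac: float | np.ndarray, params: PainModelParams, rng: np.random.Generator
):
    """Advance WOMAC by one year: add Normal(mean, sd) noise, clamp to range."""
    w = np.asarray(womac, dtype=float)
    if np.any((w < params.floor) | (w > params.ceiling)):
        raise DomainError("WOMAC score outside instrument range")
    step = rng.normal(params.annual_increment_mean, params.annual_increment_sd, size=w.shape)
    out = np.clip(w + step, params.floor, params.ceiling)
    return float(out) if np.isscalar(womac) or w.ndim == 0 else out


@dataclass(frozen=True)
class NonOAPainCurve:
    """Age profile of pain from causes other than knee OA.

    ``p_in_pain`` gives, per entry band, the share of the non-OA population
    in any pain; of those, ``moderate_share`` are in moderate pain and the
    rest severe.  Ages past 84 reuse the last band's share.
    """

    p_in_pain: dict[str, float]
    moderate_share: float = 0.90

    def __post_init__(self) -> None:
        norm = {normalize_band(b): float(p) for b, p in self.p_in_pain.items()}
        object.__setattr__(self, "p_in_pain", norm)
        for band, p in self.p_in_pain.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"p_in_pain[{band!r}] = {p} outside [0, 1]")
        if not 0.0 <= self.moderate_share <= 1.0:
            raise ParameterError(f"moderate_share {self.moderate_share} outside [0, 1]")

    def p_for_band(self, age_band: str) -> float:
        band = normalize_band(age_band)
        try:
            return self.p_in_pain[band]
        except KeyError:
            raise TableLookupError(f"pain curve has no entry for band {band!r}") from None

    def p_for_age(self, age: float) -> float:
        if age < 40:
            raise DomainError(f"age {age} below modelled range")
        return self.p_for_band(band_for_age(min(age, MODEL_END_AGE)))

    def with_moderate_share(self, moderate_share: float) -> "NonOAPainCurve":
        return replace(self, moderate_share=moderate_share)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_band": list(self.p_in_pain), "p_in_pain": list(self.p_in_pain.values())}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, moderate_share: float = 0.90) -> "NonOAPainCurve":
        return cls(
            p_in_pain={normalize_band(r.age_band): float(r.p_in_pain) for r in frame.itertuples()},
            moderate_share=moderate_share,
        )


def levels_from_uniforms(u: np.ndarray, p_in_pain: float, moderate_share: float) -> np.ndarray:
    """Map uniforms to pain-level codes: none / moderate / severe.

    The uniform is compared against cumulative thresholds ordered
    (none, moderate, severe), so with common random numbers a larger
    ``moderate_share`` can only move individuals from severe to moderate.
    """
    u = np.asarray(u)
    out = np.full(u.shape, int(PainLevel.MODERATE), dtype=np.int8)
    p_none = 1.0 - p_in_pain
    out[u < p_none] = int(PainLevel.NONE)
    out[u >= p_none + p_in_pain * moderate_share] = int(PainLevel.SEVERE)
    return out


def draw_non_oa_pain_level(
    age_band: str, curve: NonOAPainCurve, rng: np.random.Generator
) -> PainLevel:
    """Draw one pain level for a non-OA individual in the given age band."""
    p = curve.p_for_band(age_band)
    code = levels_from_uniforms(np.array(rng.random()), p, curve.moderate_share)
    return PainLevel(int(code))
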