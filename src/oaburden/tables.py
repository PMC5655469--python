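"""Stratified input tables: mortality, population counts, prevalence.

All three are keyed by (ethnicity, sex, age band).  The life table extends
past the entry bands to a closure age where death is certain, so simulated
lifetimes are finite; prevalence and population counts only cover the nine
entry bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, TableLookupError
from .strata import (
    DEFAULT_CLOSURE_AGE,
    ETHNICITIES,
    SEXES,
    STRATA,
    Stratum,
    band_for_age,
    band_start,
    extended_bands,
    normalize_band,
)

GroupKey = tuple[str, str]  # (ethnicity, sex)
EntryKey = tuple[str, str, str]  # (ethnicity, sex, age_band)


@dataclass(frozen=True)
class LifeTable:
    """5-year death probabilities by ethnicity, sex and age band.

    ``entries[(ethnicity, sex, band)]`` is the probability of dying within
    5 years for someone in that band.  Bands run from 40–44 up to the open
    closure band (e.g. ``"110+"``) where the probability is forced to 1.
    """

    entries: dict[EntryKey, float]
    closure_age: int = DEFAULT_CLOSURE_AGE

    def __post_init__(self) -> None:
        norm = {
            (eth, sex, normalize_band(band)): float(p)
            for (eth, sex, band), p in self.entries.items()
        }
        object.__setattr__(self, "entries", norm)

    def validate(self) -> None:
        """Check range, monotonicity in age, and terminal closure."""
        bands = extended_bands(self.closure_age)
        for eth in ETHNICITIES:
            for sex in SEXES:
                probs = [self.p5_band(eth, sex, b) for b in bands]
                if any(not 0.0 <= p <= 1.0 for p in probs):
                    raise ParameterError(f"death probability outside [0,1] for {eth}/{sex}")
                if any(nxt < prev - 1e-12 for prev, nxt in zip(probs, probs[1:], strict=False)):
                    raise ParameterError(f"death probability not monotone in age for {eth}/{sex}")
                if probs[-1] != 1.0:
                    raise ParameterError(
                        f"closure band probability must be 1, got {probs[-1]} for {eth}/{sex}"
                    )

    def p5_band(self, ethnicity: str, sex: str, age_band: str) -> float:
        key = (ethnicity, sex, normalize_band(age_band))
        try:
            return self.entries[key]
        except KeyError:
            raise TableLookupError(f"life table has no entry for {key!r}") from None

    def p5(self, ethnicity: str, sex: str, age: float) -> float:
        """5-year death probability for the band containing ``age``."""
        return self.p5_band(ethnicity, sex, band_for_age(age, self.closure_age))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ethnicity": eth, "sex": sex, "age_band": band, "p_death_5yr": p}
            for (eth, sex, band), p in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], band_start(kv[0][2]))
            )
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, closure_age: int | None = None) -> "LifeTable":
        entries = {
            (r.ethnicity, r.sex, normalize_band(r.age_band)): float(r.p_death_5yr)
            for r in frame.itertuples()
        }
        if closure_age is None:
            plus = [b for (_, _, b) in entries if b.endswith("+")]
            if not plus:
                raise ParameterError("life table frame has no closure band (label ending in '+')")
            closure_age = band_start(plus[0])
        return cls(entries=entries, closure_age=closure_age)


@dataclass(frozen=True)
class PopulationCounts:
    """Person counts per entry stratum (census-like)."""

    counts: dict[Stratum, int]

    def __post_init__(self) -> None:
        for s, c in self.counts.items():
            if c < 0:
                raise ParameterError(f"negative count {c} for {s}")
        if sum(self.counts.values()) <= 0:
            raise ParameterError("total population must be positive")

    def count(self, stratum: Stratum) -> int:
        try:
            return self.counts[stratum]
        except KeyError:
            raise TableLookupError(f"no population count for {stratum}") from None

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ethnicity": s.ethnicity, "sex": s.sex, "age_band": s.age_band,
             "count": self.counts[s]}
            for s in STRATA
            if s in self.counts
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationCounts":
        return cls(
            counts={
                Stratum(r.age_band, r.sex, r.ethnicity): int(r.count)
                for r in frame.itertuples()
            }
        )


@dataclass(frozen=True)
class PrevalenceTable:
    """Knee-OA prevalence (proportion) per entry stratum.

    ``adjusted`` records whether the values have been deflated by the
    positive predictive value of self-reported diagnosis (the base case)
    or are the raw self-report series.
    """

    values: dict[Stratum, float]
    adjusted: bool = True

    def __post_init__(self) -> None:
        for s, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"prevalence {v} for {s} outside [0, 1]")

    def prevalence(self, stratum: Stratum) -> float:
        try:
            return self.values[stratum]
        except KeyError:
            raise TableLookupError(f"no prevalence for {stratum}") from None

    def _ppv_for(self, ppv: float | dict[GroupKey, float], stratum: Stratum) -> float:
        p = ppv[stratum.group] if isinstance(ppv, dict) else float(ppv)
        if not 0.0 < p <= 1.0:
            raise ParameterError(f"PPV must be in (0, 1], got {p}")
        return p

    def to_unadjusted(self, ppv: float | dict[GroupKey, float]) -> "PrevalenceTable":
        """Invert the PPV adjustment: raw = adjusted / PPV, capped at 1."""
        if not self.adjusted:
            return self
        vals = {s: min(1.0, v / self._ppv_for(ppv, s)) for s, v in self.values.items()}
        return PrevalenceTable(values=vals, adjusted=False)

    def apply_ppv(self, ppv: float | dict[GroupKey, float]) -> "PrevalenceTable":
        """Deflate a raw self-report series: adjusted = raw × PPV."""
        if self.adjusted:
            return self
        vals = {s: v * self._ppv_for(ppv, s) for s, v in self.values.items()}
        return PrevalenceTable(values=vals, adjusted=True)

    def scaled(self, factor: float) -> "PrevalenceTable":
        return replace(
            self, values={s: min(1.0, v * factor) for s, v in self.values.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ethnicity": s.ethnicity, "sex": s.sex, "age_band": s.age_band,
             "prevalence": self.values[s]}
            for s in STRATA
            if s in self.values
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, adjusted: bool = True) -> "PrevalenceTable":
        return cls(
            values={
                Stratum(r.age_band, r.sex, r.ethnicity): float(r.prevalence)
                for r in frame.itertuples()
            },
            adjusted=adjusted,
        )


def survival_curve(life_table: LifeTable, ethnicity: str, sex: str) -> np.ndarray:
    """Annual survival S(t) from age 40 to closure implied by a life table.

    Uses the constant-hazard annualisation of the 5-year probabilities.
    S(0) = 1; the curve is non-increasing and reaches exactly 0 at the
    closure age (death is certain on entering the closure band).
    """
    from .microsim import annual_death_probability  # local import to avoid a cycle

    ages = np.arange(40, life_table.closure_age + 1)
    s = np.empty(ages.shape)
    s[0] = 1.0
    for i, age in enumerate(ages[:-1]):
        q = annual_death_probability(life_table, ethnicity, sex, int(age))
        s[i + 1] = s[i] * (1.0 - q)
    return s
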