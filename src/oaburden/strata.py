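"""Population strata: 5-year age bands crossed with sex and ethnicity.

The modelled population enters in nine contiguous 5-year age bands covering
ages 40-84, for each combination of sex (male/female) and ethnicity
(Māori / non-Māori) -- 36 entry strata in total.  Individuals age past the
last entry band during simulation, so tables that drive mortality extend to
a closure age at which death is certain.
"""

from __future__ import annotations

from dataclasses import dataclass

EN_DASH = "–"

MODEL_START_AGE = 40
MODEL_END_AGE = 84
DEFAULT_CLOSURE_AGE = 110

SEXES = ("male", "female")
ETHNICITIES = ("non_maori", "maori")


def _band_label(start: int) -> str:
    return f"{start}{EN_DASH}{start + 4}"


#: The nine 5-year entry bands "40–44" ... "80–84".
AGE_BANDS: tuple[str, ...] = tuple(_band_label(a) for a in range(40, 85, 5))


def normalize_band(label: str) -> str:
    """Canonicalise an age-band label.

    Accepts hyphen-minus, en-dash or em-dash separators and surrounding
    whitespace; returns the canonical en-dash form (e.g. ``"40–44"``).
    Open-ended closure labels like ``"110+"`` pass through unchanged.
    """
    s = str(label).strip().replace("—", EN_DASH).replace("-", EN_DASH)
    return s


def band_start(label: str) -> int:
    """Starting age of a band label such as ``"40–44"`` or ``"110+"``."""
    s = normalize_band(label)
    if s.endswith("+"):
        return int(s[:-1])
    return int(s.split(EN_DASH)[0])


def closure_band(closure_age: int) -> str:
    """Label of the open-ended terminal band at which death is certain."""
    return f"{closure_age}+"


def band_for_age(age: float, closure_age: int | None = None) -> str:
    """5-year band label containing ``age``.

    Ages at or beyond ``closure_age`` map to the open closure band.  Ages
    below 40 are outside the model and raise ``ValueError``.
    """
    if age < MODEL_START_AGE:
        raise ValueError(f"age {age} is below the modelled range (>= {MODEL_START_AGE})")
    if closure_age is not None and age >= closure_age:
        return closure_band(closure_age)
    start = MODEL_START_AGE + 5 * int((age - MODEL_START_AGE) // 5)
    return _band_label(start)


def extended_bands(closure_age: int = DEFAULT_CLOSURE_AGE) -> tuple[str, ...]:
    """All 5-year bands from age 40 up to closure, plus the closure band."""
    if closure_age < MODEL_END_AGE + 1:
        raise ValueError(f"closure_age must be >= {MODEL_END_AGE + 1}")
    bands = [_band_label(a) for a in range(MODEL_START_AGE, closure_age, 5)]
    bands.append(closure_band(closure_age))
    return tuple(bands)


def band_index(label: str) -> int:
    """Index of an entry band within :data:`AGE_BANDS`."""
    return AGE_BANDS.index(normalize_band(label))


@dataclass(frozen=True)
class Stratum:
    """One (age band, sex, ethnicity) cell of the modelled population."""

    age_band: str
    sex: str
    ethnicity: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_band", normalize_band(self.age_band))
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}; expected one of {AGE_BANDS}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"unknown ethnicity {self.ethnicity!r}; expected one of {ETHNICITIES}"
            )

    @property
    def start_age(self) -> int:
        return band_start(self.age_band)

    @property
    def midpoint_age(self) -> int:
        """Integer representative age for the band (lower bound + 2)."""
        return self.start_age + 2

    @property
    def group(self) -> tuple[str, str]:
        """The (ethnicity, sex) group this stratum belongs to."""
        return (self.ethnicity, self.sex)


#: All 36 entry strata in published-table order (ethnicity, then sex, then age).
STRATA: tuple[Stratum, ...] = tuple(
    Stratum(band, sex, eth) for eth in ETHNICITIES for sex in SEXES for band in AGE_BANDS
)

#: The four (ethnicity, sex) groups in published-table order.
GROUPS: tuple[tuple[str, str], ...] = tuple(
    (eth, sex) for eth in ETHNICITIES for sex in SEXES
)

_STRATUM_INDEX = {s: i for i, s in enumerate(STRATA)}


def stratum_index(stratum: Stratum) -> int:
    """Stable integer id of a stratum, used to key RNG substreams."""
    return _STRATUM_INDEX[stratum]


def group_label(ethnicity: str, sex: str) -> str:
    """Flat label like ``"non_maori_male"`` used in result tables."""
    return f"{ethnicity}_{sex}"
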