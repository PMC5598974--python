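"""Demographic strata for the district cohort.

The cohort is stratified by five-year age band (65-69 ... 85+), sex
(female/male) and ethnicity (Maori / non-Maori).  The simulation itself
ages people in single years from 65 to 110; band-indexed parameters are
looked up through :data:`BAND_OF_AGE`, with the 85+ band covering ages
85-110.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AGE_MIN = 65
AGE_MAX = 110
N_AGE = AGE_MAX - AGE_MIN + 1  # 46 single-year ages

AGE_BANDS: tuple[str, ...] = ("65-69", "70-74", "75-79", "80-84", "85+")
N_BAND = len(AGE_BANDS)
BAND_LOWER = (65, 70, 75, 80, 85)

SEXES: tuple[str, ...] = ("female", "male")
FEMALE, MALE = 0, 1

ETHNICITIES: tuple[str, ...] = ("maori", "non_maori")
MAORI, NON_MAORI = 0, 1

RISK_GROUPS: tuple[str, ...] = ("low", "high")
LOW, HIGH = 0, 1


def band_index(age: int) -> int:
    """Band index for a single-year age; 85+ covers ages 85-110."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside the modeled range {AGE_MIN}-{AGE_MAX}")
    return min((age - AGE_MIN) // 5, N_BAND - 1)


#: band index for every modeled single-year age (length 46)
BAND_OF_AGE: np.ndarray = np.array([band_index(a) for a in range(AGE_MIN, AGE_MAX + 1)])


@dataclass(frozen=True)
class Stratum:
    """One (age band, sex, ethnicity) cell of the population."""

    age_band: str
    sex: str
    ethnicity: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age_band {self.age_band!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")

    @property
    def indices(self) -> tuple[int, int, int]:
        return (
            AGE_BANDS.index(self.age_band),
            SEXES.index(self.sex),
            ETHNICITIES.index(self.ethnicity),
        )


def all_strata() -> list[Stratum]:
    """The 20 (band, sex, ethnicity) strata in a fixed deterministic order."""
    return [
        Stratum(b, s, e) for b in AGE_BANDS for s in SEXES for e in ETHNICITIES
    ]
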