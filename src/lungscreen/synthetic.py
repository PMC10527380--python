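"""Synthetic stand-ins for model inputs that have no public release.

Three inputs of the analysis come from sources that are not distributable:
the age/sex life table (census), the baseline preclinical state distribution
at cohort entry (first round of a community screening project), and regional
incidence profiles (provincial registries). This module generates plausible
replacements with the statistical structure the model assumes:

* a two-parameter Gompertz mortality curve (monotone, capped), female
  mortality a fixed fraction of male;
* an entry distribution almost entirely disease-free with a small
  preclinical mass split across stages;
* regional incidence multipliers (labelled synthetic) plus the published
  regional per-capita GDP figures that set willingness-to-pay thresholds.

All generators are deterministic functions of their arguments; the ``seed``
argument is accepted for interface uniformity with the stochastic parts of
the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ValidationError
from .states import (
    DIAGNOSED_STATES,
    HealthState,
    N_STATES,
    PRECLINICAL_STATES,
    STATE_LABELS,
)

MIN_AGE = 40
MAX_AGE = 100

# Gompertz q(age) = A * exp(B * age), anchored at q(40) = 2e-3, q(80) = 6e-2.
GOMPERTZ_B = math.log(30.0) / 40.0
GOMPERTZ_A = 2e-3 * math.exp(-MIN_AGE * GOMPERTZ_B)
MORTALITY_CAP = 0.7
FEMALE_FACTOR = 0.8

#: preclinical mass split across stages I:II:IIIA:IIIB:IV at entry
PRECLINICAL_SPLIT = (0.5, 0.2, 0.1, 0.1, 0.1)

REGIONS = ("east", "west", "south", "north")

#: published per-capita GDP (USD, 2021) by representative region
REGIONAL_GDP = {"south": 15234.0, "east": 17520.0, "west": 8941.0, "north": 7326.0}
NATIONAL_GDP = 12551.0

_N_BANDS = 10

# Synthetic age-band incidence multipliers. East: younger-shifted, overall
# high; west: low, especially under 60; south: mildly elevated; north:
# mildly depressed. These are fixtures, not registry estimates.
_REGIONAL_MULTIPLIERS = {
    "east": (1.35, 1.30, 1.25, 1.20, 1.10, 1.05, 1.00, 0.95, 0.95, 0.95),
    "west": (0.60, 0.65, 0.70, 0.75, 0.85, 0.90, 0.95, 0.95, 0.95, 0.95),
    "south": (1.10,) * _N_BANDS,
    "north": (0.85,) * _N_BANDS,
}


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability per integer age and sex."""

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self) -> None:
        for name, q in (("male", self.q_male), ("female", self.q_female)):
            if len(q) != len(self.ages):
                raise ValidationError(f"{name} column length mismatch")
            if np.any(q <= 0.0) or np.any(q >= 1.0):
                raise ValidationError(f"{name} probabilities must lie in (0, 1)")
            if np.any(np.diff(q) < 0.0):
                raise ValidationError(f"{name} mortality must be non-decreasing")
            if q[-1] < 0.2:
                raise ValidationError(f"{name} terminal-age probability below 0.2")

    def annual_q(self, age: int, sex: str) -> float:
        idx = int(age) - int(self.ages[0])
        if not 0 <= idx < len(self.ages):
            raise ValidationError(f"age {age} outside life table")
        q = self.q_male if sex == "male" else self.q_female
        return float(q[idx])

    def weighted(self, male_weight: float) -> np.ndarray:
        """Sex-aggregated annual q, indexed like ``ages``."""
        return male_weight * self.q_male + (1.0 - male_weight) * self.q_female

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": np.concatenate([self.ages, self.ages]),
                "sex": ["male"] * len(self.ages) + ["female"] * len(self.ages),
                "annual_death_probability": np.concatenate(
                    [self.q_male, self.q_female]
                ),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        male = frame[frame["sex"] == "male"].sort_values("age")
        female = frame[frame["sex"] == "female"].sort_values("age")
        return cls(
            ages=male["age"].to_numpy(dtype=int),
            q_male=male["annual_death_probability"].to_numpy(dtype=float),
            q_female=female["annual_death_probability"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))


def make_life_table(seed: int = 0, level: float = 1.0) -> LifeTable:
    """Synthetic Gompertz life table; ``level`` scales mortality overall."""
    if level <= 0.0:
        raise ValidationError(f"level must be positive: {level}")
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    q_male = np.minimum(MORTALITY_CAP, level * GOMPERTZ_A * np.exp(GOMPERTZ_B * ages))
    q_female = np.minimum(MORTALITY_CAP, FEMALE_FACTOR * q_male)
    return LifeTable(ages=ages, q_male=q_male, q_female=q_female)


@dataclass(frozen=True)
class BaselineDistribution:
    """State occupancy at model entry (age 40)."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = self.fractions
        if f.shape != (N_STATES,):
            raise ValidationError(f"expected {N_STATES} state fractions")
        if np.any(f < 0.0) or abs(float(f.sum()) - 1.0) > 1e-9:
            raise ValidationError("fractions must be non-negative and sum to 1")
        if f[HealthState.DEATH] != 0.0 or any(f[s] != 0.0 for s in DIAGNOSED_STATES):
            raise ValidationError("death and diagnosed states must start empty")

    def as_vector(self) -> np.ndarray:
        return self.fractions.copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"state": STATE_LABELS, "fraction": self.fractions})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BaselineDistribution":
        frame = pd.read_csv(path).set_index("state")
        fractions = np.array(
            [float(frame.loc[label, "fraction"]) for label in STATE_LABELS]
        )
        return cls(fractions=fractions)


def make_baseline_distribution(
    seed: int = 0, preclinical_mass: float = 0.004
) -> BaselineDistribution:
    """Entry distribution: (1 - mass) disease-free, mass split 50:20:10:10:10.

    The default 0.4% preclinical prevalence reflects the low single-round
    detection fraction reported by community LDCT programmes in heavy
    smokers at age 40.
    """
    if not 0.0 <= preclinical_mass <= 0.01:
        raise ValidationError(
            f"preclinical mass must lie in [0, 0.01]: {preclinical_mass}"
        )
    fractions = np.zeros(N_STATES)
    fractions[HealthState.NO_LC] = 1.0 - preclinical_mass
    for state, share in zip(PRECLINICAL_STATES, PRECLINICAL_SPLIT):
        fractions[state] = preclinical_mass * share
    return BaselineDistribution(fractions=fractions)


@dataclass(frozen=True)
class RegionalProfile:
    """Synthetic regional incidence multipliers + published GDP per capita."""

    region: str
    multipliers: np.ndarray  # one per 5-year incidence band, 40-44 ... 85+
    gdp_per_capita: float

    def wtp(self, multiple: int) -> float:
        """Willingness-to-pay threshold at ``multiple`` x regional GDP."""
        return float(multiple) * self.gdp_per_capita


def make_regional_profile(region: str, seed: int = 0) -> RegionalProfile:
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}; expected one of {REGIONS}")
    return RegionalProfile(
        region=region,
        multipliers=np.array(_REGIONAL_MULTIPLIERS[region]),
        gdp_per_capita=REGIONAL_GDP[region],
    )
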