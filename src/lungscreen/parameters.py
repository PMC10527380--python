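"""Typed, validated model parameters and the screening-strategy grid.

Every model input is an :class:`UncertainParameter` — a base value plus a
(min, max) range and a distribution family used by the sensitivity analyses.
The full set is a :class:`ModelParameters`, loadable from a nested YAML file
(shipped default: ``data/parameters.yaml``). A completeness check enforces
that exactly the canonical parameter names are present.

Also here: the annual-to-cycle risk conversion used throughout (the model
runs in 3-month cycles), smoking-eligibility arithmetic, and the strategy
grid — 6 starting ages x 3 stopping ages x 2 pack-year criteria = 36 annual
screening strategies, plus the three Chinese guideline strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

CYCLES_PER_YEAR = 4
ENTRY_AGE = 40
EXIT_AGE = 85
N_CYCLES = (EXIT_AGE - ENTRY_AGE) * CYCLES_PER_YEAR  # 180 three-month cycles

START_AGES = (40, 45, 50, 55, 60, 65)
STOP_AGES = (69, 74, 79)
PACKYEAR_CRITERIA = (20, 30)
#: cumulative-exposure strata of current smokers
STRATA = ("20_29", "30plus")

INCIDENCE_BANDS = (
    "40_44", "45_49", "50_54", "55_59", "60_64",
    "65_69", "70_74", "75_79", "80_84", "85plus",
)

DISTRIBUTIONS = ("beta", "gamma", "fixed")


class ConfigurationError(Exception):
    """A required key is missing from, or unknown in, a parameter file."""


class ValidationError(ValueError):
    """A parameter value violates its domain constraints."""


# ---------------------------------------------------------------------------
# canonical parameter names (one per input row of the base-case table)
# ---------------------------------------------------------------------------

def _canonical_names() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"smoking_prevalence.{s}" for s in ("male", "female")]
    names += [
        f"packyear_proportion.{sex}.{st}"
        for sex in ("male", "female")
        for st in STRATA
    ]
    names += [f"incidence.{b}" for b in INCIDENCE_BANDS]
    names += [f"relative_risk.{st}" for st in STRATA]
    prog = {
        "I": ("II", "IIIA", "IIIB", "IV", "diagnosis", "death"),
        "II": ("IIIA", "IIIB", "IV", "diagnosis", "death"),
        "IIIA": ("IIIB", "IV", "diagnosis", "death"),
        "IIIB": ("IV", "diagnosis", "death"),
        "IV": ("diagnosis", "death"),
    }
    names += [f"progression.{s}.{t}" for s, exits in prog.items() for t in exits]
    names += [f"fatality.{s}" for s in ("I", "II", "IIIA", "IIIB", "IV")]
    names += ["screen.sensitivity", "screen.specificity"]
    names += [f"screen.baseline_early_recall.{a}" for a in START_AGES]
    names += [f"screen.baseline_immediate_referral.{a}" for a in START_AGES]
    names += ["screen.annual_early_recall", "screen.annual_immediate_referral"]
    names += [f"utility.{u}" for u in ("no_lc", "I", "II", "III", "IV")]
    names += ["disutility.false_positive"]
    names += ["cost.ldct", "cost.workup"]
    names += [f"cost.treatment.{s}" for s in ("I", "II", "III", "IV")]
    names += ["discount_rate"]
    return tuple(names)


REQUIRED_PARAMETERS: tuple[str, ...] = _canonical_names()

#: name prefixes whose values must lie in [0, 1] even when distribution=fixed
_PROBABILITY_PREFIXES = (
    "smoking_prevalence.", "packyear_proportion.", "incidence.",
    "progression.", "fatality.", "screen.", "utility.", "disutility.",
)


def _is_probability(name: str) -> bool:
    return name.startswith(_PROBABILITY_PREFIXES) or name == "discount_rate"


@dataclass(frozen=True)
class UncertainParameter:
    """One model input: base value, uncertainty range, distribution family."""

    name: str
    base: float
    min: float
    max: float
    distribution: str

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValidationError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        if not (self.min <= self.base <= self.max):
            raise ValidationError(
                f"{self.name}: require min <= base <= max, got "
                f"({self.min}, {self.base}, {self.max})"
            )
        lo, hi = (0.0, 1.0) if self.distribution == "beta" else (0.0, math.inf)
        if self.distribution == "gamma":
            lo, hi = 0.0, math.inf
        if self.distribution != "fixed" and not (lo <= self.min and self.max <= hi):
            raise ValidationError(
                f"{self.name}: range [{self.min}, {self.max}] outside the "
                f"{self.distribution} support"
            )
        if _is_probability(self.name) and not (0.0 <= self.min and self.max <= 1.0):
            raise ValidationError(
                f"{self.name}: probability outside [0, 1]: "
                f"[{self.min}, {self.max}]"
            )

    @property
    def is_varied(self) -> bool:
        """True when the range is non-degenerate (eligible for OWSA)."""
        return self.max > self.min

    @property
    def is_sampled(self) -> bool:
        """True when the parameter is drawn in the PSA."""
        return self.distribution != "fixed" and self.is_varied


# ---------------------------------------------------------------------------
# nested-mapping <-> flat-name plumbing
# ---------------------------------------------------------------------------

def _flatten(tree: Mapping, prefix: str = "") -> dict[str, Mapping]:
    flat: dict[str, Mapping] = {}
    for key, node in tree.items():
        name = f"{prefix}{key}"
        if isinstance(node, Mapping) and "base" in node:
            flat[name] = node
        elif isinstance(node, Mapping):
            flat.update(_flatten(node, prefix=f"{name}."))
        else:
            raise ConfigurationError(
                f"parameter {name!r}: expected a mapping with a 'base' entry"
            )
    return flat


def _nest(flat: Mapping[str, Mapping]) -> dict:
    tree: dict = {}
    for name, leaf in flat.items():
        parts = name.split(".")
        node = tree
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = dict(leaf)
    return tree


@dataclass
class ModelParameters:
    """The complete validated input set of the screening model."""

    params: dict[str, UncertainParameter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_PARAMETERS if n not in self.params]
        if missing:
            raise ConfigurationError(f"missing parameter(s): {', '.join(missing)}")
        unknown = sorted(set(self.params) - set(REQUIRED_PARAMETERS))
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {', '.join(unknown)}")

    # -- access ------------------------------------------------------------

    def __getitem__(self, name: str) -> UncertainParameter:
        try:
            return self.params[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter: {name}") from None

    def base(self, name: str) -> float:
        return self[name].base

    def base_values(self) -> dict[str, float]:
        """Flat {name: base value} snapshot consumed by the engine."""
        return {n: p.base for n, p in self.params.items()}

    def sampled(self) -> list[UncertainParameter]:
        return [p for p in self.params.values() if p.is_sampled]

    def varied(self) -> list[UncertainParameter]:
        return [p for p in self.params.values() if p.is_varied]

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_mapping(cls, tree: Mapping) -> "ModelParameters":
        flat = _flatten(tree)
        params = {
            name: UncertainParameter(
                name=name,
                base=float(leaf["base"]),
                min=float(leaf.get("min", leaf["base"])),
                max=float(leaf.get("max", leaf["base"])),
                distribution=str(leaf.get("distribution", "fixed")),
            )
            for name, leaf in flat.items()
        }
        return cls(params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            tree = yaml.safe_load(fh)
        if not isinstance(tree, Mapping):
            raise ConfigurationError(f"{path}: not a mapping")
        return cls.from_mapping(tree)

    def to_mapping(self) -> dict:
        flat = {
            n: {
                "base": p.base,
                "min": p.min,
                "max": p.max,
                "distribution": p.distribution,
            }
            for n, p in self.params.items()
        }
        return _nest(flat)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter file (YAML)."""
    return ModelParameters.from_yaml(path)


# ---------------------------------------------------------------------------
# rate conversion
# ---------------------------------------------------------------------------

def annual_to_cycle(risk_annual: float, cycles_per_year: int = CYCLES_PER_YEAR) -> float:
    """Convert an annual risk to the per-cycle risk.

    With k cycles per year the conversion is ``1 - (1 - r)**(1/k)``: the
    unique per-cycle probability that compounds back to the annual risk.
    """
    if not 0.0 <= risk_annual <= 1.0:
        raise ValidationError(f"annual risk outside [0, 1]: {risk_annual}")
    if cycles_per_year < 1:
        raise ValidationError(f"cycles_per_year must be >= 1: {cycles_per_year}")
    return 1.0 - (1.0 - risk_annual) ** (1.0 / cycles_per_year)


# ---------------------------------------------------------------------------
# eligibility arithmetic
# ---------------------------------------------------------------------------

def _values_of(params: "ModelParameters | Mapping[str, float]") -> Mapping[str, float]:
    if isinstance(params, ModelParameters):
        return params.base_values()
    return params


def _qualifying_strata(criterion: int) -> tuple[str, ...]:
    if criterion == 20:
        return STRATA
    if criterion == 30:
        return ("30plus",)
    raise ValidationError(f"unknown pack-year criterion: {criterion}")


def eligible_fraction(
    params: "ModelParameters | Mapping[str, float]", criterion: int
) -> dict[str, float]:
    """Fraction of each sex that currently smokes and meets the criterion.

    prevalence(sex) x sum of qualifying exposure-stratum proportions.
    """
    v = _values_of(params)
    strata = _qualifying_strata(criterion)
    return {
        sex: v[f"smoking_prevalence.{sex}"]
        * sum(v[f"packyear_proportion.{sex}.{st}"] for st in strata)
        for sex in ("male", "female")
    }


def sex_weights(
    params: "ModelParameters | Mapping[str, float]",
    criterion: int,
    population_male_share: float = 0.5,
) -> tuple[float, float]:
    """(male, female) mix of the eligible cohort, from a 50/50 base population.

    Only smoking prevalence/strata and all-cause mortality are sex-linked,
    so the eligible mix is proportional to the sex-specific eligible
    fractions; it weights the sex-specific life tables.
    """
    frac = eligible_fraction(params, criterion)
    wm = population_male_share * frac["male"]
    wf = (1.0 - population_male_share) * frac["female"]
    total = wm + wf
    if total <= 0.0:
        raise ValidationError("empty eligible population")
    return wm / total, wf / total


def stratum_weights(
    params: "ModelParameters | Mapping[str, float]",
    criterion: int,
    population_male_share: float = 0.5,
) -> dict[str, float]:
    """Population weights of the exposure strata within the eligible cohort."""
    v = _values_of(params)
    strata = _qualifying_strata(criterion)
    raw = {
        st: population_male_share * v["smoking_prevalence.male"]
        * v[f"packyear_proportion.male.{st}"]
        + (1.0 - population_male_share) * v["smoking_prevalence.female"]
        * v[f"packyear_proportion.female.{st}"]
        for st in strata
    }
    total = sum(raw.values())
    if total <= 0.0:
        raise ValidationError("empty eligible population")
    return {st: w / total for st, w in raw.items()}


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Strategy:
    """An annual LDCT screening strategy: age window + pack-year criterion."""

    start_age: int
    stop_age: int
    packyear_criterion: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start_age >= self.stop_age:
            raise ValidationError(
                f"start_age {self.start_age} must be below stop_age {self.stop_age}"
            )
        if self.packyear_criterion not in PACKYEAR_CRITERIA:
            raise ValidationError(
                f"pack-year criterion must be one of {PACKYEAR_CRITERIA}: "
                f"{self.packyear_criterion}"
            )
        if self.label is None:
            object.__setattr__(
                self,
                "label",
                f"{self.start_age}-{self.stop_age}-{self.packyear_criterion}py",
            )

    @property
    def n_rounds(self) -> int:
        """Number of annual screening rounds offered."""
        return self.stop_age - self.start_age + 1

    def screens_stratum(self, stratum: str) -> bool:
        if stratum not in STRATA:
            raise ValidationError(f"unknown stratum: {stratum}")
        return stratum == "30plus" or self.packyear_criterion == 20

    @classmethod
    def parse(cls, text: str) -> "Strategy":
        """Parse "start-stop-criterion", e.g. ``55-79-20``."""
        try:
            start, stop, crit = (int(x.removesuffix("py")) for x in text.split("-"))
        except ValueError:
            raise ValidationError(f"cannot parse strategy {text!r}") from None
        return cls(start, stop, crit)


def strategy_grid() -> list[Strategy]:
    """The 36-strategy cross-product of start/stop ages and criteria."""
    return [
        Strategy(start, stop, crit)
        for crit in PACKYEAR_CRITERIA
        for start in START_AGES
        for stop in STOP_AGES
    ]


def guideline_strategies() -> list[Strategy]:
    """The three Chinese guideline-recommended strategies."""
    return [
        Strategy(50, 74, 20, label="2018 guideline"),
        Strategy(50, 74, 30, label="2021 guideline"),
        Strategy(45, 74, 20, label="2022 guideline"),
    ]
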