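"""Packaged input fixtures: the base-case parameter file and the published
reference cost/QALY totals used to validate the frontier arithmetic."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cea import StrategyOutcome
from .parameters import ModelParameters, Strategy

_DATA = resources.files("lungscreen") / "data"


def default_parameters_path():
    """Path-like handle to the shipped base-case parameter file."""
    return _DATA / "parameters.yaml"


def default_parameters() -> ModelParameters:
    with resources.as_file(default_parameters_path()) as path:
        return ModelParameters.from_yaml(path)


def load_reference_outcomes() -> list[StrategyOutcome]:
    """Published base-case totals for the 13 reported strategies.

    Discounted cost (USD) and QALYs per person for the no-screening
    comparator, the nine frontier strategies, and the three guideline
    strategies, as reported by the source analysis. These are injected
    inputs for validating ICER and dominance arithmetic, not outputs of
    this package's engine.
    """
    with resources.as_file(_DATA / "reference_outcomes.csv") as path:
        frame = pd.read_csv(path)
    outcomes = []
    for row in frame.itertuples(index=False):
        strategy = None
        if pd.notna(row.start_age):
            strategy = Strategy(
                int(row.start_age), int(row.stop_age), int(row.packyear_criterion)
            )
        outcomes.append(
            StrategyOutcome(
                label=str(row.label),
                cost=float(row.cost_usd),
                qalys=float(row.qalys),
                strategy=strategy,
            )
        )
    return outcomes
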