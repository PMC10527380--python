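"""Deterministic Markov cohort engine.

Runs the cohort from age 40 to 85 in 3-month cycles, composing the
natural-history transition matrices with the screening overlay, and
accumulates discounted costs and QALYs.

Event order within a cycle: (1) if the strategy screens at this cycle (every
4th cycle inside the age window), the screening round is applied to the
start-of-cycle occupancy; (2) the natural-history transition moves the
cohort to the end-of-cycle occupancy. Cycle rewards (state utilities,
per-cycle treatment costs) use, under the half-cycle correction, the mean of
the post-screen start-of-cycle and end-of-cycle occupancies; event costs
(screening rounds, diagnostic workups) and the one-cycle false-positive
disutility are charged at the cycle they occur. Discounting applies the
annual rate in cycle units: factor ``(1 + r) ** (-cycle / 4)``.

Strategies are evaluated on a common cohort of current smokers with at
least 20 pack-years, mixing the 20-29 and >=30 pack-year strata by their
population weights; a 30-pack-year strategy screens only the >=30 stratum.
``blend_strata`` instead reports the per-eligible-person mixture for a
strategy's own eligible population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import StrategyOutcome
from .natural_history import build_matrices
from .parameters import (
    CYCLES_PER_YEAR,
    ENTRY_AGE,
    ModelParameters,
    N_CYCLES,
    Strategy,
    ValidationError,
    sex_weights,
    stratum_weights,
)
from .screening import ANNUAL, BASELINE, ScreeningEvent, apply_screen
from .states import (
    DIAGNOSED_STATES,
    HealthState,
    N_STATES,
    PRECLINICAL_STATES,
    STAGE_GROUP,
    STAGES,
    STATE_LABELS,
)
from .synthetic import BaselineDistribution, LifeTable

NO_SCREENING_LABEL = "No screening"


def _values_of(params: ModelParameters | Mapping[str, float]) -> dict[str, float]:
    if isinstance(params, ModelParameters):
        return params.base_values()
    return dict(params)


def _utility_vector(values: Mapping[str, float]) -> np.ndarray:
    u = np.zeros(N_STATES)
    u[: HealthState.DX_I] = values["utility.no_lc"]  # disease-free + preclinical
    for stage, state in zip(STAGES, DIAGNOSED_STATES):
        u[state] = values[f"utility.{STAGE_GROUP[stage]}"]
    return u


def _treatment_vector(values: Mapping[str, float]) -> np.ndarray:
    c = np.zeros(N_STATES)
    for stage, state in zip(STAGES, DIAGNOSED_STATES):
        c[state] = values[f"cost.treatment.{STAGE_GROUP[stage]}"]
    return c


@dataclass
class CohortTrace:
    """Full per-cycle record of one cohort run."""

    occupancy: np.ndarray  # (n_cycles + 1, 12)
    overdiagnosed: np.ndarray  # (n_cycles + 1,)
    cost: np.ndarray  # undiscounted, per cycle
    qaly: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    events: list[ScreeningEvent] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.disc_qaly.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qalys_undiscounted(self) -> float:
        return float(self.qaly.sum())

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_cycles
        frame = pd.DataFrame(
            self.occupancy[: n + 1], columns=[f"occ_{s}" for s in STATE_LABELS]
        )
        frame.insert(0, "cycle", np.arange(n + 1))
        frame.insert(1, "age", ENTRY_AGE + np.arange(n + 1) / CYCLES_PER_YEAR)
        frame["overdiagnosed"] = self.overdiagnosed
        for name, arr in (
            ("cost", self.cost),
            ("qaly", self.qaly),
            ("disc_cost", self.disc_cost),
            ("disc_qaly", self.disc_qaly),
        ):
            frame[name] = np.append(arr, np.nan)
        return frame


def _simulate(
    strategy: Strategy | None,
    values: Mapping[str, float],
    matrices: np.ndarray,
    baseline_vec: np.ndarray,
    *,
    participation: float = 1.0,
    half_cycle: bool = True,
    rr_diagnosis: float = 1.0,
    overdiagnosis_rate: float = 0.0,
) -> CohortTrace:
    """Inner loop over cycles, given prebuilt transition matrices."""
    n_cycles = matrices.shape[0]
    utilities = _utility_vector(values)
    treatment = _treatment_vector(values)
    u_dx_i = utilities[HealthState.DX_I]
    c_dx_i = treatment[HealthState.DX_I]
    workup = values["cost.workup"]
    rate = values["discount_rate"]
    discount = (1.0 + rate) ** (-np.arange(n_cycles) / CYCLES_PER_YEAR)

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    over = np.zeros(n_cycles + 1)
    cost = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    events: list[ScreeningEvent] = []

    x = baseline_vec.copy()
    od = 0.0
    occupancy[0] = x
    for t in range(n_cycles):
        age_year = ENTRY_AGE + t // CYCLES_PER_YEAR
        cycle_cost = 0.0
        fp_penalty = 0.0
        if (
            strategy is not None
            and t % CYCLES_PER_YEAR == 0
            and strategy.start_age <= age_year <= strategy.stop_age
        ):
            round_type = BASELINE if age_year == strategy.start_age else ANNUAL
            x, event = apply_screen(
                x,
                round_type,
                values,
                strategy,
                participation,
                cycle=t,
                age=ENTRY_AGE + t / CYCLES_PER_YEAR,
                rr_diagnosis=rr_diagnosis,
                overdiagnosis_rate=overdiagnosis_rate,
            )
            od += event.overdiagnosed_mass
            cycle_cost += event.cost
            fp_penalty = event.disutility
            events.append(event)

        matrix = matrices[t]
        x_next = x @ matrix
        q_c = matrix[HealthState.NO_LC, HealthState.DEATH]
        od_next = od * (1.0 - q_c)
        x_next[HealthState.DEATH] += od * q_c  # other-cause deaths of the
        # overdiagnosed compartment keep total mass at 1

        # clinical-presentation flux pays the diagnostic workup once
        flux = sum(
            x[pre] * matrix[pre, dx]
            for pre, dx in zip(PRECLINICAL_STATES, DIAGNOSED_STATES)
        )
        cycle_cost += flux * workup

        occ = 0.5 * (x + x_next) if half_cycle else x
        od_occ = 0.5 * (od + od_next) if half_cycle else od
        cycle_cost += float(occ @ treatment) + od_occ * c_dx_i
        cycle_qaly = (
            float(occ @ utilities) / CYCLES_PER_YEAR
            + od_occ * u_dx_i / CYCLES_PER_YEAR
            - fp_penalty
        )

        cost[t] = cycle_cost
        qaly[t] = cycle_qaly
        x = x_next
        od = od_next
        occupancy[t + 1] = x
        over[t + 1] = od

    return CohortTrace(
        occupancy=occupancy,
        overdiagnosed=over,
        cost=cost,
        qaly=qaly,
        disc_cost=cost * discount,
        disc_qaly=qaly * discount,
        events=events,
    )


def run_cohort(
    strategy: Strategy | None,
    params: ModelParameters | Mapping[str, float],
    life_table: LifeTable,
    baseline: BaselineDistribution,
    *,
    stratum: str = "30plus",
    participation: float = 1.0,
    half_cycle: bool = True,
    rr_diagnosis: float = 1.0,
    overdiagnosis_rate: float = 0.0,
    incidence_multipliers: np.ndarray | None = None,
    cohort_criterion: int = 20,
    n_cycles: int = N_CYCLES,
    clamp_exits: bool = False,
) -> CohortTrace:
    """Run a single-stratum cohort; ``strategy=None`` is the no-screening arm."""
    values = _values_of(params)
    male_w, _ = sex_weights(values, cohort_criterion)
    matrices = build_matrices(
        values,
        life_table.weighted(male_w),
        stratum,
        n_cycles,
        incidence_multipliers=incidence_multipliers,
        clamp_exits=clamp_exits,
    )
    return _simulate(
        strategy,
        values,
        matrices,
        baseline.as_vector(),
        participation=participation,
        half_cycle=half_cycle,
        rr_diagnosis=rr_diagnosis,
        overdiagnosis_rate=overdiagnosis_rate,
    )


def evaluate_outcomes(
    strategies: Sequence[Strategy | None],
    params: ModelParameters | Mapping[str, float],
    life_table: LifeTable,
    baseline: BaselineDistribution,
    *,
    participation: float = 1.0,
    half_cycle: bool = True,
    rr_diagnosis: float = 1.0,
    overdiagnosis_rate: float = 0.0,
    incidence_multipliers: np.ndarray | None = None,
    cohort_criterion: int = 20,
    n_cycles: int = N_CYCLES,
    clamp_exits: bool = False,
) -> list[StrategyOutcome]:
    """Evaluate strategies on the common >=20-pack-year smoker cohort.

    Transition matrices are built once per exposure stratum and unscreened
    stratum runs are shared across strategies, so a full grid evaluation
    costs little more than one run per strategy.
    """
    values = _values_of(params)
    weights = stratum_weights(values, cohort_criterion)
    male_w, _ = sex_weights(values, cohort_criterion)
    annual_q = life_table.weighted(male_w)
    baseline_vec = baseline.as_vector()

    matrices = {
        st: build_matrices(
            values, annual_q, st, n_cycles,
            incidence_multipliers=incidence_multipliers, clamp_exits=clamp_exits,
        )
        for st in weights
    }
    cache: dict[tuple[str, str | None], tuple[float, float]] = {}

    def totals(st: str, strat: Strategy | None) -> tuple[float, float]:
        key = (st, strat.label if strat is not None else None)
        if key not in cache:
            trace = _simulate(
                strat,
                values,
                matrices[st],
                baseline_vec,
                participation=participation,
                half_cycle=half_cycle,
                rr_diagnosis=rr_diagnosis,
                overdiagnosis_rate=overdiagnosis_rate,
            )
            cache[key] = (trace.total_cost, trace.total_qalys)
        return cache[key]

    outcomes = []
    for strategy in strategies:
        cost = 0.0
        qalys = 0.0
        for st, w in weights.items():
            effective = (
                strategy
                if strategy is not None and strategy.screens_stratum(st)
                else None
            )
            c, q = totals(st, effective)
            cost += w * c
            qalys += w * q
        outcomes.append(
            StrategyOutcome(
                label=strategy.label if strategy else NO_SCREENING_LABEL,
                cost=cost,
                qalys=qalys,
                strategy=strategy,
            )
        )
    return outcomes


def evaluate_strategy(
    strategy: Strategy | None,
    params: ModelParameters | Mapping[str, float],
    life_table: LifeTable,
    baseline: BaselineDistribution,
    **kwargs,
) -> StrategyOutcome:
    return evaluate_outcomes([strategy], params, life_table, baseline, **kwargs)[0]


def blend_strata(
    strategy: Strategy,
    params: ModelParameters | Mapping[str, float],
    life_table: LifeTable,
    baseline: BaselineDistribution,
    *,
    participation: float = 1.0,
    **kwargs,
) -> tuple[float, float]:
    """Expected (cost, QALYs) per eligible person for a strategy.

    The eligible population is defined by the strategy's own pack-year
    criterion: a 30-pack-year strategy's figure is exactly the >=30-stratum
    run; a 20-pack-year strategy mixes both strata by their population
    weights. Every eligible member is offered screening.
    """
    values = _values_of(params)
    weights = stratum_weights(values, strategy.packyear_criterion)
    cost = 0.0
    qalys = 0.0
    for st, w in weights.items():
        trace = run_cohort(
            strategy,
            values,
            life_table,
            baseline,
            stratum=st,
            participation=participation,
            cohort_criterion=strategy.packyear_criterion,
            **kwargs,
        )
        cost += w * trace.total_cost
        qalys += w * trace.total_qalys
    return cost, qalys


def run_grid(
    params: ModelParameters | Mapping[str, float],
    life_table: LifeTable,
    baseline: BaselineDistribution,
    strategies: Sequence[Strategy] | None = None,
    include_guidelines: bool = True,
    **kwargs,
) -> list[StrategyOutcome]:
    """No-screening comparator plus the full strategy grid."""
    from .parameters import guideline_strategies, strategy_grid

    if strategies is None:
        strategies = strategy_grid()
        if include_guidelines:
            strategies = strategies + guideline_strategies()
    return evaluate_outcomes(
        [None, *strategies], params, life_table, baseline, **kwargs
    )
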