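"""One-way and probabilistic sensitivity analysis.

One-way analysis re-runs a two-strategy comparison with a single parameter
pinned at each end of its range and reports the ICER pair; the tornado
ordering ranks parameters by the ICER spread. The PSA draws every
non-fixed parameter from a beta or gamma distribution fitted by the method
of moments — mean at the base value, standard deviation ``(max - min) /
(2 x 1.96)``, treating the printed range as a 95% interval — using common
random numbers across strategies within an iteration. Cost-effectiveness
acceptability curves report, per willingness-to-pay value, the fraction of
iterations in which each strategy attains the maximal net monetary benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import StrategyOutcome, icer
from .engine import evaluate_outcomes
from .parameters import (
    ModelParameters,
    Strategy,
    UncertainParameter,
    ValidationError,
)
from .synthetic import BaselineDistribution, LifeTable

logger = logging.getLogger(__name__)

Sampler = Callable[[np.random.Generator, int], np.ndarray]


def fit_distribution(p: UncertainParameter) -> Sampler:
    """Method-of-moments sampler for one parameter.

    Degenerate ranges give a point mass at the base value. A beta fit whose
    moment constraint is infeasible on [0, 1] falls back to a beta rescaled
    onto [min, max] (logged); a fit infeasible even there collapses to a
    point mass.
    """
    if p.distribution == "fixed" or not p.is_varied:
        return lambda rng, size: np.full(size, p.base)

    mean = p.base
    sd = (p.max - p.min) / (2.0 * 1.96)
    var = sd * sd

    if p.distribution == "gamma":
        if mean <= 0.0:
            return lambda rng, size: np.full(size, p.base)
        shape = mean * mean / var
        scale = var / mean
        return lambda rng, size: rng.gamma(shape, scale, size)

    if p.distribution == "beta":
        if 0.0 < mean < 1.0 and var < mean * (1.0 - mean):
            common = mean * (1.0 - mean) / var - 1.0
            a, b = mean * common, (1.0 - mean) * common
            return lambda rng, size: rng.beta(a, b, size)
        # rescale onto the printed range
        width = p.max - p.min
        m2 = (mean - p.min) / width
        v2 = var / (width * width)
        if 0.0 < m2 < 1.0 and v2 < m2 * (1.0 - m2):
            logger.warning(
                "%s: beta moments infeasible on [0, 1]; using range-rescaled beta",
                p.name,
            )
            common = m2 * (1.0 - m2) / v2 - 1.0
            a, b = m2 * common, (1.0 - m2) * common
            return lambda rng, size: p.min + width * rng.beta(a, b, size)
        logger.warning("%s: beta moments infeasible; using point mass", p.name)
        return lambda rng, size: np.full(size, p.base)

    raise ValidationError(f"{p.name}: cannot sample distribution {p.distribution}")


# ---------------------------------------------------------------------------
# one-way sensitivity
# ---------------------------------------------------------------------------

def _pair_icer(
    values: Mapping[str, float],
    life_table: LifeTable,
    baseline: BaselineDistribution,
    strategy: Strategy | None,
    comparator: Strategy | None,
    **engine_kwargs,
) -> float:
    # bound/sampled values can push a state's joint exits past 1; project
    engine_kwargs.setdefault("clamp_exits", True)
    comp, strat = evaluate_outcomes(
        [comparator, strategy], values, life_table, baseline, **engine_kwargs
    )
    return icer(comp, strat)


def one_way(
    param_name: str,
    params: ModelParameters,
    life_table: LifeTable,
    baseline: BaselineDistribution,
    strategy: Strategy | None,
    comparator: Strategy | None,
    lo: float | None = None,
    hi: float | None = None,
    **engine_kwargs,
) -> tuple[float, float]:
    """ICER of strategy vs comparator at the two bounds of one parameter."""
    p = params[param_name]
    if not p.is_varied:
        raise ValidationError(f"{param_name} has a degenerate range")
    lo = p.min if lo is None else lo
    hi = p.max if hi is None else hi
    base_values = params.base_values()
    results = []
    for bound in (lo, hi):
        values = dict(base_values)
        values[param_name] = bound
        results.append(
            _pair_icer(
                values, life_table, baseline, strategy, comparator, **engine_kwargs
            )
        )
    return results[0], results[1]


def tornado(
    params: ModelParameters,
    life_table: LifeTable,
    baseline: BaselineDistribution,
    strategy: Strategy | None,
    comparator: Strategy | None,
    param_names: Sequence[str] | None = None,
    **engine_kwargs,
) -> pd.DataFrame:
    """One-way ICER ranges for every varied parameter, widest spread first."""
    if param_names is None:
        param_names = [p.name for p in params.varied()]
    base_icer = _pair_icer(
        params.base_values(), life_table, baseline, strategy, comparator,
        **engine_kwargs,
    )
    rows = []
    for name in param_names:
        p = params[name]
        icer_lo, icer_hi = one_way(
            name, params, life_table, baseline, strategy, comparator, **engine_kwargs
        )
        rows.append(
            {
                "parameter": name,
                "low": p.min,
                "high": p.max,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "spread": abs(icer_hi - icer_lo),
            }
        )
    frame = pd.DataFrame(rows).sort_values("spread", ascending=False)
    frame.attrs["base_icer"] = base_icer
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity
# ---------------------------------------------------------------------------

@dataclass
class PsaResult:
    """Per-iteration parameter draws and strategy outcomes."""

    outcomes: pd.DataFrame  # columns: iteration, strategy, cost, qalys
    draws: pd.DataFrame  # one column per sampled parameter
    seed: int

    @property
    def n_iterations(self) -> int:
        return int(self.outcomes["iteration"].max()) + 1

    def costs(self) -> pd.DataFrame:
        return self.outcomes.pivot(index="iteration", columns="strategy", values="cost")

    def qalys(self) -> pd.DataFrame:
        return self.outcomes.pivot(
            index="iteration", columns="strategy", values="qalys"
        )

    def incremental(self, strategy: str, comparator: str) -> pd.DataFrame:
        """Per-iteration (delta cost, delta QALYs) scatter."""
        costs, qalys = self.costs(), self.qalys()
        return pd.DataFrame(
            {
                "delta_cost": costs[strategy] - costs[comparator],
                "delta_qalys": qalys[strategy] - qalys[comparator],
            }
        )


def run_psa(
    params: ModelParameters,
    life_table: LifeTable,
    baseline: BaselineDistribution,
    strategies: Sequence[Strategy | None],
    n_iter: int,
    seed: int,
    **engine_kwargs,
) -> PsaResult:
    """Monte-Carlo parameter uncertainty analysis.

    One joint parameter draw per iteration is applied to every strategy
    (common random numbers), so incremental comparisons within an iteration
    are free of between-arm sampling noise. Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValidationError(f"n_iter must be >= 1: {n_iter}")
    rng = np.random.default_rng(seed)
    sampled = sorted(params.sampled(), key=lambda p: p.name)
    draws = {p.name: fit_distribution(p)(rng, n_iter) for p in sampled}
    draws_frame = pd.DataFrame(draws)

    engine_kwargs.setdefault("clamp_exits", True)
    base_values = params.base_values()
    records = []
    for i in range(n_iter):
        values = dict(base_values)
        for name, column in draws.items():
            values[name] = float(column[i])
        for outcome in evaluate_outcomes(
            strategies, values, life_table, baseline, **engine_kwargs
        ):
            records.append(
                {
                    "iteration": i,
                    "strategy": outcome.label,
                    "cost": outcome.cost,
                    "qalys": outcome.qalys,
                }
            )
    return PsaResult(outcomes=pd.DataFrame(records), draws=draws_frame, seed=seed)


def ceac(
    psa: PsaResult | pd.DataFrame,
    wtp_grid: Sequence[float],
    strategies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each WTP value, the probability that each strategy in the comparison
    set has the maximal net monetary benefit. Probabilities across an
    exhaustive comparison set sum to 1 at every threshold; ties split the
    count evenly.
    """
    outcomes = psa.outcomes if isinstance(psa, PsaResult) else psa
    if outcomes.empty:
        raise ValidationError("empty PSA sample")
    costs = outcomes.pivot(index="iteration", columns="strategy", values="cost")
    qalys = outcomes.pivot(index="iteration", columns="strategy", values="qalys")
    if strategies is not None:
        costs, qalys = costs[list(strategies)], qalys[list(strategies)]
    labels = list(costs.columns)

    rows = []
    for wtp in wtp_grid:
        nb = wtp * qalys.to_numpy() - costs.to_numpy()
        best = nb.max(axis=1, keepdims=True)
        winners = nb >= best - 1e-12
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for label, prob in zip(labels, probs):
            rows.append({"wtp": wtp, "strategy": label, "probability": prob})
    return pd.DataFrame(rows)
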