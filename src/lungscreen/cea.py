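"""Strategy comparison: ICERs, dominance, efficiency frontier, WTP choice.

Given total discounted cost and QALYs per strategy, the frontier is built by
removing absolutely dominated strategies (costlier, no more effective than
some alternative), then extendedly dominated ones (incremental ICER above
that of a more effective option), leaving strategies whose sequential ICERs
strictly increase with effectiveness. The optimal strategy at a
willingness-to-pay threshold is the most effective frontier member whose
incremental ICER does not exceed the threshold — equivalently, the frontier
member with ICER below WTP that maximises net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .parameters import Strategy, ValidationError

EFFICIENT = "efficient"
ABS_DOMINATED = "absolutely dominated"
EXT_DOMINATED = "extendedly dominated"


class IcerUndefinedError(ZeroDivisionError):
    """Both strategies yield identical QALYs; the ICER is undefined."""


@dataclass(frozen=True)
class StrategyOutcome:
    """Total discounted cost (USD) and QALYs of one strategy."""

    label: str
    cost: float
    qalys: float
    strategy: Strategy | None = None

    def __post_init__(self) -> None:
        if self.cost < 0.0 or self.qalys < 0.0:
            raise ValidationError(
                f"{self.label}: cost and QALYs must be non-negative"
            )


def icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Incremental cost-effectiveness ratio of b versus a (USD per QALY)."""
    dq = b.qalys - a.qalys
    if dq == 0.0:
        raise IcerUndefinedError(f"{a.label} and {b.label} have equal QALYs")
    return (b.cost - a.cost) / dq


def net_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit: WTP x QALYs - cost."""
    if wtp < 0.0:
        raise ValidationError(f"WTP must be non-negative: {wtp}")
    return wtp * outcome.qalys - outcome.cost


def _tie_key(outcome: StrategyOutcome) -> tuple:
    # ties in (cost, QALYs) keep the strategy offering fewer screening
    # rounds, then the narrower eligibility (higher pack-year criterion),
    # then the lexicographically earlier label; a comparator without a
    # strategy sorts first
    if outcome.strategy is None:
        return (0, 0, outcome.label)
    return (
        outcome.strategy.n_rounds,
        -outcome.strategy.packyear_criterion,
        outcome.label,
    )


@dataclass
class FrontierResult:
    """Dominance classification and frontier ICERs for a strategy set."""

    outcomes: list[StrategyOutcome]
    classification: dict[str, str]
    frontier: list[StrategyOutcome]  # sorted by increasing QALYs
    frontier_icers: dict[str, float]  # vs previous efficient (comparator: none)
    icers_vs_baseline: dict[str, float]
    baseline_label: str

    def table(self) -> pd.DataFrame:
        """Report mirroring the base-case results layout.

        Costs rounded to 2 dp, QALYs to 5 dp, ICERs to 2 dp; the
        classification text replaces the frontier ICER for dominated rows.
        """
        rows = []
        for o in self.outcomes:
            cls = self.classification[o.label]
            if o.label == self.baseline_label:
                vs_base, vs_prev = "", ""
            else:
                vs_base = round(self.icers_vs_baseline[o.label], 2)
                vs_prev = (
                    round(self.frontier_icers[o.label], 2)
                    if cls == EFFICIENT
                    else cls
                )
            rows.append(
                {
                    "strategy": o.label,
                    "start_age": o.strategy.start_age if o.strategy else "",
                    "stop_age": o.strategy.stop_age if o.strategy else "",
                    "packyear_criterion": (
                        o.strategy.packyear_criterion if o.strategy else ""
                    ),
                    "cost_usd": round(o.cost, 2),
                    "qalys": round(o.qalys, 5),
                    "icer_vs_no_screening": vs_base,
                    "icer_vs_previous_efficient": vs_prev,
                    "classification": cls,
                }
            )
        return pd.DataFrame(rows)


def build_frontier(
    outcomes: Sequence[StrategyOutcome], baseline_label: str | None = None
) -> FrontierResult:
    """Classify strategies and assemble the efficiency frontier.

    The baseline (comparator) defaults to the cheapest outcome; ICERs versus
    the baseline are reported for every other strategy regardless of
    dominance status.
    """
    if len(outcomes) < 2:
        raise ValidationError("need at least two outcomes to compare")
    outcomes = list(outcomes)
    labels = [o.label for o in outcomes]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate strategy labels")

    if baseline_label is None:
        baseline = min(outcomes, key=lambda o: (o.cost, o.qalys))
        baseline_label = baseline.label
    else:
        baseline = next(o for o in outcomes if o.label == baseline_label)

    classification: dict[str, str] = {}

    # absolute dominance (pairwise); exact ties resolved toward fewer rounds
    for o in outcomes:
        dominated = any(
            (p.cost <= o.cost and p.qalys >= o.qalys)
            and (
                p.cost < o.cost
                or p.qalys > o.qalys
                or _tie_key(p) < _tie_key(o)
            )
            for p in outcomes
            if p is not o
        )
        classification[o.label] = ABS_DOMINATED if dominated else EFFICIENT

    candidates = sorted(
        (o for o in outcomes if classification[o.label] == EFFICIENT),
        key=lambda o: (o.qalys, o.cost),
    )

    # extended dominance: drop any candidate whose incremental ICER exceeds
    # that of the next more effective candidate, until ICERs increase
    while True:
        if len(candidates) < 3:
            break
        icers = [
            icer(candidates[i - 1], candidates[i]) for i in range(1, len(candidates))
        ]
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                classification[candidates[i + 1].label] = EXT_DOMINATED
                del candidates[i + 1]
                removed = True
                break
        if not removed:
            break

    frontier = candidates
    frontier_icers = {
        frontier[i].label: icer(frontier[i - 1], frontier[i])
        for i in range(1, len(frontier))
    }
    icers_vs_baseline = {
        o.label: icer(baseline, o)
        for o in outcomes
        if o.label != baseline_label and o.qalys != baseline.qalys
    }
    return FrontierResult(
        outcomes=outcomes,
        classification=classification,
        frontier=frontier,
        frontier_icers=frontier_icers,
        icers_vs_baseline=icers_vs_baseline,
        baseline_label=baseline_label,
    )


def optimal_at_wtp(frontier: FrontierResult, wtp: float) -> str | None:
    """Most effective frontier strategy whose incremental ICER is within WTP.

    Returns ``None`` when even the first frontier step exceeds the
    threshold (no screening strategy is cost-effective).
    """
    if wtp <= 0.0:
        return None
    best: str | None = None
    for o in frontier.frontier:
        if o.label == frontier.baseline_label:
            continue
        if o.label not in frontier.frontier_icers:
            continue
        if frontier.frontier_icers[o.label] <= wtp:
            best = o.label
        else:
            break
    return best
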