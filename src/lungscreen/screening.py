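"""LDCT screening overlay: detection, false positives, round costs.

Screening rounds occur every 4th cycle while the cohort age lies inside the
strategy's window. Among attendees, each preclinical occupant is detected
(moved to the diagnosed state of the same stage) with the test sensitivity;
disease-free attendees become false positives with 1 - specificity,
suffering the false-positive disutility for one cycle but remaining
disease-free. Round costs per attendee combine the scan itself with the
early-recall pathway (one repeat scan) and the immediate-referral pathway
(full diagnostic workup); detected cases are additionally charged the
workup once. Baseline-round recall/referral rates depend on the age at
which screening starts; ages between the tabulated grid points use the
nearest lower tabulated age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import START_AGES, Strategy, ValidationError
from .states import DIAGNOSED_STATES, HealthState, PRECLINICAL_STATES

BASELINE = "baseline"
ANNUAL = "annual"


@dataclass(frozen=True)
class ScreeningEvent:
    """Outcome of one screening round applied to the cohort."""

    cycle: int
    age: float
    round_type: str
    attendee_fraction: float
    true_positive_by_stage: np.ndarray  # mass detected, per stage I..IV
    false_positive_mass: float
    overdiagnosed_mass: float
    cost: float
    disutility: float  # undiscounted QALY decrement incurred this cycle

    @property
    def detected_mass(self) -> float:
        return float(self.true_positive_by_stage.sum()) + self.overdiagnosed_mass


def baseline_rate_age(start_age: int) -> int:
    """Tabulated age whose baseline recall/referral rates apply."""
    if start_age < START_AGES[0]:
        raise ValidationError(
            f"no baseline screening rates below age {START_AGES[0]}"
        )
    return max(a for a in START_AGES if a <= start_age)


def screen_round_cost(
    round_type: str, start_age: int, values: dict[str, float]
) -> float:
    """Cost per attendee (USD): scan + recall repeat scan + referral workup."""
    if round_type == BASELINE:
        age = baseline_rate_age(start_age)
        early = values[f"screen.baseline_early_recall.{age}"]
        referral = values[f"screen.baseline_immediate_referral.{age}"]
    elif round_type == ANNUAL:
        early = values["screen.annual_early_recall"]
        referral = values["screen.annual_immediate_referral"]
    else:
        raise ValidationError(f"unknown round type: {round_type}")
    ldct = values["cost.ldct"]
    return ldct + early * ldct + referral * values["cost.workup"]


def apply_screen(
    occupancy: np.ndarray,
    round_type: str,
    values: dict[str, float],
    strategy: Strategy,
    participation: float,
    *,
    cycle: int = 0,
    age: float | None = None,
    rr_diagnosis: float = 1.0,
    overdiagnosis_rate: float = 0.0,
) -> tuple[np.ndarray, ScreeningEvent]:
    """Apply one screening round; returns updated occupancy and the event.

    In the overdiagnosis scenario ``rr_diagnosis`` inflates the detection
    probability applied to preclinical attendees (capped at 1), and the
    overdiagnosed share of all screen detections — indolent lesions that
    would never have progressed, hence drawn from the disease-free mass —
    is ``overdiagnosis_rate``; both default to the identity. Overdiagnosed
    mass is returned on the event and tracked by the engine in a separate
    compartment subject only to other-cause mortality, so its survival
    equals the no-cancer counterfactual while it accrues stage-I treatment
    cost and stage-I utility; occupancy + overdiagnosed mass is conserved.
    """
    if not 0.0 <= participation <= 1.0:
        raise ValidationError(f"participation outside [0, 1]: {participation}")
    detection = min(1.0, values["screen.sensitivity"] * rr_diagnosis)
    specificity = values["screen.specificity"]

    x = occupancy.copy()
    pre = np.array([x[s] for s in PRECLINICAL_STATES])
    detected = pre * participation * detection
    for i, (pre_s, dx_s) in enumerate(zip(PRECLINICAL_STATES, DIAGNOSED_STATES)):
        x[pre_s] -= detected[i]
        x[dx_s] += detected[i]

    # overdiagnosed = rate of ALL detections: od / (od + true) = rate
    no_lc_attending = float(x[HealthState.NO_LC]) * participation
    overdiagnosed = 0.0
    if overdiagnosis_rate > 0.0:
        overdiagnosed = min(
            float(detected.sum()) * overdiagnosis_rate / (1.0 - overdiagnosis_rate),
            no_lc_attending,
        )
        x[HealthState.NO_LC] -= overdiagnosed
        no_lc_attending -= overdiagnosed

    false_positive = no_lc_attending * (1.0 - specificity)

    attendees = participation * (
        float(occupancy[HealthState.NO_LC]) + float(pre.sum())
    )
    cost = attendees * screen_round_cost(round_type, strategy.start_age, values)
    cost += (float(detected.sum()) + overdiagnosed) * values["cost.workup"]

    event = ScreeningEvent(
        cycle=cycle,
        age=age if age is not None else float("nan"),
        round_type=round_type,
        attendee_fraction=attendees,
        true_positive_by_stage=detected,
        false_positive_mass=false_positive,
        overdiagnosed_mass=overdiagnosed,
        cost=cost,
        disutility=false_positive * values["disutility.false_positive"] / 4.0,
    )
    return x, event


def events_frame(events: list[ScreeningEvent]):
    """Per-round event log as a DataFrame (CSV-ready)."""
    import pandas as pd

    from .states import STAGES

    rows = []
    for ev in events:
        row = {
            "cycle": ev.cycle,
            "age": ev.age,
            "round_type": ev.round_type,
            "attendee_fraction": ev.attendee_fraction,
            "false_positive_mass": ev.false_positive_mass,
            "overdiagnosed_mass": ev.overdiagnosed_mass,
            "cost": ev.cost,
        }
        for stage, mass in zip(STAGES, ev.true_positive_by_stage):
            row[f"detected_{stage}"] = mass
        rows.append(row)
    return pd.DataFrame(rows)
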