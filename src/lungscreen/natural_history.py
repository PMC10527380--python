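"""Per-cycle transition dynamics of the unscreened disease process.

Builds the 12x12 row-stochastic transition matrix for each model cycle.
Disease onset moves disease-free occupants into preclinical stage I at the
general-population incidence for the current age band multiplied by the
smoking-stratum relative risk, converted to a 3-month probability.
Preclinical occupants progress between stages, present clinically (moving
to the diagnosed state of the same stage), or die; diagnosed occupants face
a constant stage-specific per-cycle fatality.

Competing-risk composition: within a cycle, other-cause death is applied
first at the life-table per-cycle rate, then the surviving mass is allocated
across the tabulated disease-specific exits; "stay" is the residual.
Preclinical lung-cancer death rates come from a disease model already net of
background mortality at that grain, so they are treated as
cancer-attributable and are not double-counted with the life table.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    CYCLES_PER_YEAR,
    ENTRY_AGE,
    EXIT_AGE,
    INCIDENCE_BANDS,
    STRATA,
    ValidationError,
    annual_to_cycle,
)
from .states import DIAGNOSED_STATES, HealthState, N_STATES, PRECLINICAL_STATES, STAGES


class ModelInconsistencyError(RuntimeError):
    """A transition row's residual stay probability fell below zero."""


#: per-stage preclinical exits: (target state or None for death, parameter key)
_PRECLINICAL_EXITS: dict[str, list[tuple[int | None, str]]] = {
    "I": [
        (HealthState.PRE_II, "progression.I.II"),
        (HealthState.PRE_IIIA, "progression.I.IIIA"),
        (HealthState.PRE_IIIB, "progression.I.IIIB"),
        (HealthState.PRE_IV, "progression.I.IV"),
        (HealthState.DX_I, "progression.I.diagnosis"),
        (None, "progression.I.death"),
    ],
    "II": [
        (HealthState.PRE_IIIA, "progression.II.IIIA"),
        (HealthState.PRE_IIIB, "progression.II.IIIB"),
        (HealthState.PRE_IV, "progression.II.IV"),
        (HealthState.DX_II, "progression.II.diagnosis"),
        (None, "progression.II.death"),
    ],
    "IIIA": [
        (HealthState.PRE_IIIB, "progression.IIIA.IIIB"),
        (HealthState.PRE_IV, "progression.IIIA.IV"),
        (HealthState.DX_IIIA, "progression.IIIA.diagnosis"),
        (None, "progression.IIIA.death"),
    ],
    "IIIB": [
        (HealthState.PRE_IV, "progression.IIIB.IV"),
        (HealthState.DX_IIIB, "progression.IIIB.diagnosis"),
        (None, "progression.IIIB.death"),
    ],
    "IV": [
        (HealthState.DX_IV, "progression.IV.diagnosis"),
        (None, "progression.IV.death"),
    ],
}


def incidence_band(age: float) -> str:
    """5-year incidence band key for an age within the model horizon."""
    if not ENTRY_AGE <= age <= EXIT_AGE:
        raise ValidationError(f"age {age} outside the 40-85 horizon")
    return INCIDENCE_BANDS[min((int(age) - ENTRY_AGE) // 5, len(INCIDENCE_BANDS) - 1)]


def onset_probability(
    age: float,
    stratum: str,
    values: dict[str, float],
    cycles_per_year: int = CYCLES_PER_YEAR,
    incidence_multiplier: float = 1.0,
) -> float:
    """Per-cycle probability of developing preclinical stage I cancer.

    Annual band incidence x stratum relative risk (x optional regional
    multiplier), converted to the cycle grain and capped at 1.
    """
    if stratum not in STRATA:
        raise ValidationError(f"unknown stratum: {stratum}")
    annual = (
        values[f"incidence.{incidence_band(age)}"]
        * values[f"relative_risk.{stratum}"]
        * incidence_multiplier
    )
    return annual_to_cycle(min(annual, 1.0), cycles_per_year)


def fatality_from_survival(
    two_year_survival: float, cycles: int = 2 * CYCLES_PER_YEAR
) -> float:
    """Per-cycle death probability implied by a two-year survival fraction."""
    if not 0.0 < two_year_survival <= 1.0:
        raise ValidationError(f"survival must lie in (0, 1]: {two_year_survival}")
    return 1.0 - two_year_survival ** (1.0 / cycles)


def _assemble_matrices(
    onset_c: np.ndarray, q_c: np.ndarray, values, clamp_exits: bool = False
) -> np.ndarray:
    """Stack per-cycle matrices given per-cycle onset and other-cause death.

    With ``clamp_exits`` a preclinical row whose disease-specific exit
    probabilities sum past 1 (possible when sensitivity analyses push
    several exits toward their upper bounds at once) is projected back onto
    the simplex by scaling that row's exits to sum to 1; otherwise such a
    row raises :class:`ModelInconsistencyError`.
    """
    n = len(q_c)
    mats = np.zeros((n, N_STATES, N_STATES))
    survive = 1.0 - q_c

    mats[:, HealthState.DEATH, HealthState.DEATH] = 1.0

    mats[:, HealthState.NO_LC, HealthState.PRE_I] = survive * onset_c
    mats[:, HealthState.NO_LC, HealthState.DEATH] = q_c

    for stage, pre_state in zip(STAGES, PRECLINICAL_STATES):
        exits = {key: values[key] for _, key in _PRECLINICAL_EXITS[stage]}
        total = sum(exits.values())
        scale = 1.0 / total if (clamp_exits and total > 1.0) else 1.0
        death = q_c.copy()
        for target, key in _PRECLINICAL_EXITS[stage]:
            p = exits[key] * scale
            if target is None:
                death = death + survive * p
            else:
                mats[:, pre_state, target] = survive * p
        mats[:, pre_state, HealthState.DEATH] = death

    for stage, dx_state in zip(STAGES, DIAGNOSED_STATES):
        mats[:, dx_state, HealthState.DEATH] = (
            q_c + survive * values[f"fatality.{stage}"]
        )

    # residual "stay" on the diagonal
    off_diag = mats.sum(axis=2)
    stay = 1.0 - off_diag
    bad = stay < -1e-12
    if np.any(bad):
        t, row = np.argwhere(bad)[0]
        raise ModelInconsistencyError(
            f"negative stay probability in row {HealthState(row).name} "
            f"at cycle {int(t)}"
        )
    idx = np.arange(N_STATES)
    mats[:, idx, idx] += np.maximum(stay, 0.0)
    # Death's diagonal already holds 1; the residual added there is 0.
    return mats


def build_matrix(
    age: float,
    stratum: str,
    values: dict[str, float],
    annual_other_cause_q: float,
    incidence_multiplier: float = 1.0,
) -> np.ndarray:
    """Single-age 12x12 transition matrix (handy for audit dumps)."""
    q_c = np.array([annual_to_cycle(annual_other_cause_q)])
    onset = np.array(
        [onset_probability(age, stratum, values, incidence_multiplier=incidence_multiplier)]
    )
    return _assemble_matrices(onset, q_c, values)[0]


def build_matrices(
    values: dict[str, float],
    annual_q_by_age: np.ndarray,
    stratum: str,
    n_cycles: int,
    incidence_multipliers: np.ndarray | None = None,
    clamp_exits: bool = False,
) -> np.ndarray:
    """Transition matrices for every cycle of the horizon.

    ``annual_q_by_age`` is the sex-weighted annual other-cause death
    probability indexed from age 40; ``incidence_multipliers`` optionally
    scales each 5-year incidence band (regional scenarios).
    """
    ages = ENTRY_AGE + np.arange(n_cycles) // CYCLES_PER_YEAR
    q_annual = annual_q_by_age[ages - ENTRY_AGE]
    q_c = 1.0 - (1.0 - q_annual) ** (1.0 / CYCLES_PER_YEAR)

    band_idx = np.minimum((ages - ENTRY_AGE) // 5, len(INCIDENCE_BANDS) - 1)
    incidence = np.array([values[f"incidence.{b}"] for b in INCIDENCE_BANDS])
    mult = (
        np.ones(len(INCIDENCE_BANDS))
        if incidence_multipliers is None
        else np.asarray(incidence_multipliers, dtype=float)
    )
    annual_onset = np.minimum(
        incidence[band_idx] * mult[band_idx] * values[f"relative_risk.{stratum}"], 1.0
    )
    onset_c = 1.0 - (1.0 - annual_onset) ** (1.0 / CYCLES_PER_YEAR)
    return _assemble_matrices(onset_c, q_c, values, clamp_exits=clamp_exits)


def matrix_frame(matrix: np.ndarray):
    """States x states DataFrame view of one transition matrix."""
    import pandas as pd

    from .states import STATE_LABELS

    return pd.DataFrame(matrix, index=STATE_LABELS, columns=STATE_LABELS)
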