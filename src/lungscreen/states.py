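"""Health-state space of the screening Markov model.

The cohort moves through a 12-state space: disease-free ("no lung cancer"),
five preclinical (asymptomatic, undiagnosed) stages I/II/IIIA/IIIB/IV, five
post-diagnosis states of the same stages, and an absorbing death state.
Preclinical occupants can progress, present clinically, be screen-detected,
or die; diagnosed occupants accrue stage-specific treatment cost and utility
until death. Stage is frozen at diagnosis.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    """Markov states, in occupancy-vector order."""

    NO_LC = 0
    PRE_I = 1
    PRE_II = 2
    PRE_IIIA = 3
    PRE_IIIB = 4
    PRE_IV = 5
    DX_I = 6
    DX_II = 7
    DX_IIIA = 8
    DX_IIIB = 9
    DX_IV = 10
    DEATH = 11


N_STATES = 12

STAGES = ("I", "II", "IIIA", "IIIB", "IV")

#: stage index -> preclinical / diagnosed state index
PRECLINICAL_STATES = tuple(HealthState.PRE_I + i for i in range(5))
DIAGNOSED_STATES = tuple(HealthState.DX_I + i for i in range(5))

#: stage -> utility/cost grain key (IIIA and IIIB share the stage-III figures)
STAGE_GROUP = {"I": "I", "II": "II", "IIIA": "III", "IIIB": "III", "IV": "IV"}

STATE_LABELS = tuple(s.name for s in HealthState)
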