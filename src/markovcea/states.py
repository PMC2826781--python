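"""Health states of the cohort model.

Four mutually exclusive states; ``DEAD`` is absorbing.  The integer values
double as row/column indices into transition matrices and occupancy vectors.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    """Markov health state; values index matrix rows/columns."""

    NO_RECURRENCE = 0
    LOCOREGIONAL = 1
    DISTANT = 2
    DEAD = 3

    @property
    def key(self) -> str:
        return self.name.lower()


#: states a patient can occupy while alive
ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.NO_RECURRENCE,
    HealthState.LOCOREGIONAL,
    HealthState.DISTANT,
)

#: number of states
N_STATES: int = len(HealthState)

#: lower-case config keys -> states (Dead never carries parameters)
STATE_KEYS: dict[str, HealthState] = {s.key: s for s in ALIVE_STATES}

STATE_LABELS: dict[HealthState, str] = {
    HealthState.NO_RECURRENCE: "No Recurrence",
    HealthState.LOCOREGIONAL: "Locoregional Recurrence",
    HealthState.DISTANT: "Distant Recurrence",
    HealthState.DEAD: "Dead",
}
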