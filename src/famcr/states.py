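"""State and event spaces for the family-unit multievent model.

The model tracks a mother together with her dependent offspring as one
statistical unit. Twelve demographic states ``S`` describe the unit from
one spring to the next; two intermediary spaces ``S'`` (13 states, after
independent and dependent survival) and ``S''`` (16 states, after the
breeding decision) decompose the annual transition into interpretable
steps. Twelve observation classes / field events code what is seen at a
capture; event 0 on disk means "not observed" and maps to the last
internal column (index 12 in 1-based terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Demographic states S at each spring.
STATES_S: tuple[str, ...] = (
    "J2", "J3", "SA4", "SA5",
    "A01", "A02", "A11", "A12",
    "AS1", "AS2", "A", "D",
)

#: Intermediary states S' after the survival processes.
STATES_SPRIME: tuple[str, ...] = (
    "J3", "SA4", "SA5", "A11", "A12", "AS1", "AS2",
    "A0-", "A1-", "I/AS1", "I/AS2", "A", "D",
)

#: Intermediary states S'' after the breeding decision.
STATES_SDPRIME: tuple[str, ...] = (
    "J3", "SA4", "SA5", "A11", "A12", "AS1", "AS2",
    "B/A0-", "NB/A0-", "B/A1-", "NB/A1-",
    "B/AS", "NB/AS", "B/A", "NB/A", "D",
)

#: Observation classes at the time of capture (class 12 = not captured).
OBS_CLASSES: tuple[str, ...] = tuple(str(k) for k in range(1, 13))

#: Field event codes as stored in data files; 0 denotes nonobservation.
EVENT_CODES: tuple[int, ...] = tuple(range(0, 12))

N_STATES = len(STATES_S)
N_SPRIME = len(STATES_SPRIME)
N_SDPRIME = len(STATES_SDPRIME)
N_OBS = len(OBS_CLASSES)

#: Number of alive states in S (all but the dead state D).
N_ALIVE = N_STATES - 1


def event_to_index(event: int) -> int:
    """Map an on-disk event code (0-11) to a 0-based internal column.

    Events 1..11 occupy columns 0..10; event 0 (nonobservation) maps to
    column 11, i.e. the 12th class of the observation matrices.
    """
    if not 0 <= event <= 11:
        raise ValueError(f"event code must be in 0..11, got {event}")
    return 11 if event == 0 else event - 1


def index_to_event(index: int) -> int:
    """Inverse of :func:`event_to_index`."""
    if not 0 <= index <= 11:
        raise ValueError(f"event index must be in 0..11, got {index}")
    return 0 if index == 11 else index + 1


@dataclass(frozen=True)
class StateSpace:
    """Labelled state/event sets with label -> index maps."""

    states_S: tuple[str, ...] = STATES_S
    states_Sprime: tuple[str, ...] = STATES_SPRIME
    states_Sdprime: tuple[str, ...] = STATES_SDPRIME
    obs_classes: tuple[str, ...] = OBS_CLASSES
    events: tuple[int, ...] = EVENT_CODES
    idx_S: dict = field(init=False, repr=False)
    idx_Sprime: dict = field(init=False, repr=False)
    idx_Sdprime: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "idx_S",
                           {s: i for i, s in enumerate(self.states_S)})
        object.__setattr__(self, "idx_Sprime",
                           {s: i for i, s in enumerate(self.states_Sprime)})
        object.__setattr__(self, "idx_Sdprime",
                           {s: i for i, s in enumerate(self.states_Sdprime)})


#: Module-level singleton; the spaces are fixed for this life cycle.
SPACE = StateSpace()

# Frequently used state indices.
J2, J3, SA4, SA5, A01, A02, A11, A12, AS1, AS2, A, D = range(N_STATES)
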