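"""Gait-semantic extraction and the gait pair mechanism (GPM).

A per-frame gait-state stream over {S, L, D, R, T} is sliced into 7
transition events ("gait semantics"), each localized at the frame index i
of the later state in the defining transition:

* ``L_down``   — D at i, L at i-1 (left heel strike)
* ``R_down``   — D at i, R at i-1 (right heel strike)
* ``L_up``     — L at i, D at i-1 (left toe off)
* ``R_up``     — R at i, D at i-1 (right toe off)
* ``Turn_start`` — T at i, non-T at i-1
* ``Turn_end``   — non-T at i, T at i-1
* ``Gait_start`` — non-S at i, S at i-1

Foot events then pass the gait pair mechanism: events inside turnaround
intervals are discarded, the first and last remaining foot events are
dropped (gait is unstable at the ends of the capture), and the rest are
scanned left to right into consecutive chains of 4.  A chain is a valid
gait cycle only if every adjacent pair obeys the legal cyclic order
L_up -> L_down -> R_up -> R_down -> L_up (any starting point).  Chains
violating this order, and incomplete trailing chains, are kept in the
dictionary with availability No so that adjacency between surviving cycles
remains explicit; parameters requiring neighboring cycles use only pairs of
available entries with consecutive keys.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .skeleton_io import FrameLabel

__all__ = [
    "EventType",
    "GaitSemanticEvent",
    "TurnInterval",
    "CycleEntry",
    "GaitCycleDictionary",
    "FOOT_EVENTS",
    "extract_semantics",
    "turn_intervals",
    "legal_successor",
    "chain_available",
    "build_cycle_dictionary",
    "adjacent_available_pairs",
]


class EventType(enum.Enum):
    GAIT_START = "Gait_start"
    L_UP = "L_up"
    L_DOWN = "L_down"
    R_UP = "R_up"
    R_DOWN = "R_down"
    TURN_START = "Turn_start"
    TURN_END = "Turn_end"


#: The four foot events participating in gait cycles.
FOOT_EVENTS = frozenset(
    {EventType.L_UP, EventType.L_DOWN, EventType.R_UP, EventType.R_DOWN}
)

#: Legal successor in the cyclic order of a physical gait.
_NEXT_IN_CYCLE = {
    EventType.L_UP: EventType.L_DOWN,
    EventType.L_DOWN: EventType.R_UP,
    EventType.R_UP: EventType.R_DOWN,
    EventType.R_DOWN: EventType.L_UP,
}


@dataclass(frozen=True, order=True)
class GaitSemanticEvent:
    """A localized state transition: event type at a frame index (>= 1)."""

    frame: int
    type: EventType = field(compare=False)

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError("a transition event needs a predecessor frame")


@dataclass(frozen=True)
class TurnInterval:
    """Half-open frame interval [start, end) covering one turnaround."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty turn interval [{self.start}, {self.end})")

    def __contains__(self, frame: int) -> bool:
        return self.start <= frame < self.end


@dataclass
class CycleEntry:
    """One dictionary entry: an integer key, <= 4 chained foot events, flag."""

    key: int
    events: tuple[GaitSemanticEvent, ...]
    available: bool

    def event_of_type(self, etype: EventType) -> GaitSemanticEvent | None:
        for e in self.events:
            if e.type is etype:
                return e
        return None


@dataclass
class GaitCycleDictionary:
    """Ordered registry of cycle chains, keyed 0, 1, 2, ... without gaps."""

    entries: list[CycleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries):
            if e.key != i:
                raise ValueError("cycle dictionary keys must be 0..n-1 without gaps")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def available_entries(self) -> list[CycleEntry]:
        return [e for e in self.entries if e.available]


def extract_semantics(labels: Sequence[FrameLabel]) -> list[GaitSemanticEvent]:
    """Slice a label stream into ordered gait-semantic events.

    For every i >= 1 all transition rules are evaluated on
    (state[i-1], state[i]); events are emitted in frame order.
    """
    if len(labels) == 0:
        raise ValueError("label stream is empty")
    S, L, D, R, T = (FrameLabel.S, FrameLabel.L, FrameLabel.D, FrameLabel.R, FrameLabel.T)
    events: list[GaitSemanticEvent] = []
    for i in range(1, len(labels)):
        prev, cur = labels[i - 1], labels[i]
        if cur is D and prev is L:
            events.append(GaitSemanticEvent(i, EventType.L_DOWN))
        if cur is D and prev is R:
            events.append(GaitSemanticEvent(i, EventType.R_DOWN))
        if cur is L and prev is D:
            events.append(GaitSemanticEvent(i, EventType.L_UP))
        if cur is R and prev is D:
            events.append(GaitSemanticEvent(i, EventType.R_UP))
        if cur is T and prev is not T:
            events.append(GaitSemanticEvent(i, EventType.TURN_START))
        if cur is not T and prev is T:
            events.append(GaitSemanticEvent(i, EventType.TURN_END))
        if cur is not S and prev is S:
            events.append(GaitSemanticEvent(i, EventType.GAIT_START))
    return events


def turn_intervals(
    events: Iterable[GaitSemanticEvent], sequence_length: int | None = None
) -> list[TurnInterval]:
    """Pair Turn_start/Turn_end events into half-open intervals.

    An unmatched trailing Turn_start closes at ``sequence_length`` (or one
    past the last event frame when no length is given).
    """
    events = sorted(events)
    intervals: list[TurnInterval] = []
    open_start: int | None = None
    for e in events:
        if e.type is EventType.TURN_START:
            if open_start is not None:
                raise ValueError(f"nested Turn_start at frame {e.frame}")
            open_start = e.frame
        elif e.type is EventType.TURN_END:
            if open_start is None:
                raise ValueError(f"Turn_end at frame {e.frame} without a Turn_start")
            intervals.append(TurnInterval(open_start, e.frame))
            open_start = None
    if open_start is not None:
        end = sequence_length if sequence_length is not None else (
            max(e.frame for e in events) + 1
        )
        intervals.append(TurnInterval(open_start, max(end, open_start + 1)))
    return intervals


def legal_successor(a: EventType, b: EventType) -> bool:
    """True iff b may directly follow a in a physically valid gait."""
    if a not in FOOT_EVENTS or b not in FOOT_EVENTS:
        raise ValueError(f"legal_successor is defined on foot events, got ({a}, {b})")
    return _NEXT_IN_CYCLE[a] is b


def chain_available(types: Sequence[EventType]) -> bool:
    """Availability of a candidate chain: exactly 4 foot events in legal order."""
    return len(types) == 4 and all(
        legal_successor(a, b) for a, b in zip(types, types[1:])
    )


def _chain_is_legal(chain: Sequence[GaitSemanticEvent]) -> bool:
    return chain_available([e.type for e in chain])


def _first_illegal_index(chain: Sequence[GaitSemanticEvent]) -> int | None:
    for i, (a, b) in enumerate(zip(chain, chain[1:])):
        if not legal_successor(a.type, b.type):
            return i + 1  # index of the offending event
    return None


def build_cycle_dictionary(
    events: Iterable[GaitSemanticEvent],
    turns: Sequence[TurnInterval] = (),
) -> GaitCycleDictionary:
    """Run the gait pair mechanism over an event stream.

    Foot events inside any turn interval are removed; the first and last
    remaining foot events are excluded; the rest are chunked left to right
    into chains of 4.  A chain with an illegal transition is stored
    unavailable and scanning resumes at the event after the first offender,
    so at most one cycle is lost per error burst.  Short trailing chains
    are stored unavailable.
    """
    foot = sorted(e for e in events if e.type in FOOT_EVENTS)
    foot = [e for e in foot if not any(e.frame in iv for iv in turns)]
    foot = foot[1:-1] if len(foot) > 2 else []

    entries: list[CycleEntry] = []
    i = 0
    while i < len(foot):
        chain = tuple(foot[i : i + 4])
        if _chain_is_legal(chain):
            entries.append(CycleEntry(len(entries), chain, available=True))
            i += 4
        else:
            bad = _first_illegal_index(chain)
            entries.append(CycleEntry(len(entries), chain, available=False))
            # resume after the offending event; short trailing chains end the scan
            i += bad if bad is not None else len(chain)
    return GaitCycleDictionary(entries=entries)


def adjacent_available_pairs(
    dictionary: GaitCycleDictionary,
) -> list[tuple[CycleEntry, CycleEntry]]:
    """Pairs of available entries with consecutive keys (i, i+1)."""
    e = dictionary.entries
    return [
        (a, b)
        for a, b in zip(e, e[1:])
        if a.available and b.available
    ]
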