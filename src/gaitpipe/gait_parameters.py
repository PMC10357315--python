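"""Spatiotemporal gait parameters from validated gait cycles.

Eighteen standard parameters are computed from the foot events retained by
the gait pair mechanism, then averaged over cycles:

* ``Speed`` — mean pelvis speed over straight-travel intervals (m/s).
* ``LeftStride`` / ``RightStride`` — Euclidean distance between the ankle
  positions at two successive same-foot landings, from adjacent available
  cycles (m).
* ``LeftStrideSpeed`` / ``RightStrideSpeed`` — stride / cycle time (m/s).
* ``LeftCycle`` / ``RightCycle`` — time between successive same-foot
  landings (s); ``LeftCadence`` / ``RightCadence`` = 120 / cycle time
  (steps/min; a cycle contains two steps).
* ``LeftStep`` / ``RightStep`` — distance between a foot's landing and the
  immediately preceding landing of the opposite foot (m).
* ``LeftSwing`` / ``RightSwing`` — swing time (toe-off to heel strike) as a
  percentage of the stride period; ``LeftStance`` / ``RightStance`` are the
  complements to 100.
* ``DoubleSupport`` — 100 − LeftSwing − RightSwing (the two double-support
  bouts per stride, %).
* ``LeftSwingSpeed`` / ``RightSwingSpeed`` — straight-line ankle
  displacement from toe-off to heel strike divided by swing time (m/s).

Cycle-time quantities come from pairs of available cycle-dictionary entries
with consecutive keys; per-pair and per-landing records are returned
alongside the means so that no averaging step is opaque.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from .semantics_gpm import (
    CycleEntry,
    EventType,
    GaitCycleDictionary,
    GaitSemanticEvent,
    TurnInterval,
    adjacent_available_pairs,
)
from .skeleton_io import FrameLabel, GaitSequence, JointName

__all__ = [
    "GaitParameters",
    "CycleMeasurements",
    "PARAMETER_NAMES",
    "event_time",
    "ankle_position",
    "stride_block",
    "step_block",
    "phase_block",
    "walking_speed",
    "compute_parameters",
]

log = logging.getLogger(__name__)

#: Canonical parameter order and report names.
PARAMETER_NAMES: tuple[str, ...] = (
    "Speed",
    "LeftStride",
    "RightStride",
    "LeftStrideSpeed",
    "RightStrideSpeed",
    "LeftStep",
    "RightStep",
    "LeftCadence",
    "RightCadence",
    "LeftCycle",
    "RightCycle",
    "LeftSwing",
    "RightSwing",
    "LeftStance",
    "RightStance",
    "DoubleSupport",
    "LeftSwingSpeed",
    "RightSwingSpeed",
)

_FIELD_FOR_NAME = {
    "Speed": "speed",
    "LeftStride": "left_stride",
    "RightStride": "right_stride",
    "LeftStrideSpeed": "left_stride_speed",
    "RightStrideSpeed": "right_stride_speed",
    "LeftStep": "left_step",
    "RightStep": "right_step",
    "LeftCadence": "left_cadence",
    "RightCadence": "right_cadence",
    "LeftCycle": "left_cycle",
    "RightCycle": "right_cycle",
    "LeftSwing": "left_swing",
    "RightSwing": "right_swing",
    "LeftStance": "left_stance",
    "RightStance": "right_stance",
    "DoubleSupport": "double_support",
    "LeftSwingSpeed": "left_swing_speed",
    "RightSwingSpeed": "right_swing_speed",
}


@dataclass
class GaitParameters:
    """The 18 gait parameters (units in the module docstring)."""

    speed: float
    left_stride: float
    right_stride: float
    left_stride_speed: float
    right_stride_speed: float
    left_step: float
    right_step: float
    left_cadence: float
    right_cadence: float
    left_cycle: float
    right_cycle: float
    left_swing: float
    right_swing: float
    left_stance: float
    right_stance: float
    double_support: float
    left_swing_speed: float
    right_swing_speed: float

    def as_dict(self) -> dict[str, float]:
        """Values keyed by the canonical report names."""
        return {name: getattr(self, _FIELD_FOR_NAME[name]) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "GaitParameters":
        return cls(**{_FIELD_FOR_NAME[k]: float(v) for k, v in values.items()})

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} is not finite: {v}")
        if abs(self.left_swing + self.left_stance - 100.0) > 1e-9:
            raise ValueError("left swing + stance must equal 100")
        if abs(self.right_swing + self.right_stance - 100.0) > 1e-9:
            raise ValueError("right swing + stance must equal 100")
        if not 0.0 <= self.double_support <= 100.0:
            raise ValueError(f"double support out of [0, 100]: {self.double_support}")


@dataclass
class CycleMeasurements:
    """Per-cycle / per-landing raw records behind each averaged parameter.

    Each record maps a parameter name to its value for one qualifying
    cycle pair or landing, with the dictionary keys it traces to.
    """

    records: list[dict[str, object]] = field(default_factory=list)

    def values_for(self, name: str) -> np.ndarray:
        return np.array(
            [r[name] for r in self.records if name in r], dtype=float
        )

    def add(self, keys: tuple[int, ...], **values: float) -> None:
        self.records.append({"keys": keys, **values})


_ANKLE_FOR_EVENT = {
    EventType.L_UP: JointName.ANKLE_LEFT,
    EventType.L_DOWN: JointName.ANKLE_LEFT,
    EventType.R_UP: JointName.ANKLE_RIGHT,
    EventType.R_DOWN: JointName.ANKLE_RIGHT,
}


def event_time(seq: GaitSequence, e: GaitSemanticEvent) -> float:
    """Timestamp of the frame at which the event is localized."""
    if not 0 <= e.frame < len(seq):
        raise IndexError(f"event frame {e.frame} outside sequence of {len(seq)} frames")
    return seq.frames[e.frame].time


def ankle_position(seq: GaitSequence, e: GaitSemanticEvent) -> np.ndarray:
    """Position of the event's foot's ankle at the event frame."""
    if e.type not in _ANKLE_FOR_EVENT:
        raise ValueError(f"{e.type} has no associated foot")
    if not 0 <= e.frame < len(seq):
        raise IndexError(f"event frame {e.frame} outside sequence of {len(seq)} frames")
    return np.asarray(seq.frames[e.frame].positions[_ANKLE_FOR_EVENT[e.type]])


def _pair_events(pair: tuple[CycleEntry, CycleEntry]) -> list[GaitSemanticEvent]:
    return sorted(pair[0].events + pair[1].events)


def stride_block(
    seq: GaitSequence,
    pair: tuple[CycleEntry, CycleEntry],
    side: str,
) -> dict[str, float] | None:
    """Stride length, cycle time, stride speed and cadence for one pair.

    ``side`` is "left" or "right".  Returns None (with a log notice) when a
    required landing is missing or the cycle time is nonpositive.
    """
    down = EventType.L_DOWN if side == "left" else EventType.R_DOWN
    d0 = pair[0].event_of_type(down)
    d1 = pair[1].event_of_type(down)
    if d0 is None or d1 is None:
        log.info("skipping %s stride for keys %s: missing landing", side, (pair[0].key, pair[1].key))
        return None
    cycle = event_time(seq, d1) - event_time(seq, d0)
    if cycle <= 0:
        log.info("skipping %s stride for keys %s: nonpositive cycle time", side, (pair[0].key, pair[1].key))
        return None
    stride = float(np.linalg.norm(ankle_position(seq, d1) - ankle_position(seq, d0)))
    return {
        f"{side}_stride": stride,
        f"{side}_cycle": cycle,
        f"{side}_stride_speed": stride / cycle,
        f"{side}_cadence": 120.0 / cycle,
    }


def phase_block(
    seq: GaitSequence,
    pair: tuple[CycleEntry, CycleEntry],
) -> dict[str, float] | None:
    """Swing/stance/double-support percentages and swing speeds for one pair.

    The stride period of each side is the time between its two landings in
    the pair; the swing bounding that period's start is the last same-foot
    toe-off before the second landing.
    """
    events = _pair_events(pair)
    out: dict[str, float] = {}
    for side, up_t, down_t in (
        ("left", EventType.L_UP, EventType.L_DOWN),
        ("right", EventType.R_UP, EventType.R_DOWN),
    ):
        downs = [e for e in events if e.type is down_t]
        if len(downs) != 2:
            log.info("skipping phases for keys %s: need 2 %s landings", (pair[0].key, pair[1].key), side)
            return None
        cycle = event_time(seq, downs[1]) - event_time(seq, downs[0])
        ups = [e for e in events if e.type is up_t and e.frame < downs[1].frame]
        if not ups or cycle <= 0:
            log.info("skipping phases for keys %s: no %s toe-off / bad cycle", (pair[0].key, pair[1].key), side)
            return None
        up = ups[-1]
        swing_time = event_time(seq, downs[1]) - event_time(seq, up)
        if swing_time <= 0:
            log.info("skipping phases for keys %s: nonpositive %s swing", (pair[0].key, pair[1].key), side)
            return None
        chord = float(np.linalg.norm(ankle_position(seq, downs[1]) - ankle_position(seq, up)))
        swing_pct = 100.0 * swing_time / cycle
        out[f"{side}_swing"] = swing_pct
        out[f"{side}_stance"] = 100.0 - swing_pct
        out[f"{side}_swing_speed"] = chord / swing_time
    out["double_support"] = 100.0 - out["left_swing"] - out["right_swing"]
    return out


def _available_runs(dictionary: GaitCycleDictionary) -> list[list[CycleEntry]]:
    """Maximal runs of consecutive-key available entries."""
    runs: list[list[CycleEntry]] = []
    cur: list[CycleEntry] = []
    for e in dictionary.entries:
        if e.available:
            cur.append(e)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def step_block(
    seq: GaitSequence,
    dictionary: GaitCycleDictionary,
) -> list[dict[str, float]]:
    """Step lengths for every qualifying landing.

    A left step is the distance between a left-foot landing and the last
    right-foot landing before it; only landings within one run of
    consecutive available cycles qualify, so steps never straddle a
    turnaround or a discarded cycle.
    """
    records: list[dict[str, float]] = []
    for run in _available_runs(dictionary):
        events = sorted(e for entry in run for e in entry.events)
        for i, e in enumerate(events):
            if e.type not in (EventType.L_DOWN, EventType.R_DOWN):
                continue
            opposite = EventType.R_DOWN if e.type is EventType.L_DOWN else EventType.L_DOWN
            prev = [p for p in events[:i] if p.type is opposite]
            if not prev:
                continue
            dist = float(np.linalg.norm(ankle_position(seq, e) - ankle_position(seq, prev[-1])))
            name = "left_step" if e.type is EventType.L_DOWN else "right_step"
            records.append({name: dist, "keys": tuple(en.key for en in run)})
    return records


def _straight_intervals_from_labels(labels: Sequence[FrameLabel]) -> list[tuple[int, int]]:
    """Maximal half-open frame runs whose labels are outside {S, T}."""
    intervals: list[tuple[int, int]] = []
    start: int | None = None
    for i, lab in enumerate(labels):
        walking = lab not in (FrameLabel.S, FrameLabel.T)
        if walking and start is None:
            start = i
        elif not walking and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(labels)))
    return intervals


def _straight_intervals_from_events(
    events: Sequence[GaitSemanticEvent],
    turns: Sequence[TurnInterval],
    n_frames: int,
) -> list[tuple[int, int]]:
    """Straight intervals bounded by turn intervals and the foot-event span."""
    foot = sorted(e.frame for e in events if e.type in _ANKLE_FOR_EVENT)
    if not foot:
        return []
    lo, hi = foot[0], foot[-1] + 1
    cuts = sorted((iv.start, iv.end) for iv in turns)
    intervals = []
    cur = lo
    for s, e in cuts:
        if s > cur:
            intervals.append((cur, min(s, hi)))
        cur = max(cur, e)
    if cur < hi:
        intervals.append((cur, hi))
    return [(s, e) for s, e in intervals if e - s >= 2]


def walking_speed(
    seq: GaitSequence,
    events: Sequence[GaitSemanticEvent],
    turns: Sequence[TurnInterval] = (),
    labels: Sequence[FrameLabel] | None = None,
) -> float:
    """Mean straight-travel speed: pelvis displacement over duration per pass.

    Straight intervals come from the label stream when one is supplied
    (maximal runs outside standstill and turnaround); otherwise they are
    bounded by the supplied turn intervals and the span of foot events.
    """
    if labels is not None:
        intervals = _straight_intervals_from_labels(labels)
    else:
        intervals = _straight_intervals_from_events(events, turns, len(seq))
    intervals = [(s, e) for s, e in intervals if e - s >= 2]
    if not intervals:
        raise ValueError("no straight interval to measure walking speed on")
    pelvis = seq.joint_positions(JointName.PELVIS)
    t = seq.times_array()
    speeds = []
    for s, e in intervals:
        dt = t[e - 1] - t[s]
        if dt <= 0:
            continue
        speeds.append(float(np.linalg.norm(pelvis[e - 1] - pelvis[s])) / dt)
    if not speeds:
        raise ValueError("straight intervals have zero duration")
    return float(np.mean(speeds))


def compute_parameters(
    seq: GaitSequence,
    dictionary: GaitCycleDictionary,
    events: Sequence[GaitSemanticEvent],
    turns: Sequence[TurnInterval] = (),
    labels: Sequence[FrameLabel] | None = None,
) -> tuple[GaitParameters, CycleMeasurements]:
    """All 18 parameters, averaged over qualifying cycles, plus raw records.

    Swing and stance percentages are averaged as swing means; stance is
    reported as the exact complement so swing + stance = 100 holds
    identically in the output.
    """
    pairs = adjacent_available_pairs(dictionary)
    if not dictionary.available_entries:
        raise ValueError("no available gait cycles")

    meas = CycleMeasurements()
    for a, b in pairs:
        keys = (a.key, b.key)
        for side in ("left", "right"):
            rec = stride_block(seq, (a, b), side)
            if rec:
                meas.add(keys, **rec)
        rec = phase_block(seq, (a, b))
        if rec:
            meas.add(keys, **rec)
    for r in step_block(seq, dictionary):
        meas.records.append(r)

    def mean_of(name: str) -> float:
        v = meas.values_for(name)
        if v.size == 0:
            raise ValueError(f"no cycle records for parameter {name}")
        return float(v.mean())

    left_swing = mean_of("left_swing")
    right_swing = mean_of("right_swing")
    params = GaitParameters(
        speed=walking_speed(seq, events, turns, labels),
        left_stride=mean_of("left_stride"),
        right_stride=mean_of("right_stride"),
        left_stride_speed=mean_of("left_stride_speed"),
        right_stride_speed=mean_of("right_stride_speed"),
        left_step=mean_of("left_step"),
        right_step=mean_of("right_step"),
        left_cadence=mean_of("left_cadence"),
        right_cadence=mean_of("right_cadence"),
        left_cycle=mean_of("left_cycle"),
        right_cycle=mean_of("right_cycle"),
        left_swing=left_swing,
        right_swing=right_swing,
        left_stance=100.0 - left_swing,
        right_stance=100.0 - right_swing,
        double_support=mean_of("double_support"),
        left_swing_speed=mean_of("left_swing_speed"),
        right_swing_speed=mean_of("right_swing_speed"),
    )
    params.validate()
    return params, meas
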