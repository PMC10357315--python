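"""Ankle-speed heuristic event detector (the comparison method).

The classical contactless approach: smooth each ankle's 3-D speed
magnitude, threshold it at a fraction of the per-segment peak, and read
heel strikes (foot-down) off downward threshold crossings and toe-offs
(foot-up) off upward crossings.  The events then feed the same cycle
validation and parameter stages as the classifier-based pipeline.  Turn
detection is not attempted; turnaround intervals may be supplied
externally (e.g., from labels) so that turn data can be excluded
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .semantics_gpm import EventType, GaitSemanticEvent, TurnInterval
from .skeleton_io import GaitSequence, JointName

__all__ = ["HeuristicConfig", "heuristic_events", "ankle_speed"]


@dataclass(frozen=True)
class HeuristicConfig:
    """Threshold fraction of the per-segment peak ankle speed, and the
    moving-average smoothing window (frames)."""

    speed_threshold_fraction: float = 0.25
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.speed_threshold_fraction < 1.0:
            raise ValueError("speed_threshold_fraction must be in (0, 1)")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


def ankle_speed(seq: GaitSequence, joint: JointName, smooth_window: int = 5) -> np.ndarray:
    """Smoothed 3-D speed magnitude of one ankle, m/s per frame."""
    pos = seq.joint_positions(joint)
    t = seq.times_array()
    dt = np.diff(t)
    dt[dt <= 0] = 1.0 / seq.fps
    speed = np.empty(len(seq))
    speed[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
    speed[0] = speed[1]
    if smooth_window > 1:
        half = smooth_window // 2
        padded = np.concatenate(
            [np.full(half, speed[0]), speed, np.full(half, speed[-1])]
        )
        kernel = np.ones(smooth_window) / smooth_window
        speed = np.convolve(padded, kernel, mode="valid")[: len(seq)]
    return speed


def _crossing_events(
    speed: np.ndarray,
    segments: list[tuple[int, int]],
    fraction: float,
    up_type: EventType,
    down_type: EventType,
) -> list[GaitSemanticEvent]:
    events: list[GaitSemanticEvent] = []
    for s, e in segments:
        seg = speed[s:e]
        if len(seg) < 2:
            continue
        peak = seg.max()
        if peak <= 0:
            continue
        thr = fraction * peak
        above = seg > thr
        # the segment boundary counts as below threshold, so a swing already
        # in progress at the boundary still registers its start there
        prev = False
        for i in range(len(seg)):
            frame = s + i
            if frame >= 1:
                if above[i] and not prev:
                    events.append(GaitSemanticEvent(frame, up_type))
                elif not above[i] and prev:
                    events.append(GaitSemanticEvent(frame, down_type))
            prev = above[i]
    return events


def heuristic_events(
    seq: GaitSequence,
    cfg: HeuristicConfig = HeuristicConfig(),
    turns: list[TurnInterval] | None = None,
) -> list[GaitSemanticEvent]:
    """Foot-up/foot-down events from thresholded ankle speed.

    The threshold is ``speed_threshold_fraction`` x the peak smoothed ankle
    speed of each straight segment (the whole capture when no turn
    intervals are given).  A stationary capture yields no events.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 frames")
    turns = turns or []
    # straight segments between turn intervals
    segments: list[tuple[int, int]] = []
    cur = 0
    for iv in sorted(turns, key=lambda v: v.start):
        if iv.start > cur:
            segments.append((cur, iv.start))
        cur = max(cur, iv.end)
    if cur < n:
        segments.append((cur, n))

    events: list[GaitSemanticEvent] = []
    for joint, up_t, down_t in (
        (JointName.ANKLE_LEFT, EventType.L_UP, EventType.L_DOWN),
        (JointName.ANKLE_RIGHT, EventType.R_UP, EventType.R_DOWN),
    ):
        speed = ankle_speed(seq, joint, cfg.smooth_window)
        events.extend(
            _crossing_events(speed, segments, cfg.speed_threshold_fraction, up_t, down_t)
        )
    return sorted(events)
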