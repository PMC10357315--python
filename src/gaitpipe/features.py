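"""Per-frame spatiotemporal feature extraction.

Each frame is summarized by 32 features:

* 27 temporal features — per-axis finite-difference speed of each of the 9
  lower-body joints (m/s),
* 1 spatial feature — distance between the person and the camera, taken as
  the pelvis depth coordinate z (m),
* 4 movement features — Euclidean knee–knee distance, Euclidean pelvis→left
  foot and pelvis→right foot distances (m), and the waist-rotation angle:
  the signed angle (radians) between the left-hip→right-hip vector projected
  onto the horizontal x–z plane and the camera x-axis.

Velocities use a backward difference with the first row copied from the
second (causal, no temporal support before frame 1).  No smoothing is
applied by default; an optional centered moving average on positions can be
enabled for noisy captures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_io import AXES, JOINT_ORDER, GaitSequence, JointName

__all__ = ["FeatureMatrix", "FEATURE_NAMES", "joint_speeds", "extract_features"]


FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"speed_{j.value}_{a}" for j in JOINT_ORDER for a in AXES]
    + [
        "camera_distance",
        "knee_distance",
        "pelvis_foot_left_distance",
        "pelvis_foot_right_distance",
        "waist_rotation",
    ]
)


@dataclass
class FeatureMatrix:
    """An (n_frames, 32) feature array with fixed column names."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError(
                f"expected (n, {len(self.names)}) feature matrix, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def _smooth_positions(pos: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the frame axis, edge-padded."""
    if window <= 1:
        return pos
    half = window // 2
    padded = np.concatenate(
        [np.repeat(pos[:1], half, axis=0), pos, np.repeat(pos[-1:], half, axis=0)],
        axis=0,
    )
    kernel = np.ones(window) / window
    out = np.empty_like(pos)
    for j in range(pos.shape[1]):
        for a in range(pos.shape[2]):
            out[:, j, a] = np.convolve(padded[:, j, a], kernel, mode="valid")[: pos.shape[0]]
    return out


def joint_speeds(seq: GaitSequence, smooth_window: int = 1) -> np.ndarray:
    """Backward-difference joint velocities, (n_frames, 27) in m/s.

    Row ``f`` holds ``(p[f] - p[f-1]) / (t[f] - t[f-1])`` for ``f >= 1``;
    row 0 copies row 1.  Zero time steps fall back to the nominal 1/fps.
    """
    if len(seq) < 2:
        raise ValueError("joint speeds need at least 2 frames")
    pos = _smooth_positions(seq.positions_array(), smooth_window)
    t = seq.times_array()
    dt = np.diff(t)
    dt[dt <= 0] = 1.0 / seq.fps
    vel = np.empty_like(pos)
    vel[1:] = (pos[1:] - pos[:-1]) / dt[:, None, None]
    vel[0] = vel[1]
    return vel.reshape(len(seq), -1)


def extract_features(seq: GaitSequence, smooth_window: int = 1) -> FeatureMatrix:
    """The full 32-feature matrix for a sequence (needs >= 2 frames)."""
    speeds = joint_speeds(seq, smooth_window=smooth_window)
    pos = _smooth_positions(seq.positions_array(), smooth_window)

    def traj(j: JointName) -> np.ndarray:
        return pos[:, JOINT_ORDER.index(j)]

    pelvis = traj(JointName.PELVIS)
    camera_distance = pelvis[:, 2]
    knee_distance = np.linalg.norm(
        traj(JointName.KNEE_LEFT) - traj(JointName.KNEE_RIGHT), axis=1
    )
    pelvis_foot_l = np.linalg.norm(traj(JointName.FOOT_LEFT) - pelvis, axis=1)
    pelvis_foot_r = np.linalg.norm(traj(JointName.FOOT_RIGHT) - pelvis, axis=1)

    hip_vec = traj(JointName.HIP_RIGHT) - traj(JointName.HIP_LEFT)
    # angle of the hip line in the ground (x-z) plane, relative to camera x
    waist_rotation = np.arctan2(hip_vec[:, 2], hip_vec[:, 0])

    values = np.column_stack(
        [speeds, camera_distance, knee_distance, pelvis_foot_l, pelvis_foot_r, waist_rotation]
    )
    return FeatureMatrix(values=values)
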