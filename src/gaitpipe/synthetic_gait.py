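"""Kinematic walking simulator with per-frame ground-truth labels.

Emulates the capture protocol behind the pipeline: a participant stands
still at a start line, walks straight passes of a few meters back and
forth in front of a depth camera, and turns around between passes.  The
simulator produces the 9-joint lower-body skeleton stream at a configurable
frame rate, the true per-frame gait-state labels (S/L/D/R/T), and the
analytically known gait parameters implied by the configuration.

Gait model within a pass
------------------------
A gait cycle of duration ``cycle_time`` is laid out as

    left swing | double support | right swing | double support

with swing fractions ``swing_fraction_left`` / ``swing_fraction_right`` and
the two double-support bouts sharing the remainder equally.  During stance a
foot's ankle is pinned to the ground plane; during swing it advances by one
stride (``step_length_left + step_length_right``) along the walking axis
with a smooth half-cosine horizontal profile and a half-sine vertical lift.
The pelvis advances linearly over the pass, which makes the true walking
speed exactly ``stride / cycle_time``.  Passes start in a staggered stance
(trailing foot one opposite-step behind) so every swing covers a full
stride and the analytic per-cycle parameters hold for every cycle.

Turnarounds are modeled as an in-place 180° pelvis yaw with the feet
repositioning underneath; turn frames are labeled T and are discarded by
all downstream computations, so their kinematic fidelity is unimportant.
Standstill (S) occurs only at the very start and end of the capture.
Position noise, when enabled, is i.i.d. isotropic Gaussian per joint per
frame; labels always come from the generator's schedule, never from the
noisy positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gait_parameters import GaitParameters
from .semantics_gpm import GaitSemanticEvent, extract_semantics
from .skeleton_io import JOINT_ORDER, FrameLabel, GaitSequence, JointName

__all__ = ["GaitSimConfig", "GroundTruth", "simulate_gait", "truth_events", "simulate_cohort"]


# body geometry (meters); fixed, not exposed: only relative distances and
# speeds matter downstream
_PELVIS_HEIGHT = 0.90
_HIP_HALF = 0.12
# narrow stance: keeps the Euclidean landing-to-landing distance equal to the
# configured step length to sub-millimeter accuracy, so the analytic ground
# truth is exact; knee separation stays positive via the hip offset
_FOOT_HALF = 0.01
_ANKLE_HEIGHT = 0.08
_FOOT_FORWARD = 0.12
_FOOT_HEIGHT = 0.03
_SWING_LIFT = 0.06
_Z_START = 1.5  # start line depth from the camera


@dataclass(frozen=True)
class GaitSimConfig:
    """Simulation parameters; defaults follow the capture protocol
    (5 m walkway, 3 round trips = 6 passes, 30 Hz) with gait values chosen
    near the middle of the healthy-adult ranges."""

    n_passes: int = 6
    pass_length: float = 5.0
    cycle_time: float = 0.96
    swing_fraction_left: float = 0.31
    swing_fraction_right: float = 0.31
    step_length_left: float = 0.52
    step_length_right: float = 0.50
    turn_duration: float = 2.0
    standstill_duration: float = 1.0
    fps: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swing_fraction_left + self.swing_fraction_right >= 1.0:
            raise ValueError("swing fractions must leave room for double support")
        if min(self.swing_fraction_left, self.swing_fraction_right) <= 0:
            raise ValueError("swing fractions must be positive")
        for name in ("pass_length", "cycle_time", "step_length_left",
                     "step_length_right", "turn_duration", "standstill_duration", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_passes < 1:
            raise ValueError("need at least one pass")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.cycles_per_pass < 1:
            raise ValueError(
                f"pass_length {self.pass_length} m cannot fit one stride of "
                f"{self.stride} m"
            )

    @property
    def stride(self) -> float:
        return self.step_length_left + self.step_length_right

    @property
    def cycles_per_pass(self) -> int:
        return int(np.floor(self.pass_length / self.stride))

    def true_parameters(self) -> GaitParameters:
        """Analytic gait parameters implied by the configuration."""
        c = self.cycle_time
        fl, fr = self.swing_fraction_left, self.swing_fraction_right
        return GaitParameters(
            speed=self.stride / c,
            left_stride=self.stride,
            right_stride=self.stride,
            left_stride_speed=self.stride / c,
            right_stride_speed=self.stride / c,
            left_step=self.step_length_left,
            right_step=self.step_length_right,
            left_cadence=120.0 / c,
            right_cadence=120.0 / c,
            left_cycle=c,
            right_cycle=c,
            left_swing=100.0 * fl,
            right_swing=100.0 * fr,
            left_stance=100.0 * (1 - fl),
            right_stance=100.0 * (1 - fr),
            double_support=100.0 * (1 - fl - fr),
            left_swing_speed=self.stride / (fl * c),
            right_swing_speed=self.stride / (fr * c),
        )


@dataclass
class GroundTruth:
    """Per-frame labels, derived events, and the analytic parameters."""

    labels: list[FrameLabel]
    events: list[GaitSemanticEvent]
    parameters: GaitParameters


def truth_events(truth: GroundTruth) -> list[GaitSemanticEvent]:
    """Gait-semantic events of the ground-truth label stream."""
    return extract_semantics(truth.labels)


def _progress(v: np.ndarray | float) -> np.ndarray | float:
    """Smooth monotone 0->1 profile with zero end velocities."""
    return 0.5 * (1.0 - np.cos(np.pi * np.asarray(v)))


class _PassModel:
    """Closed-form kinematics of one straight pass."""

    def __init__(self, cfg: GaitSimConfig, z0: float, direction: float):
        self.cfg = cfg
        self.z0 = z0
        self.dir = direction
        self.n = cfg.cycles_per_pass
        self.duration = self.n * cfg.cycle_time
        fl, fr = cfg.swing_fraction_left, cfg.swing_fraction_right
        self.d_half = (1.0 - fl - fr) / 2.0
        # phase boundaries within a cycle (fractions)
        self.u_l_end = fl
        self.u_r_start = fl + self.d_half
        self.u_r_end = fl + self.d_half + fr

    def left_landing(self, c: int) -> float:
        # landing of the left foot at the end of cycle c's left swing
        if c < 0:
            return self.z0 - self.dir * self.cfg.step_length_right
        return self.z0 + self.dir * (self.cfg.step_length_left + c * self.cfg.stride)

    def right_landing(self, c: int) -> float:
        if c < 0:
            return self.z0
        return self.z0 + self.dir * (c + 1) * self.cfg.stride

    def foot_state(self, tau: float) -> tuple[float, float, float, float, FrameLabel]:
        """(z_left, lift_left, z_right, lift_right, label) at pass time tau."""
        cfg = self.cfg
        c = min(int(tau // cfg.cycle_time), self.n - 1)
        u = (tau - c * cfg.cycle_time) / cfg.cycle_time
        zl, ll = self.left_landing(c - 1), 0.0
        zr, lr = self.right_landing(c - 1), 0.0
        if u < self.u_l_end:  # left swing
            v = u / cfg.swing_fraction_left
            zl = self.left_landing(c - 1) + self.dir * cfg.stride * _progress(v)
            ll = _SWING_LIFT * np.sin(np.pi * v)
            label = FrameLabel.L
        elif u < self.u_r_start:  # first double support
            zl = self.left_landing(c)
            label = FrameLabel.D
        elif u < self.u_r_end:  # right swing
            zl = self.left_landing(c)
            v = (u - self.u_r_start) / cfg.swing_fraction_right
            zr = self.right_landing(c - 1) + self.dir * cfg.stride * _progress(v)
            lr = _SWING_LIFT * np.sin(np.pi * v)
            label = FrameLabel.R
        else:  # second double support
            zl = self.left_landing(c)
            zr = self.right_landing(c)
            label = FrameLabel.D
        return zl, ll, zr, lr, label

    @property
    def mid_start(self) -> float:
        return (self.left_landing(-1) + self.right_landing(-1)) / 2.0

    @property
    def mid_end(self) -> float:
        return (self.left_landing(self.n - 1) + self.right_landing(self.n - 1)) / 2.0

    def pelvis_z(self, tau: float) -> float:
        return self.mid_start + (self.mid_end - self.mid_start) * tau / self.duration


def _skeleton(
    pelvis_z: float,
    heading: float,
    ankle_left: np.ndarray,
    ankle_right: np.ndarray,
) -> np.ndarray:
    """Assemble the (9, 3) joint array from pelvis depth, heading and ankles."""
    fw = np.array([np.sin(heading), 0.0, np.cos(heading)])
    up = np.array([0.0, 1.0, 0.0])
    left = np.cross(up, fw)
    pelvis = np.array([0.0, _PELVIS_HEIGHT, pelvis_z])
    hip_l = pelvis + left * _HIP_HALF
    hip_r = pelvis - left * _HIP_HALF
    knee_l = (hip_l + ankle_left) / 2.0
    knee_r = (hip_r + ankle_right) / 2.0
    foot_l = ankle_left + fw * _FOOT_FORWARD
    foot_l = np.array([foot_l[0], _FOOT_HEIGHT + (ankle_left[1] - _ANKLE_HEIGHT), foot_l[2]])
    foot_r = ankle_right + fw * _FOOT_FORWARD
    foot_r = np.array([foot_r[0], _FOOT_HEIGHT + (ankle_right[1] - _ANKLE_HEIGHT), foot_r[2]])
    out = np.empty((len(JOINT_ORDER), 3))
    layout = {
        JointName.PELVIS: pelvis,
        JointName.HIP_LEFT: hip_l,
        JointName.HIP_RIGHT: hip_r,
        JointName.KNEE_LEFT: knee_l,
        JointName.KNEE_RIGHT: knee_r,
        JointName.ANKLE_LEFT: ankle_left,
        JointName.ANKLE_RIGHT: ankle_right,
        JointName.FOOT_LEFT: foot_l,
        JointName.FOOT_RIGHT: foot_r,
    }
    for k, j in enumerate(JOINT_ORDER):
        out[k] = layout[j]
    return out


def _ankles(
    model: _PassModel, tau: float, heading: float
) -> tuple[np.ndarray, np.ndarray, FrameLabel]:
    zl, ll, zr, lr, label = model.foot_state(tau)
    up = np.array([0.0, 1.0, 0.0])
    fw = np.array([np.sin(heading), 0.0, np.cos(heading)])
    left = np.cross(up, fw)
    ankle_l = np.array([0.0, _ANKLE_HEIGHT + ll, zl]) + left * _FOOT_HALF
    ankle_r = np.array([0.0, _ANKLE_HEIGHT + lr, zr]) - left * _FOOT_HALF
    return ankle_l, ankle_r, label


def simulate_gait(config: GaitSimConfig) -> tuple[GaitSequence, GroundTruth]:
    """Generate one simulated walk and its ground truth.

    The schedule is standstill, then ``n_passes`` straight passes separated
    by turnarounds, then a final standstill.  Deterministic for a fixed
    config (including seed).
    """
    cfg = config
    n_cycles = cfg.cycles_per_pass

    # build pass models with alternating direction and continuous start lines
    passes: list[_PassModel] = []
    z0, direction = _Z_START, 1.0
    for _ in range(cfg.n_passes):
        model = _PassModel(cfg, z0, direction)
        passes.append(model)
        # next pass walks back from where this one ended
        z0 = model.right_landing(n_cycles - 1)
        direction = -direction

    # absolute segment schedule: (t_start, t_end, kind, payload)
    segments: list[tuple[float, float, str, object]] = []
    t = 0.0
    segments.append((t, t + cfg.standstill_duration, "standstill", passes[0]))
    t += cfg.standstill_duration
    for p, model in enumerate(passes):
        segments.append((t, t + model.duration, "pass", model))
        t += model.duration
        if p < cfg.n_passes - 1:
            segments.append((t, t + cfg.turn_duration, "turn", (model, passes[p + 1])))
            t += cfg.turn_duration
    segments.append((t, t + cfg.standstill_duration, "standstill", passes[-1]))
    t += cfg.standstill_duration
    total = t

    n_frames = int(np.floor(total * cfg.fps))
    times = np.arange(n_frames) / cfg.fps
    positions = np.empty((n_frames, len(JOINT_ORDER), 3))
    labels: list[FrameLabel] = []

    headings = {id(m): (0.0 if m.dir > 0 else np.pi) for m in passes}

    def pass_pose(model: _PassModel, tau: float) -> tuple[np.ndarray, FrameLabel]:
        heading = headings[id(model)]
        ankle_l, ankle_r, label = _ankles(model, tau, heading)
        return _skeleton(model.pelvis_z(tau), heading, ankle_l, ankle_r), label

    for i, ti in enumerate(times):
        seg = None
        for s in segments:
            if s[0] <= ti < s[1]:
                seg = s
                break
        if seg is None:  # numeric edge at the very end
            seg = segments[-1]
        t0, t1, kind, payload = seg
        if kind == "standstill":
            model = payload
            # hold the boundary pose of the adjacent pass
            if model is passes[0] and t0 == 0.0:
                pose, _ = pass_pose(model, 0.0)
            else:
                pose, _ = pass_pose(model, model.duration - 1e-9)
            positions[i] = pose
            labels.append(FrameLabel.S)
        elif kind == "pass":
            pose, label = pass_pose(payload, ti - t0)
            positions[i] = pose
            labels.append(label)
        else:  # turn: yaw 180 degrees in place, feet sliding to the next stance
            prev_model, next_model = payload
            w = (ti - t0) / (t1 - t0)
            h0 = headings[id(prev_model)]
            h1 = headings[id(next_model)]
            # rotate the shorter way through +pi
            heading = h0 + (h1 - h0 if h1 > h0 else h1 + 2 * np.pi - h0) * w
            start_pose, _ = pass_pose(prev_model, prev_model.duration - 1e-9)
            end_pose, _ = pass_pose(next_model, 0.0)
            pose = (1 - w) * start_pose + w * end_pose
            # re-orient the hip line mid-turn so waist rotation sweeps 180°
            pelvis = pose[JOINT_ORDER.index(JointName.PELVIS)]
            fw = np.array([np.sin(heading), 0.0, np.cos(heading)])
            left = np.cross(np.array([0.0, 1.0, 0.0]), fw)
            pose[JOINT_ORDER.index(JointName.HIP_LEFT)] = pelvis + left * _HIP_HALF
            pose[JOINT_ORDER.index(JointName.HIP_RIGHT)] = pelvis - left * _HIP_HALF
            # small vertical shuffle so the feet are not perfectly static
            shuffle = 0.01 * np.sin(2 * np.pi * 2.0 * (ti - t0))
            pose[JOINT_ORDER.index(JointName.ANKLE_LEFT)][1] += abs(shuffle)
            pose[JOINT_ORDER.index(JointName.ANKLE_RIGHT)][1] += abs(-shuffle)
            positions[i] = pose
            labels.append(FrameLabel.T)

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        positions = positions + rng.normal(0.0, cfg.noise_sd, size=positions.shape)

    seq = GaitSequence.from_arrays(positions, fps=cfg.fps, labels=labels, times=times)
    truth = GroundTruth(
        labels=list(labels),
        events=extract_semantics(labels),
        parameters=cfg.true_parameters(),
    )
    return seq, truth


def simulate_cohort(
    base_config: GaitSimConfig, n_walks: int, seed: int, vary: bool = True
) -> list[tuple[GaitSequence, GroundTruth]]:
    """Simulate ``n_walks`` walks with per-walk gait variation.

    Walk-to-walk variation draws cycle time, step lengths and swing
    fractions from ranges typical of adult gait, so cohort statistics span
    realistic between-subject spread; set ``vary=False`` to repeat the base
    config with fresh noise seeds only.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for k in range(n_walks):
        walk_seed = int(rng.integers(0, 2**31 - 1))
        if vary:
            cfg = replace(
                base_config,
                cycle_time=float(rng.uniform(0.85, 1.15)),
                step_length_left=float(rng.uniform(0.45, 0.60)),
                step_length_right=float(rng.uniform(0.45, 0.60)),
                swing_fraction_left=float(rng.uniform(0.27, 0.35)),
                swing_fraction_right=float(rng.uniform(0.27, 0.35)),
                seed=walk_seed,
            )
        else:
            cfg = replace(base_config, seed=walk_seed)
        cohort.append(simulate_gait(cfg))
    return cohort
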