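"""Skeleton time-series data model and plain-text tabular I/O.

A capture is a sequence of lower-body skeleton frames sampled by a depth
camera (nominally 30 Hz).  Each frame carries the 3-D camera-coordinate
positions (meters) of 9 lower-body joints; an optional per-frame gait-state
label stream from the 5-state alphabet {S, L, D, R, T} accompanies it.

Coordinate convention: right-handed camera frame with x lateral, y vertical
(up), z depth away from the camera.  Frame indices are 0-based and intervals
throughout the package are half-open ``[start, end)``.

The on-disk format is a CSV table with header
``index,time,<joint>_<axis>,...[,label]`` — joints in :class:`JointName`
order, axes x, y, z — chosen because it is diff-friendly and language
neutral.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JointName",
    "FrameLabel",
    "SkeletonFrame",
    "GaitSequence",
    "SkeletonFormatError",
    "read_skeleton_table",
    "write_skeleton_table",
    "read_label_file",
    "write_label_file",
]


class JointName(enum.Enum):
    """The 9 lower-body joints tracked by the pipeline."""

    PELVIS = "pelvis"
    HIP_LEFT = "hip_left"
    HIP_RIGHT = "hip_right"
    KNEE_LEFT = "knee_left"
    KNEE_RIGHT = "knee_right"
    ANKLE_LEFT = "ankle_left"
    ANKLE_RIGHT = "ankle_right"
    FOOT_LEFT = "foot_left"
    FOOT_RIGHT = "foot_right"


#: Fixed joint order used for array layouts and file columns.
JOINT_ORDER: tuple[JointName, ...] = tuple(JointName)

AXES = ("x", "y", "z")


class FrameLabel(enum.Enum):
    """Per-frame gait state.

    S = standstill, L = left swing, D = double support, R = right swing,
    T = turnaround.
    """

    S = "S"
    L = "L"
    D = "D"
    R = "R"
    T = "T"


class SkeletonFormatError(ValueError):
    """Raised when a skeleton/label file violates the expected format."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One captured frame: index, timestamp and all 9 joint positions."""

    index: int
    time: float
    positions: dict[JointName, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be >= 0, got {self.index}")
        missing = [j.value for j in JOINT_ORDER if j not in self.positions]
        if missing:
            raise ValueError(f"frame {self.index} missing joints: {missing}")
        for j, p in self.positions.items():
            if len(p) != 3 or not all(np.isfinite(p)):
                raise ValueError(
                    f"frame {self.index}, joint {j.value}: non-finite position {p}"
                )


@dataclass
class GaitSequence:
    """A time-ordered skeleton capture with optional gait-state labels."""

    frames: list[SkeletonFrame]
    fps: float = 30.0
    labels: list[FrameLabel] | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        t = [f.time for f in self.frames]
        if any(b < a for a, b in zip(t, t[1:])):
            raise ValueError("frame times must be nondecreasing")
        if self.labels is not None and len(self.labels) != len(self.frames):
            raise ValueError(
                f"labels length {len(self.labels)} != frame count {len(self.frames)}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        """Joint positions as an (n_frames, 9, 3) array in JOINT_ORDER."""
        out = np.empty((len(self.frames), len(JOINT_ORDER), 3))
        for i, f in enumerate(self.frames):
            for k, j in enumerate(JOINT_ORDER):
                out[i, k] = f.positions[j]
        return out

    def times_array(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def joint_positions(self, joint: JointName) -> np.ndarray:
        """(n_frames, 3) trajectory of one joint."""
        return np.array([f.positions[joint] for f in self.frames])

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        fps: float = 30.0,
        labels: Sequence[FrameLabel] | None = None,
        times: np.ndarray | None = None,
        indices: np.ndarray | None = None,
    ) -> "GaitSequence":
        """Build a sequence from an (n, 9, 3) position array."""
        positions = np.asarray(positions, dtype=float)
        n = positions.shape[0]
        if positions.shape != (n, len(JOINT_ORDER), 3):
            raise ValueError(f"expected (n, 9, 3) positions, got {positions.shape}")
        if times is None:
            times = np.arange(n) / fps
        if indices is None:
            indices = np.arange(n)
        frames = [
            SkeletonFrame(
                index=int(indices[i]),
                time=float(times[i]),
                positions={j: tuple(positions[i, k]) for k, j in enumerate(JOINT_ORDER)},
            )
            for i in range(n)
        ]
        return cls(frames=frames, fps=fps, labels=list(labels) if labels is not None else None)


def _coordinate_columns() -> list[str]:
    return [f"{j.value}_{a}" for j in JOINT_ORDER for a in AXES]


def read_skeleton_table(path: str | Path, fps: float = 30.0) -> GaitSequence:
    """Read a skeleton CSV table written by :func:`write_skeleton_table`.

    The header must name ``index``, the 27 ``<joint>_<axis>`` coordinate
    columns, and optionally ``time`` and ``label``.  A missing ``time``
    column is synthesized as ``index / fps`` (uniform sampling).
    """
    path = Path(path)
    df = pd.read_csv(path)
    coord_cols = _coordinate_columns()
    for col in ["index", *coord_cols]:
        if col not in df.columns:
            raise SkeletonFormatError(f"{path}: missing required column {col!r}")

    coords = df[coord_cols].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(coords))
    if bad.size:
        row, col = bad[0]
        raise SkeletonFormatError(
            f"{path}: non-finite coordinate in row {int(row)}, column {coord_cols[col]!r}"
        )

    indices = df["index"].to_numpy(dtype=int)
    if "time" in df.columns:
        times = df["time"].to_numpy(dtype=float)
    else:
        times = indices / fps

    labels = None
    if "label" in df.columns:
        labels = []
        for row, tok in enumerate(df["label"].astype(str)):
            try:
                labels.append(FrameLabel(tok.strip()))
            except ValueError:
                raise SkeletonFormatError(
                    f"{path}: unknown label token {tok!r} in row {row}"
                ) from None

    positions = coords.reshape(len(df), len(JOINT_ORDER), 3)
    return GaitSequence.from_arrays(
        positions, fps=fps, labels=labels, times=times, indices=indices
    )


def write_skeleton_table(seq: GaitSequence, path: str | Path) -> None:
    """Write a sequence as CSV; numeric fields keep >= 9 significant digits."""
    if len(seq.frames) == 0:
        raise ValueError("refusing to write an empty sequence")
    path = Path(path)
    data: dict[str, object] = {"index": [f.index for f in seq.frames]}
    data["time"] = [f.time for f in seq.frames]
    pos = seq.positions_array()
    for k, j in enumerate(JOINT_ORDER):
        for a_i, a in enumerate(AXES):
            data[f"{j.value}_{a}"] = pos[:, k, a_i]
    if seq.labels is not None:
        data["label"] = [lab.value for lab in seq.labels]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_label_file(path: str | Path) -> list[FrameLabel]:
    """Read a label stream: one token per line, or ``frame,label`` rows.

    Frame indices, when present, must be 0-based, contiguous and unique.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        return []
    labels: list[FrameLabel] = []
    indexed = "," in lines[0]
    seen: list[int] = []
    for lineno, ln in enumerate(lines, start=1):
        if indexed:
            parts = [p.strip() for p in ln.split(",")]
            if len(parts) != 2:
                raise SkeletonFormatError(f"{path}:{lineno}: expected 'frame,label'")
            try:
                seen.append(int(parts[0]))
            except ValueError:
                raise SkeletonFormatError(
                    f"{path}:{lineno}: bad frame index {parts[0]!r}"
                ) from None
            tok = parts[1]
        else:
            tok = ln
        try:
            labels.append(FrameLabel(tok))
        except ValueError:
            raise SkeletonFormatError(
                f"{path}:{lineno}: unknown label token {tok!r}"
            ) from None
    if indexed and seen != list(range(len(seen))):
        raise SkeletonFormatError(f"{path}: frame indices must be 0..n-1 without gaps")
    return labels


def write_label_file(labels: Sequence[FrameLabel], path: str | Path) -> None:
    Path(path).write_text("".join(f"{lab.value}\n" for lab in labels))
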