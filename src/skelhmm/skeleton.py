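"""Core skeleton data containers.

Motion data is represented as ordered frames of 25 named joints in camera
space (millimetres), the joint set reported by the Kinect v2 body tracker.
Coordinates are stored as a dense ``(T, 25, 3)`` float array together with a
per-frame/per-joint ``tracked`` flag so downstream filters can distinguish a
genuinely measured position from a dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Canonical joint order (Kinect v2 naming, 25 joints).
JOINT_NAMES: tuple[str, ...] = (
    "spine_base",
    "spine_mid",
    "neck",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
    "spine_shoulder",
    "hand_tip_left",
    "thumb_left",
    "hand_tip_right",
    "thumb_right",
)

N_JOINTS = len(JOINT_NAMES)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}


def joint_indices(names) -> np.ndarray:
    """Map joint names to their canonical indices, validating each name."""
    try:
        return np.asarray([JOINT_INDEX[n] for n in names], dtype=int)
    except KeyError as exc:  # pragma: no cover - message matters, not path
        raise ValueError(f"unknown joint name: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class SkeletonFrame:
    """A single time-stamped skeleton observation.

    Attributes
    ----------
    time_index : int
        Frame ordinal within its sequence.
    joints : (25, 3) float array
        Joint positions in millimetres, camera space, canonical joint order.
    tracked : (25,) bool array
        Per-joint validity flag.
    """

    time_index: int
    joints: np.ndarray
    tracked: np.ndarray

    def __post_init__(self):
        joints = np.asarray(self.joints, dtype=float)
        tracked = np.asarray(self.tracked, dtype=bool)
        if joints.shape != (N_JOINTS, 3):
            raise ValueError(f"expected (25, 3) joints, got {joints.shape}")
        if tracked.shape != (N_JOINTS,):
            raise ValueError(f"expected (25,) tracked flags, got {tracked.shape}")
        if not np.all(np.isfinite(joints[tracked])):
            raise ValueError("tracked joint coordinates must be finite")
        object.__setattr__(self, "joints", joints)
        object.__setattr__(self, "tracked", tracked)


@dataclass(frozen=True)
class MotionSequence:
    """An ordered sequence of skeleton frames forming one motion.

    Attributes
    ----------
    positions : (T, 25, 3) float array
        Joint positions in millimetres.
    tracked : (T, 25) bool array
        Per-frame, per-joint validity.
    time_index : (T,) int array
        Strictly increasing frame ordinals.
    label : str or None
        Optional action-class name.
    frame_rate : float
        Capture rate in Hz.
    """

    positions: np.ndarray
    tracked: np.ndarray = None  # type: ignore[assignment]
    time_index: np.ndarray = None  # type: ignore[assignment]
    label: str | None = None
    frame_rate: float = 30.0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[1:] != (N_JOINTS, 3) or pos.shape[0] < 1:
            raise ValueError(
                f"positions must be (T>=1, {N_JOINTS}, 3), got {pos.shape}"
            )
        tracked = self.tracked
        if tracked is None:
            tracked = np.ones(pos.shape[:2], dtype=bool)
        tracked = np.asarray(tracked, dtype=bool)
        if tracked.shape != pos.shape[:2]:
            raise ValueError("tracked shape must match (T, 25)")
        t_idx = self.time_index
        if t_idx is None:
            t_idx = np.arange(pos.shape[0])
        t_idx = np.asarray(t_idx, dtype=int)
        if t_idx.shape != (pos.shape[0],) or np.any(np.diff(t_idx) <= 0):
            raise ValueError("time_index must be strictly increasing, one per frame")
        if not np.all(np.isfinite(pos[tracked])):
            raise ValueError("tracked coordinates must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "tracked", tracked)
        object.__setattr__(self, "time_index", t_idx)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            time_index=int(self.time_index[i]),
            joints=self.positions[i],
            tracked=self.tracked[i],
        )

    def with_positions(self, positions: np.ndarray) -> "MotionSequence":
        """Copy of this sequence with replaced coordinates (same metadata)."""
        return replace(self, positions=positions)

    @classmethod
    def from_frames(
        cls,
        frames,
        label: str | None = None,
        frame_rate: float = 30.0,
    ) -> "MotionSequence":
        frames = list(frames)
        if not frames:
            raise ValueError("a motion sequence needs at least one frame")
        return cls(
            positions=np.stack([f.joints for f in frames]),
            tracked=np.stack([f.tracked for f in frames]),
            time_index=np.asarray([f.time_index for f in frames]),
            label=label,
            frame_rate=frame_rate,
        )
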