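"""Parametric synthetic skeleton motions for end-to-end benchmarking.

Every stage of the pipeline — filtering, keyframe compression, quantization,
HMM training, recognition — can be exercised without any recorded capture by
generating labeled motions from parametric action templates. A template is a
standing skeleton of realistic proportions (torso 500 mm, camera space,
millimetres) plus a set of per-joint motion primitives (sinusoids along an
axis or circles in a plane) that displace selected joints over the cycle.
The noise model adds i.i.d. Gaussian jitter to every coordinate and, with a
small per-joint-frame probability, an isotropic spike displacement — the two
artefact types the amplitude-limiting filter is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import JOINT_INDEX, JOINT_NAMES, N_JOINTS, MotionSequence

# ---------------------------------------------------------------------------
# Base pose: a standing skeleton, camera space (x right, y up, z depth), mm.
# spine_base at (0, 1000, 2500); torso (spine_base -> spine_shoulder) 500 mm.
# ---------------------------------------------------------------------------
_BASE = np.zeros((N_JOINTS, 3))
_P = {
    "spine_base": (0, 1000, 2500),
    "spine_mid": (0, 1250, 2500),
    "spine_shoulder": (0, 1500, 2500),
    "neck": (0, 1550, 2500),
    "head": (0, 1700, 2500),
    "shoulder_left": (-200, 1480, 2500),
    "elbow_left": (-250, 1200, 2500),
    "wrist_left": (-280, 950, 2500),
    "hand_left": (-290, 900, 2500),
    "hand_tip_left": (-295, 850, 2500),
    "thumb_left": (-265, 905, 2480),
    "shoulder_right": (200, 1480, 2500),
    "elbow_right": (250, 1200, 2500),
    "wrist_right": (280, 950, 2500),
    "hand_right": (290, 900, 2500),
    "hand_tip_right": (295, 850, 2500),
    "thumb_right": (265, 905, 2480),
    "hip_left": (-100, 980, 2500),
    "knee_left": (-110, 550, 2500),
    "ankle_left": (-115, 100, 2500),
    "foot_left": (-115, 40, 2380),
    "hip_right": (100, 980, 2500),
    "knee_right": (110, 550, 2500),
    "ankle_right": (115, 100, 2500),
    "foot_right": (115, 40, 2380),
}
for _name, _xyz in _P.items():
    _BASE[JOINT_INDEX[_name]] = _xyz


@dataclass(frozen=True)
class JointMotion:
    """One motion primitive applied additively to a set of joints.

    kind 'sine': displacement = amplitude * sin(2*pi*(freq*t + phase)) along
    ``axis``. kind 'circle': the joint traces a circle of radius
    ``amplitude`` in the plane spanned by the two axes in ``plane``.
    kind 'offset': constant displacement of ``amplitude`` along ``axis``
    (a held posture change, e.g. a raised arm). Frequencies are in Hz,
    amplitudes in mm, time in seconds.
    """

    joints: tuple[str, ...]
    kind: str  # "sine" | "circle" | "offset"
    amplitude: float
    frequency: float
    phase: float = 0.0
    axis: int = 1  # for "sine": 0=x, 1=y, 2=z
    plane: tuple[int, int] = (0, 1)  # for "circle"

    def displacement(self, t: np.ndarray) -> np.ndarray:
        """(T, 3) displacement at times t (seconds)."""
        out = np.zeros((t.size, 3))
        ang = 2 * np.pi * (self.frequency * t + self.phase)
        if self.kind == "sine":
            out[:, self.axis] = self.amplitude * np.sin(ang)
        elif self.kind == "offset":
            out[:, self.axis] = self.amplitude
        elif self.kind == "circle":
            a, b = self.plane
            out[:, a] = self.amplitude * np.cos(ang)
            out[:, b] = self.amplitude * np.sin(ang)
        else:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        return out


@dataclass(frozen=True)
class ActionTemplate:
    """A named action: base pose + additive per-joint motion primitives."""

    name: str
    motions: tuple[JointMotion, ...]
    duration: int = 120  # default frame count when none is requested
    frame_rate: float = 30.0

    def evaluate(self, T: int) -> MotionSequence:
        """Noise-free trajectory over T frames at the template frame rate."""
        if T < 2:
            raise ValueError("T must be >= 2")
        t = np.arange(T) / self.frame_rate
        pos = np.broadcast_to(_BASE, (T, N_JOINTS, 3)).copy()
        for m in self.motions:
            disp = m.displacement(t)
            for name in m.joints:
                pos[:, JOINT_INDEX[name]] += disp
        return MotionSequence(positions=pos, label=self.name, frame_rate=self.frame_rate)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters: Gaussian sd (mm) per coordinate, and
    sparse isotropic spikes of fixed magnitude (mm) with per-joint-frame
    probability ``spike_prob``."""

    gaussian_sd: float = 3.0
    spike_prob: float = 0.005
    spike_magnitude: float = 150.0

    def __post_init__(self):
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike_prob must be in [0, 1]")
        if self.gaussian_sd < 0 or self.spike_magnitude < 0:
            raise ValueError("noise magnitudes must be non-negative")


def default_library() -> tuple[ActionTemplate, ...]:
    """Five distinguishable whole-body action templates.

    arm_wave: the right arm swings laterally overhead; draw_circle: the
    right hand traces a circle in the frontal plane; squat: the whole body
    bobs vertically with knees flexing forward; sit_up_cycle: the torso and
    head pitch toward the knees and back; pull_up_cycle: both arms stay
    raised while the whole body translates vertically.
    """
    arm_r = ("elbow_right", "wrist_right", "hand_right", "hand_tip_right", "thumb_right")
    arm_l = ("elbow_left", "wrist_left", "hand_left", "hand_tip_left", "thumb_left")
    upper = (
        "spine_mid", "spine_shoulder", "neck", "head",
        "shoulder_left", "shoulder_right",
    ) + arm_r + arm_l
    whole = JOINT_NAMES
    return (
        ActionTemplate(
            "arm_wave",
            motions=(
                JointMotion(("wrist_right", "hand_right", "hand_tip_right", "thumb_right"), "offset", amplitude=500, frequency=0.0, axis=1),
                JointMotion(("elbow_right",), "offset", amplitude=250, frequency=0.0, axis=1),
                JointMotion(("wrist_right", "hand_right", "hand_tip_right", "thumb_right"), "sine", amplitude=250, frequency=0.5, axis=0),
                JointMotion(("elbow_right",), "sine", amplitude=100, frequency=0.5, axis=0),
            ),
        ),
        ActionTemplate(
            "draw_circle",
            motions=(
                JointMotion(
                    ("wrist_right", "hand_right", "hand_tip_right", "thumb_right"),
                    "circle", amplitude=250, frequency=0.5, plane=(0, 1),
                ),
                JointMotion(("elbow_right",), "circle", amplitude=120, frequency=0.5, plane=(0, 1)),
            ),
        ),
        ActionTemplate(
            "squat",
            motions=(
                JointMotion(
                    tuple(j for j in whole if j not in ("ankle_left", "ankle_right", "foot_left", "foot_right")),
                    "sine", amplitude=200, frequency=0.4, axis=1, phase=0.75,
                ),
                JointMotion(("knee_left", "knee_right"), "sine", amplitude=150, frequency=0.4, axis=2, phase=0.25),
            ),
        ),
        ActionTemplate(
            "sit_up_cycle",
            motions=(
                JointMotion(("head", "neck"), "sine", amplitude=400, frequency=0.3, axis=2, phase=0.25),
                JointMotion(("spine_shoulder", "shoulder_left", "shoulder_right"), "sine", amplitude=300, frequency=0.3, axis=2, phase=0.25),
                JointMotion(("head", "neck", "spine_shoulder", "shoulder_left", "shoulder_right"), "sine", amplitude=250, frequency=0.3, axis=1, phase=0.5),
                JointMotion(arm_r + arm_l, "sine", amplitude=200, frequency=0.3, axis=2, phase=0.25),
            ),
        ),
        ActionTemplate(
            "pull_up_cycle",
            motions=(
                JointMotion(arm_r + arm_l, "sine", amplitude=300, frequency=0.35, axis=1, phase=0.25),
                JointMotion(
                    tuple(j for j in whole if j not in arm_r + arm_l),
                    "sine", amplitude=250, frequency=0.35, axis=1, phase=0.25,
                ),
                JointMotion(("knee_left", "knee_right"), "sine", amplitude=100, frequency=0.35, axis=2, phase=0.75),
            ),
        ),
    )


def generate_motion(
    template: ActionTemplate,
    T: int,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
) -> MotionSequence:
    """Evaluate a template over T frames and corrupt it with the noise model.

    Deterministic given (template, T, noise, seed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = template.evaluate(T)
    pos = clean.positions.copy()
    if noise.gaussian_sd > 0:
        pos += rng.normal(0.0, noise.gaussian_sd, size=pos.shape)
    if noise.spike_prob > 0 and noise.spike_magnitude > 0:
        hits = rng.random((T, N_JOINTS)) < noise.spike_prob
        n_hits = int(hits.sum())
        if n_hits:
            dirs = rng.normal(size=(n_hits, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pos[hits] += noise.spike_magnitude * dirs
    return clean.with_positions(pos)


def generate_dataset(
    library=None,
    n_per_class: int = 20,
    T: int = 120,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> list[MotionSequence]:
    """``n_per_class`` labeled sequences per template, reproducibly.

    Per-sequence generators are spawned from one master SeedSequence, so
    regenerating with the same master seed gives an identical dataset and
    no two sequences share a random stream.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    library = tuple(library) if library is not None else default_library()
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(library) * n_per_class)
    out = []
    k = 0
    for tpl in library:
        for _ in range(n_per_class):
            rng = np.random.default_rng(children[k])
            out.append(generate_motion(tpl, T, noise, rng))
            k += 1
    return out
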