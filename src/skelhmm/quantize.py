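"""From continuous skeletons to discrete observation symbols.

A discrete HMM consumes a finite symbol alphabet, so each skeleton frame is
first summarised as a pose feature vector and then vector-quantized against
a k-means codebook. Features are the concatenated coordinates of a subset of
informative joints after two normalizations that remove nuisance variation:
the skeleton is translated so ``spine_base`` sits at the origin (camera
position independence) and scaled by the torso length (subject size
independence). Symbols are 1-based, matching the usual V_1 ... V_M notation
for discrete HMM observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .skeleton import JOINT_NAMES, MotionSequence, joint_indices

#: Joints at the "vital positions" of a moving body: extremities plus the
#: proximal joints that drive them, and the root for reference.
DEFAULT_JOINT_SUBSET: tuple[str, ...] = (
    "head",
    "hand_left",
    "hand_right",
    "elbow_left",
    "elbow_right",
    "shoulder_left",
    "shoulder_right",
    "knee_left",
    "knee_right",
    "foot_left",
    "foot_right",
    "spine_base",
)

DEFAULT_M = 16


@dataclass(frozen=True)
class Codebook:
    """M centroids mapping pose feature vectors to discrete symbols 1..M."""

    centroids: np.ndarray
    seed: int
    joint_subset: tuple[str, ...] = DEFAULT_JOINT_SUBSET

    def __post_init__(self):
        c = np.asarray(self.centroids, dtype=float)
        if c.ndim != 2 or c.shape[0] < 1:
            raise ValueError("centroids must be a (M >= 1, dim) array")
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "joint_subset", tuple(self.joint_subset))

    @property
    def M(self) -> int:
        return self.centroids.shape[0]

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]


@dataclass(frozen=True)
class ObservationSequence:
    """Ordered symbols in [1, M] produced by encoding one motion."""

    symbols: np.ndarray
    label: str | None = None

    def __post_init__(self):
        s = np.asarray(self.symbols, dtype=int)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("symbols must be a non-empty 1-D sequence")
        if s.min() < 1:
            raise ValueError("symbols are 1-based; found a value < 1")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return self.symbols.size


def extract_features(
    seq: MotionSequence,
    joint_subset=DEFAULT_JOINT_SUBSET,
    velocity: bool = False,
) -> np.ndarray:
    """Per-frame pose feature vectors, shape ``(T, 3 * len(joint_subset))``.

    Each frame is translated so spine_base is the origin and scaled by the
    torso length (spine_base to spine_shoulder distance), then the selected
    joints' coordinates are concatenated in the given order. With
    ``velocity=True``, first differences of the pose features are appended
    (zero for the first frame), doubling the dimension.

    Raises
    ------
    ValueError
        If ``joint_subset`` is empty or contains an unknown name, or if any
        frame has a degenerate (zero-length) torso.
    """
    if len(joint_subset) == 0:
        raise ValueError("joint_subset must not be empty")
    sel = joint_indices(joint_subset)
    root = seq.positions[:, joint_indices(["spine_base"])[0]]
    top = seq.positions[:, joint_indices(["spine_shoulder"])[0]]
    torso = np.linalg.norm(top - root, axis=1)
    if np.any(torso <= 0):
        bad = int(np.flatnonzero(torso <= 0)[0])
        raise ValueError(f"degenerate skeleton: zero torso length at frame {bad}")
    centred = (seq.positions[:, sel] - root[:, None, :]) / torso[:, None, None]
    feats = centred.reshape(len(seq), -1)
    if velocity:
        vel = np.zeros_like(feats)
        vel[1:] = np.diff(feats, axis=0)
        feats = np.concatenate([feats, vel], axis=1)
    return feats


def build_codebook(
    features: np.ndarray,
    M: int = DEFAULT_M,
    seed: int = 0,
    joint_subset=DEFAULT_JOINT_SUBSET,
) -> Codebook:
    """k-means codebook over pooled frame features; deterministic given seed.

    Requires at least ``M`` distinct feature vectors.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be (n_frames, dim)")
    n_distinct = np.unique(features, axis=0).shape[0]
    if M > n_distinct:
        raise ValueError(
            f"alphabet size M={M} exceeds the {n_distinct} distinct feature vectors"
        )
    km = KMeans(n_clusters=M, random_state=seed, n_init=10)
    km.fit(features)
    # Sort centroids lexicographically so the codebook is independent of
    # k-means' internal label order.
    order = np.lexsort(km.cluster_centers_.T[::-1])
    return Codebook(
        centroids=km.cluster_centers_[order],
        seed=seed,
        joint_subset=tuple(joint_subset),
    )


def encode(
    features: np.ndarray,
    codebook: Codebook,
    label: str | None = None,
) -> ObservationSequence:
    """Map each frame to its nearest centroid (Euclidean); ties take the
    lowest symbol index. Symbols are 1-based."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != codebook.dim:
        raise ValueError(
            f"feature dimension {features.shape} does not match codebook dim {codebook.dim}"
        )
    d2 = (
        (features**2).sum(axis=1, keepdims=True)
        - 2 * features @ codebook.centroids.T
        + (codebook.centroids**2).sum(axis=1)
    )
    # Exact re-check of near-ties so float noise in the expanded form cannot
    # flip the lowest-index rule.
    sym = np.empty(features.shape[0], dtype=int)
    for i, row in enumerate(d2):
        cand = np.flatnonzero(row <= row.min() + 1e-9)
        if cand.size > 1:
            exact = np.linalg.norm(features[i] - codebook.centroids[cand], axis=1)
            cand = cand[exact <= exact.min() + 1e-12]
        sym[i] = cand[0] + 1
    return ObservationSequence(symbols=sym, label=label)


def encode_sequence(
    seq: MotionSequence,
    codebook: Codebook,
    velocity: bool = False,
) -> ObservationSequence:
    """Feature extraction + encoding of a whole motion sequence."""
    feats = extract_features(seq, codebook.joint_subset, velocity=velocity)
    return encode(feats, codebook, label=seq.label)
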