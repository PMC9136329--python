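"""Skeleton stream conditioning: amplitude-limiting filter and keyframe extraction.

Joint streams from consumer depth sensors carry two kinds of error with very
different signatures. Micro-jitter is a small tremor around a stationary
position; isolated tracking failures throw a joint hundreds of millimetres
off for a frame or two. The amplitude-limiting filter handles both with one
causal rule per joint: displacements below ``jitter_radius`` are suppressed
(the previous filtered position is held), displacements above
``deviation_radius`` are clamped to that radius along the displacement
direction, and anything in between passes through unchanged.

Keyframe extraction then compresses the cleaned sequence, treating the
reconstruction error and the number of keyframes as the two optimization
goals: it keeps the fewest frames such that linearly interpolating every
dropped frame between its surviving neighbours stays within a per-joint
reconstruction-error budget. The compression ratio is total frames divided
by retained frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import MotionSequence


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the amplitude-limiting filter, in millimetres.

    ``jitter_radius`` is the dead-band below which a displacement is treated
    as tremor and discarded; ``deviation_radius`` is the largest credible
    one-frame displacement, beyond which the step is clamped.
    """

    jitter_radius: float = 5.0
    deviation_radius: float = 50.0

    def __post_init__(self):
        if not 0 <= self.jitter_radius < self.deviation_radius:
            raise ValueError(
                "need 0 <= jitter_radius < deviation_radius, got "
                f"{self.jitter_radius} / {self.deviation_radius}"
            )


@dataclass(frozen=True)
class KeyframeResult:
    """Outcome of keyframe extraction on one sequence."""

    indices: np.ndarray
    max_error: float
    compression_ratio: float

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise ValueError("keyframe index set cannot be empty")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("keyframe indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)


def limit_filter(seq: MotionSequence, params: FilterParams = FilterParams()) -> MotionSequence:
    """Apply the causal amplitude-limiting filter to every joint stream.

    The first frame passes unchanged. For each later frame, per joint, with
    displacement delta = ||x_t - xhat_{t-1}|| from the previous *filtered*
    position:

    * delta < jitter_radius  -> hold xhat_{t-1} (jitter suppressed);
    * delta > deviation_radius -> clamp to xhat_{t-1} +
      deviation_radius * (x_t - xhat_{t-1}) / delta (spike rejected);
    * otherwise -> pass x_t through.

    Untracked samples hold the last tracked filtered position. A joint with
    no tracked sample anywhere in the sequence is an error. Filter state
    never crosses sequence boundaries.
    """
    pos = seq.positions
    tracked = seq.tracked
    never_tracked = ~tracked.any(axis=0)
    if never_tracked.any():
        from .skeleton import JOINT_NAMES

        bad = [JOINT_NAMES[j] for j in np.flatnonzero(never_tracked)]
        raise ValueError(f"joint(s) never tracked in sequence: {', '.join(bad)}")

    T = pos.shape[0]
    out = pos.copy()
    # Initialize each joint's state from its first tracked sample so the
    # filter has a credible anchor even when frame 0 has dropouts.
    first_tracked = tracked.argmax(axis=0)  # index of first True per joint
    state = pos[first_tracked, np.arange(pos.shape[1])].copy()
    out[0] = state

    for t in range(T):
        cur = pos[t]
        trk = tracked[t]
        delta_vec = cur - state
        delta = np.linalg.norm(delta_vec, axis=1)
        if t == 0:
            # First frame passes unchanged (state already holds the first
            # tracked sample per joint; untracked joints keep that anchor).
            out[0] = np.where(trk[:, None], cur, state)
            state = out[0].copy()
            continue
        hold = (delta < params.jitter_radius) | ~trk
        clamp = (delta > params.deviation_radius) & trk
        new = cur.copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(delta[:, None] > 0, delta_vec / delta[:, None], 0.0)
        new[clamp] = state[clamp] + params.deviation_radius * unit[clamp]
        new[hold] = state[hold]
        out[t] = new
        state = new.copy()

    return seq.with_positions(out)


def _span_error(pos: np.ndarray, lo: int, hi: int) -> float:
    """Max per-joint error when frames (lo, hi) are linearly interpolated
    between keyframes lo and hi. Zero when the span has no interior."""
    if hi - lo < 2:
        return 0.0
    ts = np.arange(lo + 1, hi)
    w = (ts - lo) / (hi - lo)
    interp = (1 - w)[:, None, None] * pos[lo] + w[:, None, None] * pos[hi]
    return float(np.linalg.norm(interp - pos[lo + 1 : hi], axis=2).max())


#: Consecutive infeasible span extensions tolerated before the search stops
#: lengthening a span. Interpolation error grows with span length on smooth
#: motion, so a short grace window recovers the occasional noise-induced dip
#: without scanning every one of the O(T^2) spans.
_SPAN_SCAN_GRACE = 5


def extract_keyframes(seq: MotionSequence, max_error: float) -> KeyframeResult:
    """Minimum-keyframe frame reduction under a reconstruction-error budget.

    Finds the smallest set of retained frames (first and last always kept)
    such that linearly interpolating every dropped frame between its
    surviving neighbours deviates at most ``max_error`` (mm, per joint, per
    frame), via shortest-path dynamic programming over feasible spans: frame
    b is reachable from keyframe a when the span a..b reconstructs within
    budget. Candidate spans stop growing after ``_SPAN_SCAN_GRACE``
    consecutive infeasible extensions, which keeps the search linear in the
    typical span length. Ties between equally small keyframe sets resolve to
    the earliest predecessor, making the result deterministic.
    """
    if max_error < 0:
        raise ValueError(f"max_error must be >= 0, got {max_error}")
    T = seq.n_frames
    if T < 2:
        raise ValueError("keyframe extraction needs a sequence of >= 2 frames")

    pos = seq.positions
    big = T + 1
    n_keys = np.full(T, big)  # fewest keyframes ending at frame t
    prev = np.full(T, -1)
    n_keys[0] = 1
    for a in range(T - 1):
        if n_keys[a] >= big:
            continue
        misses = 0
        for b in range(a + 1, T):
            if _span_error(pos, a, b) <= max_error:
                misses = 0
                if n_keys[a] + 1 < n_keys[b]:
                    n_keys[b] = n_keys[a] + 1
                    prev[b] = a
            else:
                misses += 1
                if misses >= _SPAN_SCAN_GRACE:
                    break

    chain = [T - 1]
    while prev[chain[-1]] >= 0:
        chain.append(int(prev[chain[-1]]))
    indices = np.asarray(chain[::-1])
    achieved = 0.0
    for a, b in zip(indices[:-1], indices[1:]):
        achieved = max(achieved, _span_error(pos, int(a), int(b)))
    return KeyframeResult(
        indices=indices,
        max_error=achieved,
        compression_ratio=T / len(indices),
    )


def reconstruct(result: KeyframeResult, seq: MotionSequence) -> MotionSequence:
    """Rebuild the full-length sequence from its keyframes.

    Non-key frames are linearly interpolated per joint between the flanking
    keyframes; frames outside the keyframe range are held at the nearest
    keyframe. Companion to :func:`extract_keyframes` for verifying the
    reconstruction-error bound.
    """
    idx = result.indices
    if idx.size == 0:
        raise ValueError("empty keyframe index set")
    T = seq.n_frames
    if idx.min() < 0 or idx.max() >= T:
        raise ValueError("keyframe indices outside sequence range")
    pos = seq.positions
    out = pos.copy()
    t_all = np.arange(T)
    flat = pos[idx].reshape(len(idx), -1)
    recon = np.empty((T, flat.shape[1]))
    for c in range(flat.shape[1]):
        recon[:, c] = np.interp(t_all, idx, flat[:, c])
    out = recon.reshape(T, *pos.shape[1:])
    return seq.with_positions(out)


def reconstruction_error(result: KeyframeResult, seq: MotionSequence) -> float:
    """Max per-joint, per-frame deviation of the reconstruction from ``seq``."""
    rec = reconstruct(result, seq)
    return float(np.linalg.norm(rec.positions - seq.positions, axis=2).max())
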