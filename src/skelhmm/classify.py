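"""Per-action HMM training and maximum-likelihood recognition.

One discrete HMM is trained per action class. Because Baum–Welch only finds
a local optimum, each class model is seeded by uniform segmentation: every
training sequence is split into N equal contiguous segments, frames in
segment i are provisionally assigned hidden state i, and the initial
(pi0, A0, B0) are the count-based estimates under that assignment. This
naturally yields a near-left-to-right transition structure that Baum–Welch
is free to adjust (no left-to-right constraint is enforced).

Recognition scores a test sequence with the forward algorithm under every
class model and returns the label with the largest log P(O | lambda_i).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .hmm import (
    DEFAULT_FLOOR,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    DiscreteHMM,
    baum_welch,
    forward,
)
from .quantize import Codebook, ObservationSequence

DEFAULT_N_STATES = 5


@dataclass(frozen=True)
class InitStats:
    """Count statistics of the uniform-segmentation initialization."""

    segment_assignment: list[np.ndarray]  # per sequence: frame -> state (1-based)
    first_state_counts: np.ndarray  # N_i^m summed over sequences
    transition_counts: np.ndarray  # N_{i,j}^m summed over sequences


@dataclass(frozen=True)
class BaumWelchOptions:
    max_iter: int = DEFAULT_MAX_ITER
    tol: float = DEFAULT_TOL
    floor: float = DEFAULT_FLOOR


@dataclass(frozen=True)
class ActionModelSet:
    """One trained HMM per action class, sharing a codebook and (N, M)."""

    labels: tuple[str, ...]
    models: dict[str, DiscreteHMM]
    codebook: Codebook | None
    N: int
    M: int

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if set(self.labels) != set(self.models):
            raise ValueError("labels and models must correspond one-to-one")
        for lbl, m in self.models.items():
            if m.M != self.M:
                raise ValueError(f"model {lbl!r} has M={m.M}, expected {self.M}")

    def to_dict(self) -> dict:
        d = {
            "N": self.N,
            "M": self.M,
            "labels": list(self.labels),
            "models": {lbl: m.to_dict() for lbl, m in self.models.items()},
        }
        if self.codebook is not None:
            d["codebook"] = {
                "centroids": self.codebook.centroids.tolist(),
                "seed": self.codebook.seed,
                "joint_subset": list(self.codebook.joint_subset),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ActionModelSet":
        cb = None
        if "codebook" in d:
            cb = Codebook(
                centroids=np.asarray(d["codebook"]["centroids"]),
                seed=int(d["codebook"]["seed"]),
                joint_subset=tuple(d["codebook"]["joint_subset"]),
            )
        return cls(
            labels=tuple(d["labels"]),
            models={lbl: DiscreteHMM.from_dict(m) for lbl, m in d["models"].items()},
            codebook=cb,
            N=int(d["N"]),
            M=int(d["M"]),
        )


@dataclass(frozen=True)
class RecognitionResult:
    predicted_label: str
    per_class_log_likelihoods: dict[str, float]
    margin: float


@dataclass(frozen=True)
class EvaluationReport:
    recognition_rate: float
    confusion_matrix: np.ndarray  # true x predicted, label order
    labels: tuple[str, ...]
    per_class_rates: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "recognition_rate": self.recognition_rate,
            "labels": list(self.labels),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class_rates": dict(self.per_class_rates),
        }


def uniform_segments(T: int, N: int) -> np.ndarray:
    """Frame -> state assignment (1-based) splitting T frames into N equal
    contiguous segments; remainder frames go to the later segments."""
    if T < N:
        raise ValueError(f"sequence of length {T} cannot be split into {N} segments")
    base, rem = divmod(T, N)
    sizes = [base] * (N - rem) + [base + 1] * rem
    return np.repeat(np.arange(1, N + 1), sizes)


def init_params(
    obs_set,
    N: int,
    M: int,
    return_stats: bool = False,
):
    """Count-based (pi0, A0, B0) from uniform segmentation.

    pi0 comes from first-frame state counts (so it is always the indicator
    of state 1), A0 from adjacent-frame transition counts normalized per
    source state, and B0 from per-state symbol frequencies with add-one
    smoothing. All rows are valid probability distributions.
    """
    obs_set = list(obs_set)
    if not obs_set:
        raise ValueError("obs_set must contain at least one sequence")
    first_counts = np.zeros(N)
    trans_counts = np.zeros((N, N))
    emit_counts = np.zeros((N, M))
    assignments = []
    for m_idx, obs in enumerate(obs_set):
        T = len(obs)
        if T < N:
            raise ValueError(
                f"sequence #{m_idx} (label={obs.label!r}) has {T} frames, "
                f"fewer than the {N} states to initialize"
            )
        seg = uniform_segments(T, N)
        assignments.append(seg)
        first_counts[seg[0] - 1] += 1
        np.add.at(trans_counts, (seg[:-1] - 1, seg[1:] - 1), 1)
        np.add.at(emit_counts, (seg - 1, obs.symbols - 1), 1)

    pi0 = first_counts / first_counts.sum()
    a_den = trans_counts.sum(axis=1, keepdims=True)
    A0 = np.where(a_den > 0, trans_counts / np.where(a_den > 0, a_den, 1.0), 0.0)
    # A state with no outgoing transitions (only possible for the final
    # state of length-N sequences) self-loops.
    for i in np.flatnonzero(a_den.ravel() == 0):
        A0[i, i] = 1.0
    B0 = (emit_counts + 1.0) / (emit_counts + 1.0).sum(axis=1, keepdims=True)
    hmm0 = DiscreteHMM(pi=pi0, A=A0, B=B0)
    if return_stats:
        return hmm0, InitStats(
            segment_assignment=assignments,
            first_state_counts=first_counts,
            transition_counts=trans_counts,
        )
    return hmm0


def train_action_models(
    labeled_seqs,
    N: int = DEFAULT_N_STATES,
    M: int | None = None,
    codebook: Codebook | None = None,
    bw_options: BaumWelchOptions = BaumWelchOptions(),
) -> ActionModelSet:
    """Train one HMM per label from uniform-segmentation initialization.

    ``labeled_seqs`` is an iterable of ObservationSequence with non-None
    labels. M defaults to the codebook size when a codebook is given.
    Deterministic: the initialization is count-based and Baum–Welch has no
    random element.
    """
    seqs = list(labeled_seqs)
    if M is None:
        if codebook is None:
            raise ValueError("give M explicitly or provide a codebook")
        M = codebook.M
    by_label: dict[str, list[ObservationSequence]] = {}
    for s in seqs:
        if s.label is None:
            raise ValueError("every training sequence needs a label")
        by_label.setdefault(s.label, []).append(s)
    if not by_label:
        raise ValueError("no training sequences given")
    for lbl, group in by_label.items():
        if not group:
            raise ValueError(f"label {lbl!r} has no training sequences")

    models = {}
    for lbl in sorted(by_label):
        hmm0 = init_params(by_label[lbl], N=N, M=M)
        trained, _ = baum_welch(
            hmm0,
            by_label[lbl],
            max_iter=bw_options.max_iter,
            tol=bw_options.tol,
            floor=bw_options.floor,
        )
        models[lbl] = trained
    return ActionModelSet(
        labels=tuple(sorted(by_label)), models=models, codebook=codebook, N=N, M=M
    )


def recognize(models: ActionModelSet, obs: ObservationSequence) -> RecognitionResult:
    """Label an observation sequence by maximum forward log-likelihood.

    Ties go to the lexicographically first label. The margin is the gap
    between the best and runner-up log-likelihoods (infinite for a
    single-model set).
    """
    if not models.models:
        raise ValueError("empty model set")
    lls = {
        lbl: forward(models.models[lbl], obs).log_likelihood
        for lbl in sorted(models.labels)
    }
    best = max(lls, key=lambda l: (lls[l], ))  # max with lexicographic tie-break
    # Python's max keeps the first of equal keys; sorted(labels) makes that
    # the lexicographically first label.
    values = sorted(lls.values(), reverse=True)
    margin = float("inf") if len(values) < 2 else values[0] - values[1]
    return RecognitionResult(
        predicted_label=best, per_class_log_likelihoods=lls, margin=margin
    )


def evaluate(models: ActionModelSet, labeled_test_set) -> EvaluationReport:
    """Recognition rate, confusion matrix and per-class rates on a test set."""
    test = list(labeled_test_set)
    if not test:
        raise ValueError("test set must not be empty")
    labels = models.labels
    index = {lbl: i for i, lbl in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for obs in test:
        if obs.label not in index:
            raise ValueError(f"unknown true label {obs.label!r}")
        pred = recognize(models, obs).predicted_label
        cm[index[obs.label], index[pred]] += 1
    totals = cm.sum(axis=1)
    per_class = {
        lbl: (cm[i, i] / totals[i] if totals[i] else float("nan"))
        for i, lbl in enumerate(labels)
    }
    return EvaluationReport(
        recognition_rate=float(np.trace(cm) / cm.sum()),
        confusion_matrix=cm,
        labels=labels,
        per_class_rates=per_class,
    )
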