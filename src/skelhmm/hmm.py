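"""Discrete hidden Markov models: evaluation, learning, decoding.

A discrete HMM lambda = (pi, A, B) has N hidden states and an alphabet of M
observation symbols: ``pi`` is the initial state distribution, ``A[i, j]``
the probability of moving from state i to state j between consecutive
frames, and ``B[j, k]`` the probability of emitting symbol k from state j.
States and symbols are 1-based in all I/O and documentation (theta_1..N,
V_1..M); arrays are 0-indexed internally.

The three canonical problems are implemented with per-step normalization of
the forward/backward trellises (the textbook recursions multiply T
probabilities and underflow for realistic sequence lengths); the scale
factors are accumulated in log space, so log-likelihoods are exact up to
floating point. On tiny instances, exponentiating and unscaling reproduces
the literal unscaled recursions, which is how the test suite checks them
against exhaustive path enumeration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("skelhmm.hmm")

from .quantize import ObservationSequence

#: Default smoothing floor applied to A and B rows after each re-estimation.
#: Without it, symbols unseen in training get exactly zero emission
#: probability and send every held-out sequence containing them to -inf.
DEFAULT_FLOOR = 1e-6
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100

_ROW_SUM_TOL = 1e-9


def _check_stochastic(v: np.ndarray, name: str) -> None:
    if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    sums = v.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL):
        raise ValueError(f"{name} rows must sum to 1 (got sums {sums})")


@dataclass(frozen=True)
class DiscreteHMM:
    """lambda = (pi, A, B) over N hidden states and M symbols."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        N = pi.shape[0]
        if pi.ndim != 1 or A.shape != (N, N) or B.ndim != 2 or B.shape[0] != N:
            raise ValueError(
                f"inconsistent shapes: pi {pi.shape}, A {A.shape}, B {B.shape}"
            )
        _check_stochastic(pi[None, :], "pi")
        _check_stochastic(A, "A")
        _check_stochastic(B, "B")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def N(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]

    # ---- serialization -------------------------------------------------
    def to_dict(self, metadata: dict | None = None) -> dict:
        return {
            "N": self.N,
            "M": self.M,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "metadata": metadata or {},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteHMM":
        return cls(pi=np.asarray(d["pi"]), A=np.asarray(d["A"]), B=np.asarray(d["B"]))

    def to_json(self, metadata: dict | None = None) -> str:
        return json.dumps(self.to_dict(metadata), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "DiscreteHMM":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class TrellisResult:
    """A scaled forward or backward trellis.

    ``scaled`` holds rows normalized to sum 1; ``log_scale[t]`` is the log
    of the normalizer removed at step t, so the unscaled trellis row t is
    ``scaled[t] * exp(log_scale[: t+1].sum())`` for the forward direction
    (and the suffix sum for the backward one).
    """

    kind: str  # "forward" or "backward"
    scaled: np.ndarray
    log_scale: np.ndarray
    log_likelihood: float


@dataclass(frozen=True)
class PosteriorStats:
    """State posteriors gamma[t, i] and pairwise posteriors xi[t, i, j]."""

    gamma: np.ndarray
    xi: np.ndarray


@dataclass(frozen=True)
class ViterbiResult:
    """Most probable hidden path (1-based states) and its log probability."""

    path: np.ndarray
    log_prob: float
    backpointers: np.ndarray


def _symbols0(hmm: DiscreteHMM, obs: ObservationSequence) -> np.ndarray:
    sym = obs.symbols - 1
    if sym.min() < 0 or sym.max() >= hmm.M:
        raise ValueError(
            f"observation symbols must lie in [1, {hmm.M}]; got range "
            f"[{obs.symbols.min()}, {obs.symbols.max()}]"
        )
    return sym


def forward(hmm: DiscreteHMM, obs: ObservationSequence) -> TrellisResult:
    """Scaled forward recursion.

    alpha_1(i) = pi_i b_i(O_1); alpha_{t+1}(j) = [sum_i alpha_t(i) a_ij]
    b_j(O_{t+1}); P(O|lambda) = sum_i alpha_T(i). Each row is normalized to
    sum 1 and the log normalizers accumulate into the log-likelihood. A
    sequence impossible under the model yields log-likelihood -inf.
    """
    sym = _symbols0(hmm, obs)
    T, N = sym.size, hmm.N
    scaled = np.zeros((T, N))
    log_scale = np.full(T, -np.inf)
    loglik = 0.0
    row = hmm.pi * hmm.B[:, sym[0]]
    for t in range(T):
        if t > 0:
            row = (scaled[t - 1] @ hmm.A) * hmm.B[:, sym[t]]
        c = row.sum()
        if c == 0.0:
            loglik = -np.inf
            scaled[t:] = 0.0
            break
        scaled[t] = row / c
        log_scale[t] = np.log(c)
        loglik += log_scale[t]
    return TrellisResult("forward", scaled, log_scale, float(loglik))


def backward(hmm: DiscreteHMM, obs: ObservationSequence) -> TrellisResult:
    """Scaled backward recursion.

    beta_T(i) = 1; beta_t(i) = sum_j a_ij b_j(O_{t+1}) beta_{t+1}(j) for
    t = T-1 .. 1; P(O|lambda) = sum_i pi_i b_i(O_1) beta_1(i). Rows are
    normalized to sum 1 with log normalizers recorded per step.
    """
    sym = _symbols0(hmm, obs)
    T, N = sym.size, hmm.N
    scaled = np.zeros((T, N))
    log_scale = np.full(T, -np.inf)
    suffix = 0.0
    dead = False
    for t in range(T - 1, -1, -1):
        row = (
            np.ones(N)
            if t == T - 1
            else hmm.A @ (hmm.B[:, sym[t + 1]] * scaled[t + 1])
        )
        c = row.sum()
        if c == 0.0 or dead:
            dead = True
            continue
        scaled[t] = row / c
        log_scale[t] = np.log(c)
        suffix += log_scale[t]
    term = float(hmm.pi @ (hmm.B[:, sym[0]] * scaled[0]))
    loglik = -np.inf if (dead or term == 0.0) else np.log(term) + suffix
    return TrellisResult("backward", scaled, log_scale, float(loglik))


def posteriors(
    hmm: DiscreteHMM,
    obs: ObservationSequence,
    fwd: TrellisResult | None = None,
    bwd: TrellisResult | None = None,
) -> PosteriorStats:
    """State and transition posteriors gamma_t(i), xi_t(i, j).

    gamma_t(i) = alpha_t(i) beta_t(i) / sum_j alpha_t(j) beta_t(j);
    xi_t(i, j) = alpha_t(i) a_ij b_j(O_{t+1}) beta_{t+1}(j), normalized over
    (i, j). Computed entirely from the scaled trellises: the per-step scale
    factors cancel in each normalization.
    """
    fwd = fwd if fwd is not None else forward(hmm, obs)
    bwd = bwd if bwd is not None else backward(hmm, obs)
    if fwd.kind != "forward" or bwd.kind != "backward":
        raise ValueError("posteriors needs one forward and one backward trellis")
    if fwd.scaled.shape != bwd.scaled.shape:
        raise ValueError("mismatched trellises: differing shapes")
    sym = _symbols0(hmm, obs)
    T = sym.size
    if fwd.scaled.shape[0] != T:
        raise ValueError("trellises do not match the observation sequence")
    if not np.isfinite(fwd.log_likelihood):
        raise ValueError("observation sequence impossible under the model")

    g = fwd.scaled * bwd.scaled
    gamma = g / g.sum(axis=1, keepdims=True)
    if T > 1:
        emit_next = hmm.B[:, sym[1:]].T * bwd.scaled[1:]  # (T-1, N)
        xi = fwd.scaled[:-1, :, None] * hmm.A[None] * emit_next[:, None, :]
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.zeros((0, hmm.N, hmm.N))
    return PosteriorStats(gamma=gamma, xi=xi)


def _floor_rows(rows: np.ndarray, floor: float) -> np.ndarray:
    if floor <= 0:
        return rows
    rows = np.maximum(rows, floor)
    return rows / rows.sum(axis=-1, keepdims=True)


def baum_welch(
    hmm0: DiscreteHMM,
    obs_set,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    floor: float = DEFAULT_FLOOR,
) -> tuple[DiscreteHMM, np.ndarray]:
    """Multi-sequence Baum–Welch (EM) re-estimation.

    Each iteration accumulates posteriors over all sequences and updates

    * pi_i   = mean over sequences of gamma_1(i),
    * a_ij   = sum_t xi_t(i, j) / sum_t gamma_t(i)  (t < T, summed over
      sequences),
    * b_j(k) = sum_t gamma_t(j) [O_t = V_k] / sum_t gamma_t(j),

    then floors A and B rows at ``floor`` and renormalizes. Iteration stops
    when the total log-likelihood improves by less than ``tol`` or after
    ``max_iter`` rounds.

    Returns the trained model and the per-iteration total log-likelihoods
    (evaluated at the parameters entering each iteration).
    """
    obs_set = list(obs_set)
    if not obs_set:
        raise ValueError("obs_set must contain at least one sequence")
    hmm = hmm0
    N, M = hmm0.N, hmm0.M
    history: list[float] = []

    for _ in range(max_iter):
        pi_acc = np.zeros(N)
        a_num = np.zeros((N, N))
        a_den = np.zeros(N)
        b_num = np.zeros((N, M))
        b_den = np.zeros(N)
        total = 0.0
        for obs in obs_set:
            fwd = forward(hmm, obs)
            if not np.isfinite(fwd.log_likelihood):
                raise ValueError(
                    "a training sequence has zero probability under the "
                    "current model; use a nonzero smoothing floor or a "
                    "broader initialization"
                )
            bwd = backward(hmm, obs)
            post = posteriors(hmm, obs, fwd, bwd)
            total += fwd.log_likelihood
            sym = obs.symbols - 1
            pi_acc += post.gamma[0]
            if post.xi.shape[0] > 0:
                a_num += post.xi.sum(axis=0)
                a_den += post.gamma[:-1].sum(axis=0)
            np.add.at(b_num.T, sym, post.gamma)
            b_den += post.gamma.sum(axis=0)
        history.append(total)
        logger.debug("baum_welch iter %d: log-likelihood %.6f", len(history), total)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
            break

        pi = pi_acc / pi_acc.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(a_den[:, None] > 0, a_num / np.where(a_den > 0, a_den, 1.0)[:, None], hmm.A)
            B = b_num / np.where(b_den > 0, b_den, 1.0)[:, None]
            B = np.where(b_den[:, None] > 0, B, hmm.B)
        A = _floor_rows(A, floor)
        B = _floor_rows(B, floor)
        hmm = DiscreteHMM(pi=pi, A=A, B=B)

    return hmm, np.asarray(history)


def viterbi(hmm: DiscreteHMM, obs: ObservationSequence) -> ViterbiResult:
    """Most probable hidden-state path by max-product dynamic programming.

    delta_1(i) = pi_i b_i(O_1); delta_t(j) = max_i delta_{t-1}(i) a_ij *
    b_j(O_t) with backpointers phi_t(j) = argmax_i; the path is recovered by
    backtracking from argmax_i delta_T(i). Computed in log space; all argmax
    ties resolve to the lowest state index. Returned states are 1-based.
    """
    sym = _symbols0(hmm, obs)
    T, N = sym.size, hmm.N
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.pi)
        log_A = np.log(hmm.A)
        log_B = np.log(hmm.B)
    delta = np.zeros((T, N))
    phi = np.zeros((T, N), dtype=int)
    delta[0] = log_pi + log_B[:, sym[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_A  # cand[i, j]
        phi[t] = np.argmax(cand, axis=0)  # first (lowest) index on ties
        delta[t] = cand[phi[t], np.arange(N)] + log_B[:, sym[t]]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = phi[t + 1][path[t + 1]]
    return ViterbiResult(
        path=path + 1,
        log_prob=float(delta[-1].max()),
        backpointers=phi,
    )


def sample(
    hmm: DiscreteHMM, T: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, ObservationSequence]:
    """Ancestral sampling of (state path, observations), both 1-based."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.zeros(T, dtype=int)
    symbols = np.zeros(T, dtype=int)
    s = rng.choice(hmm.N, p=hmm.pi)
    for t in range(T):
        if t > 0:
            s = rng.choice(hmm.N, p=hmm.A[s])
        states[t] = s
        symbols[t] = rng.choice(hmm.M, p=hmm.B[s])
    return states + 1, ObservationSequence(symbols=symbols + 1)


def random_hmm(N: int, M: int, seed: int | np.random.Generator) -> DiscreteHMM:
    """Dirichlet(1)-distributed random model; handy for tests and inits."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(N))
    A = rng.dirichlet(np.ones(N), size=N)
    B = rng.dirichlet(np.ones(M), size=N)
    return DiscreteHMM(pi=pi, A=A, B=B)
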