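"""Independent brute-force oracles for tiny HMM instances.

These enumerate all N^T hidden-state paths directly from the model
definition and never touch the dynamic-programming implementations they
check.
"""

from itertools import product

import numpy as np


def _path_prob(hmm, path, sym0):
    p = hmm.pi[path[0]] * hmm.B[path[0], sym0[0]]
    for t in range(1, len(sym0)):
        p *= hmm.A[path[t - 1], path[t]] * hmm.B[path[t], sym0[t]]
    return p


def enum_likelihood(hmm, obs) -> float:
    """P(O | lambda) by summing over every hidden path."""
    sym0 = obs.symbols - 1
    return sum(
        _path_prob(hmm, path, sym0)
        for path in product(range(hmm.N), repeat=len(sym0))
    )


def enum_gamma(hmm, obs) -> np.ndarray:
    """State posteriors gamma[t, i] by path enumeration."""
    sym0 = obs.symbols - 1
    T = len(sym0)
    g = np.zeros((T, hmm.N))
    total = 0.0
    for path in product(range(hmm.N), repeat=T):
        p = _path_prob(hmm, path, sym0)
        total += p
        for t, s in enumerate(path):
            g[t, s] += p
    return g / total


def enum_viterbi(hmm, obs):
    """(best path 1-based, best path probability) by enumeration; ties
    resolve to the lexicographically smallest path."""
    sym0 = obs.symbols - 1
    best_p, best_path = -1.0, None
    for path in product(range(hmm.N), repeat=len(sym0)):
        p = _path_prob(hmm, path, sym0)
        if p > best_p:
            best_p, best_path = p, path
    return np.asarray(best_path) + 1, best_p
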