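import numpy as np
import pytest

from skelhmm import DiscreteHMM, MotionSequence
from skelhmm.skeleton import N_JOINTS


@pytest.fixture
def det_hmm():
    """Deterministic 2-state 2-symbol HMM: pi=(1,0), A=I, B=I."""
    return DiscreteHMM(pi=[1.0, 0.0], A=np.eye(2), B=np.eye(2))


@pytest.fixture
def uniform_hmm():
    """Fully uniform 2-state 2-symbol HMM."""
    return DiscreteHMM(pi=[0.5, 0.5], A=np.full((2, 2), 0.5), B=np.full((2, 2), 0.5))


def make_sequence(positions, **kw) -> MotionSequence:
    """Build a MotionSequence from a (T, 25, 3) array (or broadcastable)."""
    pos = np.asarray(positions, dtype=float)
    return MotionSequence(positions=pos, **kw)


@pytest.fixture
def still_pose():
    """A static, non-degenerate skeleton pose (25, 3): every joint distinct."""
    rng = np.random.default_rng(0)
    return rng.uniform(-500, 500, size=(N_JOINTS, 3)) + np.array([0, 1000, 2500])
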