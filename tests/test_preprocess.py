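import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skelhmm import (
    FilterParams,
    MotionSequence,
    extract_keyframes,
    limit_filter,
    reconstruct,
    reconstruction_error,
)
from skelhmm.skeleton import N_JOINTS

from conftest import make_sequence


def _static(pose, T):
    return make_sequence(np.broadcast_to(pose, (T, N_JOINTS, 3)).copy())


class TestLimitFilter:
    def test_constant_sequence_unchanged(self, still_pose):
        seq = _static(still_pose, 10)
        out = limit_filter(seq, FilterParams(5, 50))
        np.testing.assert_allclose(out.positions, seq.positions)

    def test_spike_clamped_to_deviation_radius(self, still_pose):
        seq = _static(still_pose, 10)
        pos = seq.positions.copy()
        pos[5, 3] += np.array([100.0, 0, 0])  # 100 mm spike on one joint
        out = limit_filter(make_sequence(pos), FilterParams(jitter_radius=2, deviation_radius=20))
        step = np.linalg.norm(out.positions[5, 3] - out.positions[4, 3])
        assert step <= 20 + 1e-9

    def test_small_oscillation_suppressed(self, still_pose):
        T = 20
        pos = np.broadcast_to(still_pose, (T, N_JOINTS, 3)).copy()
        pos[:, 7, 0] += 2.0 * (-1) ** np.arange(T)  # +/-2 mm flicker
        out = limit_filter(make_sequence(pos), FilterParams(jitter_radius=5, deviation_radius=50))
        traj = out.positions[1:, 7]
        assert np.ptp(traj, axis=0).max() == 0.0  # constant after frame 1

    def test_intermediate_motion_passes_through(self, still_pose):
        T = 10
        pos = np.broadcast_to(still_pose, (T, N_JOINTS, 3)).copy()
        pos[:, 7, 0] += 20.0 * np.arange(T)  # 20 mm/frame, between radii
        out = limit_filter(make_sequence(pos), FilterParams(5, 50))
        np.testing.assert_allclose(out.positions, pos)

    def test_untracked_samples_carried_forward(self, still_pose):
        T = 6
        pos = np.broadcast_to(still_pose, (T, N_JOINTS, 3)).copy()
        pos[:, 2, 1] += 20.0 * np.arange(T)
        tracked = np.ones((T, N_JOINTS), dtype=bool)
        tracked[3, 2] = False
        pos[3, 2] = np.array([9e5, 9e5, 9e5])  # garbage while untracked
        out = limit_filter(MotionSequence(positions=pos, tracked=tracked), FilterParams(5, 50))
        np.testing.assert_allclose(out.positions[3, 2], out.positions[2, 2])

    def test_fully_untracked_joint_errors(self, still_pose):
        T = 4
        tracked = np.ones((T, N_JOINTS), dtype=bool)
        tracked[:, 10] = False
        seq = MotionSequence(
            positions=np.broadcast_to(still_pose, (T, N_JOINTS, 3)).copy(),
            tracked=tracked,
        )
        with pytest.raises(ValueError, match="never tracked"):
            limit_filter(seq, FilterParams(5, 50))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), jitter=st.floats(0, 10), span=st.floats(1, 200))
    def test_step_bound_and_causality(self, seed, jitter, span):
        """Filtered frame-to-frame displacement never exceeds the deviation
        radius, and output at t is unchanged by future inputs."""
        rng = np.random.default_rng(seed)
        pose = np.random.default_rng(0).uniform(-500, 500, size=(N_JOINTS, 3))
        T = 15
        deviation = jitter + span
        pos = pose + rng.normal(0, 40, size=(T, N_JOINTS, 3))
        out = limit_filter(make_sequence(pos), FilterParams(jitter, deviation))
        steps = np.linalg.norm(np.diff(out.positions, axis=0), axis=2)
        assert steps.max() <= deviation + 1e-9
        cut = 8
        head = limit_filter(make_sequence(pos[:cut]), FilterParams(jitter, deviation))
        np.testing.assert_allclose(head.positions, out.positions[:cut])


class TestKeyframes:
    def test_linear_motion_keeps_only_endpoints(self, still_pose):
        T = 30
        drift = np.linspace(0, 300, T)[:, None, None] * np.array([1.0, 0, 0])
        seq = make_sequence(still_pose + drift)
        res = extract_keyframes(seq, max_error=1.0)
        np.testing.assert_array_equal(res.indices, [0, T - 1])
        assert res.compression_ratio == pytest.approx(T / 2)
        assert res.max_error <= 1e-9

    def test_zero_budget_on_noise_keeps_all_frames(self, still_pose):
        rng = np.random.default_rng(1)
        seq = make_sequence(still_pose + rng.normal(0, 5, size=(12, N_JOINTS, 3)))
        res = extract_keyframes(seq, max_error=0.0)
        np.testing.assert_array_equal(res.indices, np.arange(12))
        assert res.compression_ratio == 1.0

    def test_random_walk_respects_budget_frame_by_frame(self, still_pose):
        rng = np.random.default_rng(2)
        walk = np.cumsum(rng.normal(0, 4, size=(60, N_JOINTS, 3)), axis=0)
        seq = make_sequence(still_pose + walk)
        res = extract_keyframes(seq, max_error=10.0)
        # independent replay of the interpolation
        assert reconstruction_error(res, seq) <= 10.0 + 1e-9
        assert res.max_error == pytest.approx(reconstruction_error(res, seq))
        assert res.indices[0] == 0 and res.indices[-1] == len(seq) - 1

    def test_compression_monotone_in_budget(self, still_pose):
        rng = np.random.default_rng(3)
        t = np.arange(80) / 30
        pos = still_pose + 200 * np.sin(2 * np.pi * 0.4 * t)[:, None, None]
        seq = make_sequence(pos + rng.normal(0, 1, size=pos.shape))
        ratios = [
            extract_keyframes(seq, budget).compression_ratio
            for budget in (1.0, 3.0, 10.0, 30.0)
        ]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_single_frame_errors(self, still_pose):
        with pytest.raises(ValueError, match=">= 2 frames"):
            extract_keyframes(_static(still_pose, 1), 5.0)
        with pytest.raises(ValueError, match="max_error"):
            extract_keyframes(_static(still_pose, 5), -1.0)


class TestReconstruct:
    def test_all_indices_is_identity(self, still_pose):
        rng = np.random.default_rng(4)
        seq = make_sequence(still_pose + rng.normal(0, 10, size=(9, N_JOINTS, 3)))
        res = extract_keyframes(seq, 0.0)
        out = reconstruct(res, seq)
        np.testing.assert_allclose(out.positions, seq.positions)

    def test_endpoints_of_linear_motion_reconstruct_exactly(self, still_pose):
        T = 16
        drift = np.linspace(0, 100, T)[:, None, None] * np.array([0, 1.0, 0])
        seq = make_sequence(still_pose + drift)
        res = extract_keyframes(seq, 0.5)
        out = reconstruct(res, seq)
        np.testing.assert_allclose(out.positions, seq.positions, atol=1e-9)

    def test_empty_indices_rejected(self, still_pose):
        from skelhmm.preprocess import KeyframeResult

        with pytest.raises(ValueError):
            KeyframeResult(indices=np.array([]), max_error=0, compression_ratio=1)
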