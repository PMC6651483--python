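"""Gravity filtering, vertical projection, and shake synchronization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from actinovelty.preprocessing import (
    PreprocessingError,
    SyncParams,
    TriaxialTrace,
    VerticalSignal,
    decompose,
    detect_shake_end,
    estimate_gravity,
    synchronize,
    vertical_projection,
)


def _trace(samples, sensor_id="lf", rate=10.0):
    return TriaxialTrace(sensor_id=sensor_id, rate_hz=rate, samples=samples)


class TestGravityEstimate:
    def test_constant_trace_is_fixed_point(self):
        trace = _trace(np.tile([0.0, 0.0, 1.0], (100, 1)))
        g = estimate_gravity(trace, 20)
        assert np.allclose(g.vectors, [0.0, 0.0, 1.0])

    def test_alternating_noise_attenuation(self):
        """Zero-mean +/-eps alternation with period 2: the interior mean over
        an odd 21-sample window is eps/21 at most (direct summation oracle)."""
        eps = 0.3
        n = 100
        samples = np.tile([0.0, 0.0, 1.0], (n, 1))
        samples[:, 0] += eps * (-1.0) ** np.arange(n)
        g = estimate_gravity(_trace(samples), 20)
        interior = g.vectors[10 : n - 10]
        # oracle: direct window sums
        for i in (20, 43, 77):
            expected = samples[i - 10 : i + 11].mean(axis=0)
            assert np.allclose(g.vectors[i], expected)
        assert np.abs(interior[:, 0]).max() <= eps / 21 + 1e-12
        assert np.allclose(interior[:, 2], 1.0)

    def test_boundary_window_truncation(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(size=(50, 3)) * 0.1 + [0, 0, 1]
        g = estimate_gravity(_trace(samples), 20)
        assert np.allclose(g.vectors[0], samples[:11].mean(axis=0))
        assert np.allclose(g.vectors[-1], samples[-11:].mean(axis=0))

    def test_rejects_short_trace_and_odd_window(self):
        trace = _trace(np.tile([0.0, 0.0, 1.0], (15, 1)))
        with pytest.raises(PreprocessingError):
            estimate_gravity(trace, 20)
        with pytest.raises(PreprocessingError):
            estimate_gravity(trace, 7)


class TestVerticalProjection:
    def test_orthogonal_movement_projects_to_zero(self):
        n = 60
        samples = np.tile([0.0, 0.0, 1.0], (n, 1))
        samples[:, 0] += 0.4 * (-1.0) ** np.arange(n)  # x, orthogonal to z
        from actinovelty.preprocessing import GravityEstimate

        gravity = GravityEstimate(np.tile([0.0, 0.0, 1.0], (n, 1)), 20)
        av = vertical_projection(_trace(samples), gravity).values
        assert np.abs(av).max() < 1e-12

    def test_parallel_offset_recovered(self):
        n = 40
        samples = np.tile([0.0, 0.0, 1.5], (n, 1))
        from actinovelty.preprocessing import GravityEstimate

        gravity = GravityEstimate(np.tile([0.0, 0.0, 1.0], (n, 1)), 20)
        av = vertical_projection(_trace(samples), gravity).values
        assert np.allclose(av, 0.5)

    def test_degenerate_gravity_names_index(self):
        n = 40
        from actinovelty.preprocessing import GravityEstimate

        vecs = np.tile([0.0, 0.0, 1.0], (n, 1))
        vecs[17] = 0.0
        gravity = GravityEstimate(vecs, 20)
        with pytest.raises(PreprocessingError, match="17"):
            vertical_projection(_trace(np.zeros((n, 3))), gravity)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_orientation_invariance(self, seed):
        """av is unchanged (to 1e-9) under any fixed rotation of the trace."""
        rng = np.random.default_rng(seed)
        n = 120
        t = np.arange(n)
        world = np.column_stack(
            [
                0.2 * np.sin(2 * np.pi * t / 13),
                0.1 * np.cos(2 * np.pi * t / 17),
                1.0 + 0.5 * np.sin(2 * np.pi * t / 21),
            ]
        )
        rot = Rotation.from_quat(rng.normal(size=4))
        a = _trace(world)
        b = _trace(rot.apply(world))
        av_a = vertical_projection(a, estimate_gravity(a, 20)).values
        av_b = vertical_projection(b, estimate_gravity(b, 20)).values
        assert np.abs(av_a - av_b).max() < 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_decomposition_orthogonality(self, seed):
        """am = amv + amh with amv . amh = 0 at every sample."""
        rng = np.random.default_rng(seed)
        samples = rng.normal(scale=0.3, size=(80, 3)) + [0, 0, 1]
        trace = _trace(samples)
        gravity = estimate_gravity(trace, 20)
        amv, amh = decompose(trace, gravity)
        assert np.allclose(amv + amh, samples - gravity.vectors, atol=1e-12)
        assert np.abs(np.einsum("ij,ij->i", amv, amh)).max() < 1e-9


def _vs(values, sensor_id="lf"):
    return VerticalSignal(sensor_id=sensor_id, rate_hz=10.0, values=np.asarray(values, float))


class TestShakeDetection:
    def test_burst_with_lead_in(self):
        av = np.r_[np.full(50, 0.1), np.full(30, 3.0), np.full(20, 0.05)]
        assert detect_shake_end(_vs(av), SyncParams()) == 80

    def test_no_shake_detected(self):
        with pytest.raises(PreprocessingError, match="no shake"):
            detect_shake_end(_vs(np.full(100, 0.1)), SyncParams(th1=2.0))

    def test_burst_at_origin(self):
        av = np.r_[np.full(30, 3.0) * (-1.0) ** np.arange(30), np.full(40, 0.02)]
        assert detect_shake_end(_vs(av), SyncParams()) == 30

    def test_burst_never_ends(self):
        av = np.r_[np.full(10, 0.1), np.full(90, 3.0)]
        with pytest.raises(PreprocessingError, match="never ends"):
            detect_shake_end(_vs(av), SyncParams())

    def test_linear_scan_oracle(self):
        """Against a naive per-index scan of the detection conditions."""
        rng = np.random.default_rng(3)
        p = SyncParams()
        for _ in range(20):
            off = rng.integers(0, 40)
            quiet = rng.uniform(0, 0.3, size=200)
            av = np.r_[quiet[:off], 3.0 * (-1.0) ** np.arange(30), quiet[off:]]
            k = detect_shake_end(_vs(av), p)
            absav = np.abs(av)
            expected = None
            first_hit = int(np.argmax(absav >= p.th1))
            for i in range(first_hit + 1, len(av) - p.n_sync):
                w = absav[i : i + p.n_sync + 1]
                if w.mean() <= p.th2 and w.max() < p.th1:
                    expected = i
                    break
            assert k == expected


class TestSynchronize:
    @staticmethod
    def _planted(offsets, seed=0, content_n=200):
        rng = np.random.default_rng(seed)
        content = rng.uniform(-0.3, 0.3, size=content_n)
        burst = 3.0 * (-1.0) ** np.arange(30)
        signals = {}
        for sid, off in zip(("lf", "lh", "rf", "rh"), offsets):
            av = np.r_[np.zeros(off), burst, np.zeros(10), content]
            signals[sid] = _vs(av, sid)
        return signals

    def test_planted_offsets_realign(self):
        signals = self._planted((0, 5, 10, 15))
        rec = synchronize(signals, SyncParams())
        for c in range(1, 4):
            assert np.array_equal(rec.data[:, 0], rec.data[:, c])

    def test_identical_signals_trivial(self):
        signals = self._planted((3, 3, 3, 3), seed=1)
        rec = synchronize(signals, SyncParams())
        tail = signals["lf"].values[33:]
        assert np.array_equal(rec.data[:, 0], tail[: len(rec)])

    def test_failing_channel_names_sensor(self):
        signals = self._planted((0, 5, 10, 15))
        signals["rf"] = _vs(np.full(100, 0.1), "rf")
        with pytest.raises(PreprocessingError, match="rf"):
            synchronize(signals, SyncParams())

    def test_hundred_random_planted_offsets(self):
        """Post-sync misalignment <= 1 sample over 100 random offset draws."""
        rng = np.random.default_rng(12)
        for trial in range(100):
            offsets = rng.integers(0, 30, size=4)
            signals = self._planted(tuple(offsets), seed=trial)
            rec = synchronize(signals, SyncParams())
            residual = [rec.origins[sid] - off for sid, off in
                        zip(("lf", "lh", "rf", "rh"), offsets)]
            assert max(residual) - min(residual) <= 1
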