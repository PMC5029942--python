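"""Steady-state cascade dynamics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texshape.cascade import (CascadeParams, feedback_signal, inhibitory_pool,
                              rect, run_stage, steady_state)


@pytest.fixture
def params():
    return CascadeParams(beta=2.0, xi=0.8, eta=0.0, alpha=0.5, gamma=1.0,
                         delta=0.3, epsilon=0.5, lambda_fb=1.0, pool_sigma=1.5,
                         fb_radius=2)


def pool_oracle(r, p):
    """Direct two-loop evaluation of the inhibitory pool."""
    H, W, T, F = r.shape
    feat_max = r.max(axis=(2, 3))
    from scipy.ndimage import gaussian_filter
    spatial = gaussian_filter(feat_max, p.pool_sigma, mode="reflect", truncate=3.0)
    q = np.empty_like(r)
    for y in range(H):
        for x in range(W):
            s = r[y, x].sum()
            for t in range(T):
                for f in range(F):
                    q[y, x, t, f] = p.delta * (s + p.epsilon * spatial[y, x])
    return q


class TestRect:
    @pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (0.0, 0.0), (2.5, 2.5)])
    def test_scalar_values(self, x, expected):
        assert rect(np.array(x)) == expected


class TestInhibitoryPool:
    def test_zero_input_zero_pool(self, params):
        assert np.all(inhibitory_pool(np.zeros((4, 4, 2, 2)), params) == 0)

    def test_single_unit_without_spatial_term(self, params):
        p = params.replace(epsilon=0.0, delta=0.7)
        r = np.zeros((5, 5, 3, 2)); r[2, 3, 1, 0] = 1.0
        q = inhibitory_pool(r, p)
        assert np.allclose(q[2, 3], 0.7)       # all features at that location
        q[2, 3] = 0.0
        assert np.all(q == 0)

    def test_matches_brute_force_on_random_stack(self, params, rng):
        r = rng.random((8, 8, 4, 2))
        assert np.allclose(inhibitory_pool(r, params), pool_oracle(r, params),
                           atol=1e-10)


class TestFeedbackSignal:
    def test_zero_higher_activity_gives_zero(self, params):
        own = np.random.default_rng(0).random((6, 6, 2, 2))
        assert np.all(feedback_signal(own, np.zeros_like(own), params) == 0)

    def test_gate_closes_at_lambda(self, params):
        own = np.full((6, 6, 2, 2), params.lambda_fb + 0.5)
        higher = np.ones_like(own)
        assert np.all(feedback_signal(own, higher, params) == 0)

    def test_matches_brute_force(self, params, rng):
        own = rng.random((6, 6, 2, 2))
        higher = rng.random((6, 6, 2, 2))
        net = feedback_signal(own, higher, params)
        R = params.fb_radius
        H, W = 6, 6
        for y, x, t, f in [(0, 0, 0, 0), (3, 2, 1, 1), (5, 5, 0, 1)]:
            acc, cnt = 0.0, 0
            for dy in range(-R, R + 1):
                for dx in range(-R, R + 1):
                    yy = min(max(0, y + dy), H - 1) if not (0 <= y + dy < H) else y + dy
                    # reflect padding of uniform_filter
                    yy = y + dy
                    xx = x + dx
                    yy = -yy - 1 if yy < 0 else (2 * H - yy - 1 if yy >= H else yy)
                    xx = -xx - 1 if xx < 0 else (2 * W - xx - 1 if xx >= W else xx)
                    acc += higher[yy, xx, t, f]; cnt += 1
            expected = max(params.lambda_fb - own[y, x, t, f], 0.0) \
                * params.fb_gain * acc / cnt
            assert np.isclose(net[y, x, t, f], expected, atol=1e-10)

    def test_grid_mismatch_rejected(self, params):
        with pytest.raises(ValueError, match="mismatch"):
            feedback_signal(np.zeros((4, 4, 2, 2)), np.zeros((4, 4, 3, 2)), params)


class TestSteadyState:
    def test_matches_scalar_oracle(self, params, rng):
        drive = rng.random((5, 5, 2, 2)) * 3
        net = rng.random((5, 5, 2, 2))
        q = rng.random((5, 5, 2, 2))
        r = steady_state(drive, net, q, params)
        it = np.nditer(drive, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            d, n, qq = drive[idx], net[idx], q[idx]
            expected = max((params.beta * d * (1 + n) - params.xi * qq + params.eta)
                           / (params.alpha + params.gamma * d * (1 + n) + qq), 0.0)
            assert np.isclose(r[idx], expected, atol=1e-12)

    def test_saturates_at_beta_over_gamma(self, params):
        """Response approaches beta/gamma within 1% under very large drive."""
        q = np.array([[[[0.7]]]])
        drive = np.full_like(q, 1e4 * max(params.alpha, float(q.max())))
        r = steady_state(drive, 0.0, q, params)
        assert abs(r[0, 0, 0, 0] - params.beta / params.gamma) \
            < 0.01 * params.beta / params.gamma

    def test_zero_drive_zero_eta_rectifies_to_zero(self, params):
        r = steady_state(np.zeros((3, 3, 2, 2)), 0.0, 0.5, params)
        assert np.all(r == 0)

    @settings(max_examples=50, deadline=None)
    @given(d=st.floats(0, 1e3), q=st.floats(0, 1e2), n=st.floats(0, 1e2))
    def test_bounded_above_and_below(self, d, q, n):
        p = CascadeParams()
        r = float(steady_state(np.array(d), n, q, p))
        assert 0.0 <= r <= p.bound + 1e-9

    def test_monotone_in_drive(self, params):
        drives = np.linspace(0, 20, 50)
        rs = [float(steady_state(np.array(d), 0.3, 0.4, params)) for d in drives]
        assert all(a <= b + 1e-12 for a, b in zip(rs, rs[1:]))


class TestRunStage:
    def test_single_cycle_is_pure_feedforward(self, params, rng):
        drive = rng.random((6, 6, 2, 2))
        r = run_stage(drive, params, n_cycles=1)
        assert np.allclose(r, steady_state(drive, 0.0, 0.0, params))

    def test_zero_input_zero_output(self, params):
        assert np.all(run_stage(np.zeros((6, 6, 2, 2)), params, n_cycles=3) == 0)

    def test_scaling_beta_gamma_together_keeps_bound(self, params, rng):
        drive = rng.random((4, 4, 2, 2)) * 1e6
        r1 = run_stage(drive, params, n_cycles=1)
        p2 = params.replace(beta=2 * params.beta, gamma=2 * params.gamma)
        r2 = run_stage(drive, p2, n_cycles=1)
        assert np.isclose(r1.max(), r2.max(), rtol=1e-3)
        assert r1.max() < params.beta / params.gamma

    def test_output_within_bound(self, params, rng):
        drive = rng.random((8, 8, 3, 2)) * 100
        r = run_stage(drive, params, n_cycles=3)
        assert np.all(r >= 0) and np.all(r <= params.bound + 1e-9)

    def test_normalization_preserves_strong_over_weak(self):
        """With a shared pool, the strong/weak response ratio is at least the
        drive ratio (winner enhancement)."""
        p = CascadeParams(beta=2.0, xi=1.0, alpha=1.0, gamma=1.0, delta=0.3,
                          epsilon=0.0, pool_sigma=1.0)
        drive = np.zeros((1, 1, 2, 1))
        drive[0, 0, 0, 0], drive[0, 0, 1, 0] = 1.0, 0.4
        r = run_stage(drive, p, n_cycles=4)
        assert r[0, 0, 0, 0] / r[0, 0, 1, 0] >= 1.0 / 0.4

    def test_invalid_cycle_count(self, params):
        with pytest.raises(ValueError):
            run_stage(np.zeros((4, 4, 2, 2)), params, n_cycles=0)
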