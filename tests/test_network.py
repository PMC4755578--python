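"""Unit tests for the nonlinearity, fixed-point solver and integrator."""

import numpy as np
import pytest

from infomaxnet import (
    DivergentDynamicsError,
    NetworkParams,
    integrate_dynamics,
    logistic_eval,
    solve_fixed_point,
    solve_fixed_point_batch,
)
from infomaxnet.network import LOGISTIC
from infomaxnet.ring import build_ring, cosine_interaction, ring_angles
from infomaxnet.metrics import population_vector

from conftest import random_subcritical_network


class TestLogistic:
    @pytest.mark.parametrize("u,value,d1,d2", [
        (0.0, 0.5, 0.25, 0.0),
        (np.log(3), 0.75, 0.1875, -0.09375),   # g=3/4: g'=3/16, g''=g'(1-2g)
    ])
    def test_closed_form_values(self, u, value, d1, d2):
        v, g1, g2 = logistic_eval(u)
        assert v == pytest.approx(value)
        assert g1 == pytest.approx(d1)
        assert g2 == pytest.approx(d2)

    def test_gain_at_zero_is_one_quarter(self):
        assert LOGISTIC.gamma0 == 0.25
        assert LOGISTIC.deriv1(0.0) == pytest.approx(0.25)

    def test_derivatives_match_finite_differences(self):
        u = np.linspace(-6, 6, 25)
        h = 1e-6
        v, g1, g2 = logistic_eval(u)
        fd1 = (logistic_eval(u + h)[0] - logistic_eval(u - h)[0]) / (2 * h)
        fd2 = (logistic_eval(u + h)[1] - logistic_eval(u - h)[1]) / (2 * h)
        assert np.allclose(g1, fd1, atol=1e-8)
        assert np.allclose(g2, fd2, atol=1e-8)

    def test_saturates_gracefully(self):
        v, g1, g2 = logistic_eval(np.array([-800.0, 800.0]))
        assert np.all(np.isfinite([v, g1, g2]))
        assert v[0] == pytest.approx(0.0)
        assert v[1] == pytest.approx(1.0)


class TestFixedPoint:
    def test_no_recurrence_zero_input_gives_half(self):
        p = NetworkParams(W=np.ones((4, 2)), K=np.zeros((4, 4)))
        fp = solve_fixed_point(p, np.zeros(2))
        assert fp.converged
        assert np.allclose(fp.s, 0.5)

    def test_no_recurrence_is_pure_feedforward(self, rng):
        p = NetworkParams(W=rng.standard_normal((6, 3)),
                          K=np.zeros((6, 6)))
        x = rng.standard_normal(3)
        fp = solve_fixed_point(p, x, tol=1e-12)
        assert np.allclose(fp.s, LOGISTIC.eval(p.W @ x), atol=1e-10)

    def test_residual_on_random_subcritical_networks(self, rng):
        tol = 1e-9
        for _ in range(20):
            M = int(rng.integers(3, 11))
            p = random_subcritical_network(rng, M=M, N=2)
            x = rng.standard_normal(2)
            fp = solve_fixed_point(p, x, tol=tol)
            assert fp.converged
            resid = np.abs(fp.s - LOGISTIC.eval(fp.net_input))
            assert resid.max() <= 10 * tol
            assert np.all((fp.s > 0) & (fp.s < 1))

    def test_supercritical_ring_forms_hill(self):
        M = 41
        p = build_ring(M).with_K(cosine_interaction(M, 8.8))  # 10% above k1c
        fp = solve_fixed_point(p, np.zeros(2), tol=1e-10,
                               noise_scale=1e-6, seed=7, max_iter=100_000)
        pv = population_vector(fp.s, ring_angles(M))
        assert pv.magnitude > 0.1 * M * fp.s.max()

    def test_batch_solver_matches_single(self, rng):
        p = random_subcritical_network(rng, M=7, N=3)
        X = rng.standard_normal((5, 3))
        S, U, iters, done, deltas = solve_fixed_point_batch(p, X, tol=1e-11)
        assert np.all(deltas < 1e-11)
        assert done.all()
        for b in range(5):
            fp = solve_fixed_point(p, X[b], tol=1e-11)
            assert np.allclose(S[b], fp.s, atol=1e-9)

    def test_nonconvergence_reported_not_raised(self):
        p = NetworkParams(W=np.ones((3, 2)), K=np.zeros((3, 3)))
        fp = solve_fixed_point(p, np.ones(2), tol=1e-14, max_iter=3)
        assert not fp.converged
        assert fp.iterations == 3

    def test_invalid_inputs_rejected(self):
        p = NetworkParams(W=np.ones((3, 2)), K=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            solve_fixed_point(p, np.zeros(2), tol=-1.0)
        with pytest.raises(ValueError):
            solve_fixed_point(p, np.array([np.inf, 0.0]))


class TestIntegration:
    def test_stationary_at_fixed_point(self, rng):
        p = random_subcritical_network(rng, M=5, N=2)
        x = rng.standard_normal(2)
        fp = solve_fixed_point(p, x, tol=1e-13)
        _, traj = integrate_dynamics(p, x, duration=5.0, dt=0.01, init=fp.s)
        assert np.max(np.abs(traj - fp.s)) < 1e-8

    def test_exponential_relaxation_matches_linear_ode(self):
        # K=0, scalar-ish case: tau ds/dt = -s + g(w x); closed form is
        # s(t) = g + (s0 - g) exp(-t/tau)
        p = NetworkParams(W=np.array([[1.0]]), K=np.zeros((1, 1)), tau=1.0)
        x = np.array([0.7])
        target = LOGISTIC.eval(0.7)
        times, traj = integrate_dynamics(p, x, duration=4.0, dt=1e-3,
                                         init=np.array([0.1]))
        expected = target + (0.1 - target) * np.exp(-times)
        assert np.max(np.abs(traj[:, 0] - expected)) < 5e-4  # dt-order error

    def test_long_integration_agrees_with_solver(self, rng):
        tol = 1e-9
        for _ in range(20):
            M = int(rng.integers(3, 11))
            p = random_subcritical_network(rng, M=M, N=2)
            x = rng.standard_normal(2)
            fp = solve_fixed_point(p, x, tol=tol)
            _, traj = integrate_dynamics(p, x, duration=60.0, dt=0.1)
            assert np.max(np.abs(traj[-1] - fp.s)) <= 10 * tol

    def test_unstable_step_size_rejected(self):
        p = NetworkParams(W=np.ones((3, 2)), K=np.zeros((3, 3)), tau=1.0)
        with pytest.raises(ValueError):
            integrate_dynamics(p, np.zeros(2), duration=1.0, dt=1.0)


class TestParamsValidationAndIO:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            NetworkParams(W=np.ones((3, 2)), K=np.ones((2, 2)))
        with pytest.raises(ValueError):
            NetworkParams(W=np.ones((2, 3)), K=np.ones((2, 2)))  # M < N
        with pytest.raises(ValueError):
            NetworkParams(W=np.full((3, 2), np.nan), K=np.zeros((3, 3)))

    def test_roundtrip_is_bit_faithful(self, rng, tmp_path):
        p = random_subcritical_network(rng, M=6, N=3)
        p.save(tmp_path / "net")
        q = NetworkParams.load(tmp_path / "net")
        assert np.array_equal(p.W, q.W)
        assert np.array_equal(p.K, q.K)
        assert q.tau == p.tau
        assert q.nonlinearity.name == "logistic"
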