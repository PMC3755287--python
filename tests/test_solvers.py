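import numpy as np
import pytest

from sgpdeconv.forward_model import ImagingOperator
from sgpdeconv.objectives import Objective
from sgpdeconv.psf import PSFKernel
from sgpdeconv.solvers import (
    NonDescentError,
    SGPConfig,
    alternate_steplength,
    armijo_backtrack,
    bb_steps,
    default_x0,
    rl_deconvolve,
    rl_step,
    scaling_matrix,
    sgp_deconvolve,
)
from tests.conftest import make_noisy_problem


class TestRLStep:
    def test_identity_operator_one_step(self, delta_kernel_2d):
        op = ImagingOperator.from_kernel(delta_kernel_2d, (1, 1))
        x1 = rl_step(op, np.array([[6.0]]), np.array([[3.0]]))
        assert x1[0, 0] == pytest.approx(6.0, rel=1e-12)

    def test_noiseless_fixed_point(self, small_gaussian_kernel):
        op = ImagingOperator.from_kernel(small_gaussian_kernel, (16, 16))
        rng = np.random.default_rng(0)
        truth = rng.uniform(0.5, 2.0, size=(16, 16))
        y = op.convolve(truth)
        x1 = rl_step(op, y, truth)
        np.testing.assert_allclose(x1, truth, rtol=1e-10)

    def test_two_pixel_averaging_kernel(self):
        kernel = PSFKernel(np.array([0.5, 0.5]), (20.0,), "sum_to_one")
        op = ImagingOperator.from_kernel(kernel, (2,))
        x1 = rl_step(op, np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(x1, [1.0, 1.0], rtol=1e-12)


class TestScalingMatrix:
    def test_interior_value(self):
        d = scaling_matrix(np.array([0.5]), np.ones(1), 0.0, np.zeros(1), 0.1, 10.0)
        assert d[0] == pytest.approx(0.5)

    def test_upper_clip(self):
        d = scaling_matrix(np.array([20.0]), np.ones(1), 0.0, np.zeros(1), 0.1, 10.0)
        assert d[0] == 10.0

    def test_tikhonov_scaling(self):
        d = scaling_matrix(np.array([1.0]), np.ones(1), 1.0, np.array([1.0]), 1e-10, 1e10)
        assert d[0] == pytest.approx(0.5)


class TestBBSteps:
    def test_identity_scaling_collinear(self):
        a1, a2 = bb_steps(np.array([1.0, 1.0]), np.array([2.0, 2.0]), np.ones(2))
        assert a1 == pytest.approx(0.5)
        assert a2 == pytest.approx(0.5)

    def test_negative_curvature_unavailable(self):
        a1, a2 = bb_steps(np.array([1.0, 0.0]), np.array([-2.0, 0.0]), np.ones(2))
        assert a1 is None and a2 is None

    def test_scaled_hand_computation(self):
        D = 2.0 * np.ones(2)
        s = np.array([1.0, 0.0])
        w = np.array([3.0, 0.0])
        a1, a2 = bb_steps(s, w, D)
        assert a1 == pytest.approx(0.25 / 1.5)
        assert a2 == pytest.approx(6.0 / 36.0)


class TestAlternation:
    def test_bb1_branch(self):
        alpha, tau = alternate_steplength(0.5, 0.5, [], 0.5, 1e-5, 1e5, 3, 1.0)
        assert alpha == pytest.approx(0.5)
        assert tau == pytest.approx(0.55)

    def test_bb2_branch_uses_history_minimum(self):
        alpha, tau = alternate_steplength(10.0, 1.0, [0.8, 2.0], 0.5, 1e-5, 1e5, 3, 1.0)
        assert alpha == pytest.approx(0.8)  # min of last M-1 history + current
        assert tau == pytest.approx(0.45)

    def test_result_clipped(self):
        alpha, _ = alternate_steplength(1e9, 1e9, [], 0.5, 1e-5, 1e5, 3, 1.0)
        assert alpha == 1e5
        alpha, _ = alternate_steplength(None, None, [], 0.5, 1e-5, 1e5, 3, 1e9)
        assert alpha == 1e5


class TestArmijo:
    def test_full_step_accepted(self):
        f = lambda u: float(u[0] ** 2)
        lam, x, fx, _ = armijo_backtrack(
            f, np.array([1.0]), np.array([-1.0]), np.array([2.0]),
            armijo_beta=0.1, theta=0.5,
        )
        assert lam == 1.0 and fx == 0.0

    def test_two_halvings_needed(self):
        f = lambda u: float(u[0] ** 2)
        lam, x, fx, halvings = armijo_backtrack(
            f, np.array([1.0]), np.array([-4.0]), np.array([2.0]),
            armijo_beta=0.5, theta=0.5,
        )
        assert lam == pytest.approx(0.25)
        assert halvings == 2

    def test_accepted_value_strictly_decreases(self):
        rng = np.random.default_rng(3)
        Q = np.diag(rng.uniform(0.5, 2.0, size=4))
        f = lambda u: float(u @ Q @ u)
        x = rng.uniform(0.5, 1.5, size=4)
        g = 2 * Q @ x
        d = -g
        _, _, fx, _ = armijo_backtrack(f, x, d, g)
        assert fx < f(x)

    def test_non_descent_rejected(self):
        f = lambda u: float(u[0] ** 2)
        with pytest.raises(NonDescentError):
            armijo_backtrack(f, np.array([1.0]), np.array([1.0]), np.array([2.0]))


class TestDeconvolutionDrivers:
    def test_max_iter_zero_returns_x0(self, noisy_problem):
        objective, truth, y = noisy_problem
        cfg = SGPConfig(max_iter=0)
        res = sgp_deconvolve(objective, cfg)
        np.testing.assert_array_equal(res.x_final, default_x0(objective))
        assert res.stop_reason == "max_iter"
        assert res.iterations_run == 0

    def test_rl_fixed_point_at_noiseless_truth(self, small_gaussian_kernel):
        op = ImagingOperator.from_kernel(small_gaussian_kernel, (16, 16))
        rng = np.random.default_rng(1)
        truth = rng.uniform(0.5, 2.0, size=(16, 16))
        y = op.convolve(truth)
        objective = Objective("ml_kl", op, np.clip(y, 0, None))
        res = rl_deconvolve(objective, SGPConfig(max_iter=100), x0=truth)
        assert res.stop_reason == "fixed_point"
        assert res.iterations_run <= 1

    def test_rl_flux_conservation_each_iteration(self, noisy_problem):
        objective, _, y = noisy_problem
        op = objective.operator
        x = default_x0(objective)
        for _ in range(10):
            x = rl_step(op, y, x)
            assert x.sum() == pytest.approx(y.sum(), rel=1e-10)

    def test_rl_data_fit_non_increasing(self, noisy_problem):
        objective, _, _ = noisy_problem
        res = rl_deconvolve(objective, SGPConfig(max_iter=60, tol=1e-15))
        assert np.all(np.diff(res.f_trace) <= 1e-9 * np.abs(res.f_trace[:-1]) + 1e-12)

    def test_sgp_objective_monotone_and_envelope(self, noisy_problem):
        objective, _, _ = noisy_problem
        cfg = SGPConfig(max_iter=80, tol=1e-12)
        res = sgp_deconvolve(objective, cfg)
        assert np.all(np.diff(res.f_trace) <= 0)
        alphas = res.alpha_trace[1:]
        assert np.all((alphas >= cfg.alpha_min) & (alphas <= cfg.alpha_max))
        assert np.all(res.scaling_min_trace[1:] >= cfg.L1)
        assert np.all(res.scaling_max_trace[1:] <= cfg.L2)
        assert np.all(res.x_final >= 0)

    def test_sgp_and_rl_reach_same_kl_minimum(self):
        # both minimize the same KL objective; run to tight tolerance
        objective, _, _ = make_noisy_problem(size=32, seed=12)
        cfg = SGPConfig(max_iter=8000, tol=1e-8)
        rl = rl_deconvolve(objective, cfg)
        sgp = sgp_deconvolve(objective, cfg)
        assert sgp.f_trace[-1] == pytest.approx(rl.f_trace[-1], rel=1e-4)

    def test_reduces_to_projected_gradient_with_identity_scaling(self):
        objective, _, _ = make_noisy_problem(size=16, seed=13)
        alpha = 1e-3
        cfg = SGPConfig(
            max_iter=100, tol=1e-30, use_scaling=False, fixed_alpha=alpha,
            fixed_point_rtol=0.0,
        )
        res = sgp_deconvolve(objective, cfg)
        # brute-force projected gradient oracle
        x = default_x0(objective)
        for _ in range(100):
            x = np.clip(x - alpha * objective.gradient(x), 0.0, None)
        np.testing.assert_allclose(res.x_final, x, rtol=1e-8, atol=1e-12)

    def test_semiconvergence_interior_minimum(self):
        objective, truth, _ = make_noisy_problem(size=64, seed=14, peak=25.0)
        res = rl_deconvolve(
            objective,
            SGPConfig(stop_mode="kl_to_truth_min", max_iter=4000, kl_patience=80),
            ground_truth=truth,
        )
        assert res.stop_reason == "kl_to_truth_min"
        assert 1 < res.optimal_iteration < res.iterations_run

    def test_beta_zero_tikhonov_path_bit_equal_to_ml(self, noisy_problem):
        objective, _, y = noisy_problem
        map_obj = Objective("map_tikhonov", objective.operator, y, reg_beta=0.0)
        cfg = SGPConfig(max_iter=40, tol=1e-15)
        a = sgp_deconvolve(objective, cfg)
        b = sgp_deconvolve(map_obj, cfg)
        np.testing.assert_array_equal(a.x_final, b.x_final)
        np.testing.assert_array_equal(a.f_trace, b.f_trace)

    def test_tikhonov_regularization_shrinks_solution_norm(self, noisy_problem):
        objective, _, y = noisy_problem
        map_obj = Objective("map_tikhonov", objective.operator, y, reg_beta=0.05)
        cfg = SGPConfig(max_iter=200, tol=1e-8)
        ml = sgp_deconvolve(objective, cfg)
        map_res = sgp_deconvolve(map_obj, cfg)
        assert (map_res.x_final**2).sum() < (ml.x_final**2).sum()

    def test_kl_stop_requires_ground_truth(self, noisy_problem):
        objective, _, _ = noisy_problem
        with pytest.raises(ValueError, match="ground truth"):
            sgp_deconvolve(objective, SGPConfig(stop_mode="kl_to_truth_min"))

    def test_rl_rejects_regularized_objective(self, noisy_problem):
        objective, _, y = noisy_problem
        map_obj = Objective("map_tikhonov", objective.operator, y, reg_beta=0.1)
        with pytest.raises(ValueError):
            rl_deconvolve(map_obj)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"armijo_beta": 0.0},
            {"theta": 1.0},
            {"alpha_min": 1.0, "alpha_max": 0.5},
            {"L1": 2.0, "L2": 1.0},
            {"tol": 0.0},
            {"alternation_tau0": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SGPConfig(**kwargs)
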