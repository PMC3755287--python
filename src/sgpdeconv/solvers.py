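"""Richardson-Lucy and scaled-gradient-projection (SGP) deconvolution.

Richardson-Lucy (RL) is the classical multiplicative fixed-point iteration
for nonnegative minimizers of the Poisson (generalized KL) data fit:

    x <- (x / w) * H^T( y / (Hx + b) ),     w = H^T 1

With a sum-normalized kernel, no boundary correction and b = 0 it conserves
total flux (sum x_k = sum y) at every iteration, and the KL data fit is
non-increasing along the iterates.  Convergence is slow — hundreds of
iterations — and since the unregularized minimizers are spiky "night-sky"
solutions, early stopping is the regularizer in practice.

SGP accelerates the same minimization.  Each iteration scales the gradient
by a diagonal matrix D_k inspired by the RL/split-gradient update,

    D_k = clip( x_k / (w + beta * V1(x_k)), L1, L2 ),

projects x_k - alpha_k D_k grad f onto the nonnegative orthant, and moves
along the resulting feasible direction with a monotone Armijo backtracking
line search.  The step length alpha_k alternates adaptively between the two
scaled Barzilai-Borwein (BB) rules

    alpha_BB1 = s^T D^-2 s / s^T D^-1 w,
    alpha_BB2 = s^T D w   / w^T D^2  w,

(s and w the iterate and gradient differences) — when the two rules disagree
strongly (alpha_BB2/alpha_BB1 below a moving threshold) the smaller recent
BB2 values are preferred, otherwise BB1 is used.  Global convergence only
needs alpha_k in [alpha_min, alpha_max] and diag(D_k) in [L1, L2], so the
alternation is a speed heuristic, not a correctness requirement.

Two stopping rules are provided: relative objective decrease below a
tolerance (the rule for real images, default 1e-3), and — when the ground
truth is known, i.e. on simulated data — detection of the minimum of the KL
divergence to the scaled truth (semiconvergence point).  In the latter mode
the solver runs a fixed patience past the running minimum, and returns the
iterate snapshot taken at the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .forward_model import ImagingOperator
from .objectives import Objective
from .metrics import kl_to_truth

__all__ = [
    "SGPConfig",
    "SolverResult",
    "rl_step",
    "scaling_matrix",
    "bb_steps",
    "alternate_steplength",
    "armijo_backtrack",
    "sgp_deconvolve",
    "rl_deconvolve",
    "default_x0",
    "NonDescentError",
    "BacktrackingStagnation",
    "NumericalFailure",
]


class NonDescentError(RuntimeError):
    """The line-search direction was not a descent direction."""


class BacktrackingStagnation(RuntimeError):
    """Armijo backtracking exceeded its halving budget."""


class NumericalFailure(RuntimeError):
    """Non-finite objective or model breakdown; carries a state dump."""

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = state or {}


StopMode = Literal["kl_to_truth_min", "objective_tol"]


@dataclass
class SGPConfig:
    """Solver configuration.

    ``armijo_beta`` is the sufficient-decrease parameter of the line search
    (the regularization weight lives on the Objective as ``reg_beta``);
    ``theta`` the backtracking shrink factor; ``alpha0`` the first-iteration
    step; ``bb_memory`` the number of recent BB2 steps kept for the
    alternation; ``alternation_tau0`` its initial switching threshold.
    ``tol`` is the relative-objective stopping tolerance (objective_tol
    mode); ``kl_patience`` how many iterations past the running KL-to-truth
    minimum to search before declaring it (kl_to_truth_min mode).
    """

    armijo_beta: float = 1e-4
    theta: float = 0.4
    alpha_min: float = 1e-5
    alpha_max: float = 1e5
    L1: float = 1e-10
    L2: float = 1e10
    alpha0: float = 1.3
    max_iter: int = 1000
    tol: float = 1e-3
    stop_mode: StopMode = "objective_tol"
    bb_memory: int = 3
    alternation_tau0: float = 0.5
    kl_patience: int = 50
    tol_consecutive: int = 3  # objective_tol must hold this many iterations in a row
    alpha_damping: float = 10.0  # per-iteration cap on step collapse (0 = off)
    max_halvings: int = 60
    fixed_point_rtol: float = 1e-12
    single_precision: bool = False  # store iterates in float32 (FFTs stay double)
    use_scaling: bool = True        # identity scaling when False (diagnostics)
    fixed_alpha: float | None = None  # bypass BB alternation when set

    def __post_init__(self) -> None:
        if not (0 < self.armijo_beta < 1):
            raise ValueError("armijo_beta must lie in (0, 1)")
        if not (0 < self.theta < 1):
            raise ValueError("theta must lie in (0, 1)")
        if not (0 < self.alpha_min < self.alpha_max):
            raise ValueError("need 0 < alpha_min < alpha_max")
        if not (0 < self.L1 < self.L2):
            raise ValueError("need 0 < L1 < L2")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not (0 < self.alternation_tau0 < 1):
            raise ValueError("alternation_tau0 must lie in (0, 1)")


@dataclass
class SolverResult:
    """Outcome of a deconvolution run.

    ``x_final`` is the iterate at the optimal iteration in kl_to_truth_min
    mode, the last iterate otherwise.  Traces are indexed so that entry 0 is
    the initial point and entry k the state after iteration k.
    """

    x_final: np.ndarray
    iterations_run: int
    optimal_iteration: int
    f_trace: np.ndarray
    kl_truth_trace: np.ndarray | None
    stop_reason: str
    alpha_trace: np.ndarray | None = None
    lambda_trace: np.ndarray | None = None
    scaling_min_trace: np.ndarray | None = None
    scaling_max_trace: np.ndarray | None = None
    n_backtracks: int = 0

    def trace_frame(self):
        """Per-iteration trace as a pandas DataFrame (for CSV export)."""
        import pandas as pd

        n = self.iterations_run
        cols = {"iteration": np.arange(n + 1), "f": self.f_trace}
        if self.kl_truth_trace is not None:
            cols["kl_to_truth"] = self.kl_truth_trace
        if self.alpha_trace is not None:
            cols["alpha"] = self.alpha_trace
        if self.lambda_trace is not None:
            cols["lambda"] = self.lambda_trace
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# elementary operations


def rl_step(
    op: ImagingOperator,
    y: np.ndarray,
    x: np.ndarray,
    weights: np.ndarray | None = None,
    active: np.ndarray | None = None,
) -> np.ndarray:
    """One Richardson-Lucy multiplicative update."""
    w = op.weights() if weights is None else weights
    m = op.convolve(x)[op.window_slices] + op.background
    yarr = np.asarray(y, dtype=x.dtype)
    if np.any((m <= 0) & (yarr > 0)):
        raise NumericalFailure(
            "model vanished where counts are positive (diverged ratio)",
            {"min_model": float(m.min())},
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m > 0, yarr / np.where(m > 0, m, 1.0), 0.0)
    correction = op.adjoint(op.embed_image(ratio))
    if active is None:
        x_next = x / w * correction
    else:
        x_next = np.zeros_like(x)
        x_next[active] = x[active] / w[active] * correction[active]
    np.clip(x_next, 0.0, None, out=x_next)
    return x_next


def scaling_matrix(
    x: np.ndarray,
    weights: np.ndarray,
    reg_beta: float,
    V1: np.ndarray,
    L1: float,
    L2: float,
) -> np.ndarray:
    """Diagonal SGP scaling D = clip(x / (w + beta*V1), L1, L2)."""
    denom = weights + reg_beta * V1
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), L1)
    return np.clip(d, L1, L2)


def bb_steps(
    s: np.ndarray, w_grad_diff: np.ndarray, D: np.ndarray
) -> tuple[float | None, float | None]:
    """Scaled Barzilai-Borwein step lengths (None where degenerate).

    alpha_BB1 = (s^T D^-2 s)/(s^T D^-1 w); alpha_BB2 = (s^T D w)/(w^T D^2 w).
    A denominator <= 0 (curvature failure) yields None for that rule.
    """
    if s.shape != w_grad_diff.shape or s.shape != D.shape:
        raise ValueError("s, gradient difference and D must share a shape")
    s = s.ravel()
    w = w_grad_diff.ravel()
    D = D.ravel()
    sD = s / D
    denom1 = float(sD @ w)
    alpha1 = float(sD @ sD) / denom1 if denom1 > 0 else None
    Dw = D * w
    denom2 = float(Dw @ Dw)
    num2 = float(s @ Dw)
    alpha2 = num2 / denom2 if (denom2 > 0 and num2 > 0) else None
    return alpha1, alpha2


def alternate_steplength(
    alpha_bb1: float | None,
    alpha_bb2: float | None,
    bb2_history: Sequence[float],
    tau_k: float,
    alpha_min: float,
    alpha_max: float,
    memory: int,
    prev_alpha: float,
) -> tuple[float, float]:
    """Adaptive alternation between the two BB rules.

    If alpha_BB2/alpha_BB1 <= tau_k the step is the minimum of the last
    ``memory`` BB2 values (including the current one) and the threshold is
    relaxed (tau *= 0.9); otherwise BB1 is chosen and the threshold is
    tightened (tau *= 1.1).  A degenerate (unavailable) rule is replaced by
    alpha_max, so the other rule wins the alternation; if both rules are
    unavailable the previous step is kept.  The result is always clipped to
    [alpha_min, alpha_max].
    """
    # tau starts in (0,1) but may transiently exceed 1 after a run of BB1
    # choices; since alpha_BB2 <= alpha_BB1 (Cauchy-Schwarz) the BB2 branch
    # then fires and shrinks it back.
    if tau_k <= 0:
        raise ValueError("tau_k must be positive")
    clip = lambda a: float(np.clip(a, alpha_min, alpha_max))
    if alpha_bb1 is None and alpha_bb2 is None:
        return clip(prev_alpha), tau_k
    if alpha_bb1 is None:
        alpha_bb1 = alpha_max
    if alpha_bb2 is None:
        alpha_bb2 = alpha_max
    if alpha_bb2 / alpha_bb1 <= tau_k:
        recent = list(bb2_history[-(memory - 1):]) if memory > 1 else []
        recent.append(alpha_bb2)
        return clip(min(recent)), tau_k * 0.9
    return clip(alpha_bb1), tau_k * 1.1


def armijo_backtrack(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    d: np.ndarray,
    grad: np.ndarray,
    armijo_beta: float = 1e-4,
    theta: float = 0.4,
    max_halvings: int = 60,
) -> tuple[float, np.ndarray, float, int]:
    """Monotone Armijo backtracking along a feasible descent direction.

    Returns (lambda, accepted point, f at accepted point, halvings used).
    With d = z - x for feasible z and lambda <= 1, the accepted point stays
    in the nonnegative orthant automatically.
    """
    x = np.asarray(x, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    gd = float(np.asarray(grad).ravel() @ d.ravel())
    if gd >= 0:
        raise NonDescentError(f"grad^T d = {gd} >= 0: not a descent direction")
    f_x = f(x)
    lam = 1.0
    for halvings in range(max_halvings + 1):
        candidate = x + lam * d
        f_new = f(candidate)
        if f_new <= f_x + armijo_beta * lam * gd:
            return lam, candidate, f_new, halvings
        lam *= theta
    raise BacktrackingStagnation(
        f"no sufficient decrease after {max_halvings} halvings (f={f_x})"
    )


def default_x0(objective: Objective) -> np.ndarray:
    """Flux-consistent constant start: total sum(y - b) clipped at zero,
    spread uniformly over the active object pixels."""
    op = objective.operator
    y = objective.data
    flux = max(float((y - op.background).sum()), float(y.sum()) * 1e-6)
    x0 = np.zeros(op.object_shape, dtype=np.float64)
    if op.boundary is not None:
        active = op.boundary.active
        x0[active] = flux / int(active.sum())
    else:
        x0[...] = flux / x0.size
    return x0


# ---------------------------------------------------------------------------
# drivers


def _prepare(objective, config, x0, ground_truth):
    op = objective.operator
    if config.stop_mode == "kl_to_truth_min" and ground_truth is None:
        raise ValueError("kl_to_truth_min stopping requires the scaled ground truth")
    if x0 is None:
        x0 = default_x0(objective)
    x0 = np.asarray(x0, dtype=np.float32 if config.single_precision else np.float64)
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")
    if x0.shape != op.object_shape:
        raise ValueError(f"x0 shape {x0.shape} != object shape {op.object_shape}")
    weights = op.weights()
    if op.boundary is not None:
        active = op.boundary.active
    else:
        active = np.ones(op.object_shape, dtype=bool)
    x0 = x0.copy()
    x0[~active] = 0.0
    return x0, weights, active


def _truth_kl(x, op, ground_truth):
    return kl_to_truth(x[op.window_slices], ground_truth)


def sgp_deconvolve(
    objective: Objective,
    config: SGPConfig | None = None,
    x0: np.ndarray | None = None,
    ground_truth: np.ndarray | None = None,
) -> SolverResult:
    """Run the scaled-gradient-projection iteration.

    ``ground_truth`` (required for kl_to_truth_min stopping) is the phantom
    already scaled to emitted photons — compare
    :attr:`~sgpdeconv.forward_model.SyntheticDataset.scaled_truth`.
    """
    config = config or SGPConfig()
    op = objective.operator
    x, weights, active = _prepare(objective, config, x0, ground_truth)
    y = objective.data
    beta = objective.reg_beta

    m = np.clip(op.convolve(x)[op.window_slices] + op.background, 0.0, None)
    f_x = objective.value_from_model(x, m)
    if not np.isfinite(f_x):
        raise NumericalFailure("non-finite objective at the starting point",
                               {"f": f_x, "min_model": float(m.min())})
    grad = _kl_grad_from_model(op, y, m, weights)
    if beta > 0:
        grad += beta * x

    f_trace = [f_x]
    kl_trace = None
    best_x = None
    best_kl = np.inf
    best_iter = 0
    if config.stop_mode == "kl_to_truth_min":
        kl0 = _truth_kl(x, op, ground_truth)
        kl_trace = [kl0]
        best_x, best_kl, best_iter = x.copy(), kl0, 0

    alpha_trace = [np.nan]
    lambda_trace = [np.nan]
    dmin_trace = [np.nan]
    dmax_trace = [np.nan]
    total_backtracks = 0

    alpha = float(np.clip(config.alpha0, config.alpha_min, config.alpha_max))
    tau_k = config.alternation_tau0
    tol_hits = 0
    bb2_history: list[float] = []
    prev_x = None
    prev_grad = None
    stop_reason = "max_iter"
    k = 0

    for k in range(1, config.max_iter + 1):
        if config.use_scaling:
            V1 = objective.splitting(x)
            D = scaling_matrix(x, weights, beta, V1, config.L1, config.L2)
        else:
            D = np.ones_like(x)
        D = np.where(active, D, config.L1)

        if config.fixed_alpha is not None:
            alpha = float(np.clip(config.fixed_alpha, config.alpha_min, config.alpha_max))
        elif prev_x is not None:
            s = (x - prev_x)[active]
            wg = (grad - prev_grad)[active]
            a1, a2 = bb_steps(s, wg, D[active])
            prev_alpha = alpha
            alpha, tau_k = alternate_steplength(
                a1, a2, bb2_history, tau_k,
                config.alpha_min, config.alpha_max, config.bb_memory, alpha,
            )
            if config.alpha_damping > 0:
                # after an over-aggressive projection the model can graze zero
                # and BB reports enormous curvature; an undamped collapse to
                # alpha_min stalls the iteration for tens of iterations (the
                # line search already protects monotonicity, so damping the
                # collapse is safe)
                alpha = max(alpha, prev_alpha / config.alpha_damping)
            if a2 is not None:
                bb2_history.append(float(np.clip(a2, config.alpha_min, config.alpha_max)))
                del bb2_history[:-config.bb_memory]

        z = x - alpha * D * grad
        np.clip(z, 0.0, None, out=z)
        z[~active] = 0.0

        scale = max(float(np.abs(x).max()), np.finfo(np.float64).tiny)
        if float(np.abs(z - x).max()) <= config.fixed_point_rtol * scale:
            stop_reason = "fixed_point"
            k -= 1
            break

        d = z - x
        gd = float(grad.ravel() @ d.ravel())
        if gd >= 0:
            raise NonDescentError(
                f"projection direction not descent at iteration {k} (g^T d={gd})"
            )
        Hd = op.convolve(d)[op.window_slices]
        lam = 1.0
        accepted = False
        for halvings in range(config.max_halvings + 1):
            m_new = m + lam * Hd
            np.clip(m_new, 0.0, None, out=m_new)
            x_new = x + lam * d
            f_new = objective.value_from_model(x_new, m_new)
            if np.isfinite(f_new) and f_new <= f_x + config.armijo_beta * lam * gd:
                accepted = True
                break
            lam *= config.theta
            total_backtracks += 1
        if not accepted:
            raise BacktrackingStagnation(
                f"line search stalled at iteration {k} (f={f_x})"
            )

        prev_x, prev_grad = x, grad
        x, m, f_x = x_new.astype(x.dtype, copy=False), m_new, f_new
        np.clip(x, 0.0, None, out=x)
        if k % 50 == 0:  # refresh the incrementally-updated model
            m = np.clip(op.convolve(x)[op.window_slices] + op.background, 0.0, None)
        grad = _kl_grad_from_model(op, y, m, weights)
        if beta > 0:
            grad += beta * x

        f_trace.append(f_x)
        alpha_trace.append(alpha)
        lambda_trace.append(lam)
        dmin_trace.append(float(D[active].min()))
        dmax_trace.append(float(D[active].max()))

        if config.stop_mode == "kl_to_truth_min":
            klv = _truth_kl(x, op, ground_truth)
            kl_trace.append(klv)
            if klv < best_kl:
                best_kl, best_iter = klv, k
                best_x = x.copy()
            if k - best_iter >= config.kl_patience:
                stop_reason = "kl_to_truth_min"
                break
        else:
            # BB step lengths make single-iteration progress erratic, so the
            # relative-decrease criterion must hold several iterations in a
            # row before it is trusted
            if abs(f_trace[-2] - f_trace[-1]) <= config.tol * abs(f_trace[-1]):
                tol_hits += 1
                if tol_hits >= config.tol_consecutive:
                    stop_reason = "objective_tol"
                    break
            else:
                tol_hits = 0
    else:
        k = config.max_iter

    iterations_run = len(f_trace) - 1
    if config.stop_mode == "kl_to_truth_min":
        x_out = best_x
        optimal = best_iter
    else:
        x_out = x
        optimal = iterations_run
    return SolverResult(
        x_final=x_out,
        iterations_run=iterations_run,
        optimal_iteration=optimal,
        f_trace=np.asarray(f_trace),
        kl_truth_trace=None if kl_trace is None else np.asarray(kl_trace),
        stop_reason=stop_reason,
        alpha_trace=np.asarray(alpha_trace),
        lambda_trace=np.asarray(lambda_trace),
        scaling_min_trace=np.asarray(dmin_trace),
        scaling_max_trace=np.asarray(dmax_trace),
        n_backtracks=total_backtracks,
    )


def _kl_grad_from_model(op, y, m, weights):
    yarr = np.asarray(y, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m > 0, yarr / np.where(m > 0, m, 1.0), 0.0)
    return weights - op.adjoint(op.embed_image(ratio))


def rl_deconvolve(
    objective: Objective,
    config: SGPConfig | None = None,
    x0: np.ndarray | None = None,
    ground_truth: np.ndarray | None = None,
) -> SolverResult:
    """Run the Richardson-Lucy iteration with the same stopping rules as SGP.

    Only the pure-ML objective is supported (RL is the classical solver of
    the unregularized KL problem).
    """
    config = config or SGPConfig()
    if objective.reg_beta != 0:
        raise ValueError("rl_deconvolve handles the unregularized (ml_kl) problem only")
    op = objective.operator
    x, weights, active = _prepare(objective, config, x0, ground_truth)
    y = objective.data
    yarr = np.asarray(y, dtype=np.float64)

    from .objectives import kl_value

    m = np.clip(op.convolve(x)[op.window_slices] + op.background, 0.0, None)
    f_trace = [kl_value(yarr, m)]
    kl_trace = None
    best_x = None
    best_kl = np.inf
    best_iter = 0
    if config.stop_mode == "kl_to_truth_min":
        kl0 = _truth_kl(x, op, ground_truth)
        kl_trace = [kl0]
        best_x, best_kl, best_iter = x.copy(), kl0, 0

    stop_reason = "max_iter"
    tol_hits = 0
    for k in range(1, config.max_iter + 1):
        if np.any((m <= 0) & (yarr > 0)):
            raise NumericalFailure(
                "model vanished where counts are positive (diverged ratio)",
                {"iteration": k, "min_model": float(m.min())},
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(m > 0, yarr / np.where(m > 0, m, 1.0), 0.0)
        correction = op.adjoint(op.embed_image(ratio))
        x_new = np.zeros_like(x)
        x_new[active] = x[active] / weights[active] * correction[active]
        np.clip(x_new, 0.0, None, out=x_new)
        x_new = x_new.astype(x.dtype, copy=False)
        scale = max(float(np.abs(x).max()), np.finfo(np.float64).tiny)
        if float(np.abs(x_new - x).max()) <= config.fixed_point_rtol * scale:
            stop_reason = "fixed_point"
            break
        x = x_new
        m = np.clip(op.convolve(x)[op.window_slices] + op.background, 0.0, None)
        f_trace.append(kl_value(yarr, m))
        if config.stop_mode == "kl_to_truth_min":
            klv = _truth_kl(x, op, ground_truth)
            kl_trace.append(klv)
            if klv < best_kl:
                best_kl, best_iter = klv, k
                best_x = x.copy()
            if k - best_iter >= config.kl_patience:
                stop_reason = "kl_to_truth_min"
                break
        else:
            if abs(f_trace[-2] - f_trace[-1]) <= config.tol * abs(f_trace[-1]):
                tol_hits += 1
                if tol_hits >= config.tol_consecutive:
                    stop_reason = "objective_tol"
                    break
            else:
                tol_hits = 0

    iterations_run = len(f_trace) - 1
    if config.stop_mode == "kl_to_truth_min":
        x_out = best_x
        optimal = best_iter
    else:
        x_out = x
        optimal = iterations_run
    return SolverResult(
        x_final=x_out,
        iterations_run=iterations_run,
        optimal_iteration=optimal,
        f_trace=np.asarray(f_trace),
        kl_truth_trace=None if kl_trace is None else np.asarray(kl_trace),
        stop_reason=stop_reason,
    )
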