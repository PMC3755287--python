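"""Restoration-quality metrics against known ground truth.

On simulated data the object is known, so reconstruction quality can be
tracked per iteration as the generalized KL divergence of the scaled ground
truth from the current iterate.  The truth is scaled to emitted photons
(tau times the simulation-kernel sum times the phantom — see
``SyntheticDataset.flux_scale``), the flux at which a converged
reconstruction matches it.  The iteration at which this divergence is
minimal — the semiconvergence point — is the "optimal iteration", and the
headline solver comparison is the percentage reduction in optimal iteration
count of SGP relative to RL on identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .objectives import kl_value

__all__ = [
    "EvaluationTrace",
    "kl_to_truth",
    "optimal_iteration",
    "iteration_reduction",
]


def kl_to_truth(
    x_k: np.ndarray, scaled_truth: np.ndarray, floor_rel: float = 1e-8
) -> float:
    """Generalized KL divergence of the scaled truth from the iterate x_k.

    Same formula and zero-count conventions as the data-fidelity term, with
    the truth in the role of the counts and the iterate as the model.

    Projection-based solvers produce iterates with exact zeros (the
    unregularized minimizers are sparse night-sky solutions), and a zero at
    a pixel where the truth is positive makes the raw divergence +inf for
    every later iterate, destroying the semiconvergence minimum the metric
    exists to locate.  The iterate is therefore floored at ``floor_rel``
    times the truth peak, so wrongly-zeroed pixels contribute a large but
    finite penalty.  Set ``floor_rel=0`` for the strict divergence.
    """
    x_k = np.asarray(x_k, dtype=np.float64)
    scaled_truth = np.asarray(scaled_truth, dtype=np.float64)
    if floor_rel > 0 and scaled_truth.size:
        floor = floor_rel * float(scaled_truth.max())
        if floor > 0:
            x_k = np.maximum(x_k, floor)
    return kl_value(scaled_truth, x_k)


def optimal_iteration(trace: np.ndarray) -> int:
    """1-based index of the first minimum of a KL-to-truth trace."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("empty trace")
    return int(np.argmin(trace)) + 1


def iteration_reduction(rl_optimal: float, sgp_optimal: float) -> float:
    """Percentage reduction in optimal iterations: 100*(RL - SGP)/RL."""
    if rl_optimal <= 0:
        raise ValueError("rl_optimal must be > 0")
    return 100.0 * (rl_optimal - sgp_optimal) / rl_optimal


@dataclass
class EvaluationTrace:
    """Per-iteration KL-to-truth trace plus its minimizer."""

    kl_to_truth: np.ndarray
    scaled_truth: np.ndarray

    def __post_init__(self) -> None:
        self.kl_to_truth = np.asarray(self.kl_to_truth, dtype=np.float64)

    @property
    def optimal(self) -> int:
        return optimal_iteration(self.kl_to_truth)

    @property
    def minimum(self) -> float:
        return float(self.kl_to_truth.min())
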