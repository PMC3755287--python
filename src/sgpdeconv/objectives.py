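"""Poisson data-fidelity and regularized objectives for deconvolution.

The maximum-likelihood objective under Poisson counting noise is the
generalized Kullback-Leibler (Csiszar I-) divergence of the data y from the
model m = Hx + b:

    f0(x) = sum_i [ y_i ln(y_i / m_i) + m_i - y_i ]

with the y_i = 0 term equal to m_i (the continuous limit of y ln y -> 0).
Its gradient is H^T(1 - y/m); with a sum-normalized kernel and periodic
boundary H^T 1 = 1, and with boundary correction H^T 1 is replaced by the
precomputed window weights.

The maximum-a-posteriori (MAP) objective adds a differentiable penalty
beta * f1(x); the quadratic (Tikhonov) case f1 = ||x||^2 / 2 is implemented.
The split-gradient decomposition of grad f1 into a nonnegative part V1
(V1 = x for Tikhonov, V1 = 0 for pure ML) feeds the diagonal scaling of the
SGP solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .forward_model import ImagingOperator

__all__ = [
    "Objective",
    "kl_value",
    "kl_gradient",
    "tikhonov_value",
    "tikhonov_gradient",
    "sgm_splitting",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    pass


ObjectiveKind = Literal["ml_kl", "map_tikhonov"]


def kl_value(y: np.ndarray, model: np.ndarray) -> float:
    """Generalized KL divergence of counts y from model m.

    Nonnegative, zero iff y == m.  Zero counts contribute m_i exactly (no
    epsilon padding).  If m_i = 0 where y_i > 0 the divergence is +inf,
    returned as a non-finite float rather than raised.
    """
    y = np.asarray(y, dtype=np.float64)
    m = np.asarray(model, dtype=np.float64)
    if y.shape != m.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {m.shape}")
    if np.any(y < 0) or np.any(m < 0):
        raise ValueError("counts and model must be nonnegative")
    pos = y > 0
    if np.any(m[pos] == 0):
        return float("inf")
    total = float(m.sum() - y.sum())
    yp = y[pos]
    total += float((yp * np.log(yp / m[pos])).sum())
    # tiny negative values from cancellation are numerically zero
    return total


def kl_gradient(op: ImagingOperator, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Gradient of the KL data fit: H^T 1 - H^T(window * y / (Hx + b)).

    With no boundary correction H^T 1 = 1 exactly (sum-normalized kernel).
    """
    hx = op.convolve(x)
    m = hx[op.window_slices] + op.background
    ratio = np.zeros(op.object_shape, dtype=np.float64)
    yw = np.asarray(y, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(m > 0, yw / np.where(m > 0, m, 1.0), 0.0)
    ratio[op.window_slices] = q
    return op.weights() - op.adjoint(ratio)


def tikhonov_value(x: np.ndarray) -> float:
    """Quadratic penalty f1(x) = ||x||^2 / 2."""
    x = np.asarray(x, dtype=np.float64)
    return 0.5 * float((x**2).sum())


def tikhonov_gradient(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=np.float64).copy()


def sgm_splitting(kind: ObjectiveKind, x: np.ndarray) -> np.ndarray:
    """Nonnegative split V1 of the penalty gradient, used in the SGP scaling.

    ml_kl -> 0 (no penalty); map_tikhonov -> x itself.
    """
    x = np.asarray(x, dtype=np.float64)
    if kind == "ml_kl":
        return np.zeros_like(x)
    if kind == "map_tikhonov":
        return x.copy()
    raise ConfigurationError(f"unknown objective kind {kind!r}")


@dataclass
class Objective:
    """Bundles the imaging operator, data and penalty weight.

    ``reg_beta`` is the regularization parameter (0 for pure ML); it is
    distinct from the Armijo line-search parameter of the solver.
    """

    kind: ObjectiveKind
    operator: ImagingOperator
    data: np.ndarray
    reg_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ml_kl", "map_tikhonov"):
            raise ConfigurationError(f"unknown objective kind {self.kind!r}")
        if self.reg_beta < 0:
            raise ConfigurationError("reg_beta must be >= 0")
        if self.kind == "ml_kl" and self.reg_beta != 0:
            raise ConfigurationError("ml_kl objective requires reg_beta = 0")
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.operator.image_shape:
            raise ValueError("data shape must match operator image shape")
        if np.any(self.data < 0):
            raise ValueError("counts must be nonnegative")

    def model(self, x: np.ndarray) -> np.ndarray:
        """Expected counts Hx + b on the recorded field (FFT roundoff can
        leave tiny negatives in Hx; they are clipped to zero)."""
        m = self.operator.convolve(x)[self.operator.window_slices] + self.operator.background
        return np.clip(m, 0.0, None)

    def value(self, x: np.ndarray) -> float:
        f = kl_value(self.data, self.model(x))
        if self.reg_beta > 0:
            f += self.reg_beta * tikhonov_value(x)
        return f

    def value_from_model(self, x: np.ndarray, m: np.ndarray) -> float:
        """Objective from a precomputed model array (saves an FFT pair)."""
        f = kl_value(self.data, m)
        if self.reg_beta > 0:
            f += self.reg_beta * tikhonov_value(x)
        return f

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = kl_gradient(self.operator, self.data, x)
        if self.reg_beta > 0:
            g += self.reg_beta * tikhonov_gradient(x)
        return g

    def splitting(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "ml_kl" or self.reg_beta == 0:
            return np.zeros_like(np.asarray(x, dtype=np.float64))
        return sgm_splitting(self.kind, x)
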