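import numpy as np
import pytest

from sgpdeconv.forward_model import ImagingOperator
from sgpdeconv.objectives import Objective
from sgpdeconv.psf import GaussianPSFParams, PSFKernel, gaussian_psf


@pytest.fixture
def delta_kernel_2d():
    """1x1 identity kernel: H is the identity operator."""
    return PSFKernel(np.ones((1, 1)), (20.0, 20.0), "sum_to_one")


@pytest.fixture
def small_gaussian_kernel():
    """9x9 sum-to-one Gaussian kernel at 20 nm pixels (sigma 40 nm)."""
    return gaussian_psf(GaussianPSFParams(sigma_r=40.0), (9, 9), (20.0, 20.0))


def make_noisy_problem(size=32, sigma_r=40.0, peak=30.0, seed=0, background=0.0):
    """Small seeded Poisson deconvolution problem with known truth.

    A few Gaussian blobs as ground truth, blurred with a sum-to-one kernel,
    scaled so the blurred peak is ``peak`` counts, Poisson-corrupted.
    Returns (objective, truth, y).
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    truth = np.zeros((size, size))
    for _ in range(4):
        cy, cx = rng.uniform(size * 0.2, size * 0.8, size=2)
        amp = rng.uniform(0.3, 1.0)
        truth += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
    kside = 9 if size >= 9 else 5
    kernel = gaussian_psf(GaussianPSFParams(sigma_r=sigma_r), (kside, kside), (20.0, 20.0))
    op = ImagingOperator.from_kernel(kernel, (size, size), background=background)
    blurred = np.clip(op.convolve(truth), 0, None)
    scale = peak / blurred.max()
    truth = truth * scale
    mean = np.clip(op.convolve(truth), 0, None) + background
    y = rng.poisson(mean).astype(np.float64)
    objective = Objective("ml_kl", op, y)
    return objective, truth, y


@pytest.fixture
def noisy_problem():
    return make_noisy_problem(seed=7)
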