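"""Parametric point-spread-function models for confocal and CW-STED microscopy.

A confocal (CLSM) PSF is modelled as a radially symmetric Gaussian with
lateral width ``sigma_r`` (and axial width ``sigma_z`` for 3D stacks).  A
CW-STED PSF is modelled as the confocal Gaussian multiplied by a Lorentzian
suppression factor that narrows the profile as the depletion-beam saturation
factor grows while leaving the peak value unchanged:

    h(r) = exp(-r^2 / (2 sigma_r^2)) / (1 + saturation * (psi * r)^2)

where ``psi`` (nm^-1) encodes the shape of the doughnut-shaped depletion
intensity near the focus and ``saturation`` is the ratio of the peak
depletion intensity to the effective saturation intensity of the marker.
``saturation = 0`` recovers the confocal model exactly.  The exponent of the
Lorentzian denominator is configurable (``lorentz_exponent``); the default 1
is the form used throughout this package.

Kernels are rasterized by evaluating the model at pixel centres on a grid
with odd dimensions, so the analytic peak lands on a single centre pixel.
Two normalization modes are supported: ``sum_to_one`` (for use as a
convolution kernel in deconvolution) and ``peak_preserving`` (raw model
values, peak equal to the analytic peak — the mode used when simulating the
STED-vs-confocal photon budget, where narrowing the PSF reduces the total
collected signal but not the peak brightness).

Module also provides estimation of ``sigma`` and ``saturation`` from 1D
intensity profiles through sub-resolved structures, the calibration route
used on real images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GaussianPSFParams",
    "STEDPSFParams",
    "PSFKernel",
    "gaussian_psf",
    "sted_psf",
    "fwhm_from_sigma",
    "sigma_from_fwhm",
    "estimate_gaussian_sigma",
    "estimate_saturation",
    "PSFParameterError",
    "PSFGeometryError",
    "ProfileFitError",
    "load_psf_params",
    "save_psf_params",
    "read_kernel_tiff",
    "write_kernel_tiff",
]

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class PSFParameterError(ValueError):
    """Invalid PSF model parameter (non-positive width, negative saturation...)."""


class PSFGeometryError(ValueError):
    """Invalid rasterization geometry (even grid dims, non-positive pixels)."""


class ProfileFitError(RuntimeError):
    """A profile fit could not be performed (degenerate input or no convergence)."""


@dataclass(frozen=True)
class GaussianPSFParams:
    """Confocal PSF parameters: lateral sigma, optional axial sigma, in nm."""

    sigma_r: float
    sigma_z: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_r <= 0:
            raise PSFParameterError(f"sigma_r must be > 0, got {self.sigma_r}")
        if self.sigma_z is not None and self.sigma_z <= 0:
            raise PSFParameterError(f"sigma_z must be > 0, got {self.sigma_z}")


@dataclass(frozen=True)
class STEDPSFParams:
    """CW-STED PSF parameters.

    ``psi`` is in nm^-1; ``saturation`` is the dimensionless saturation
    factor (peak depletion intensity over effective saturation intensity).
    ``saturation = 0`` reduces the model to :class:`GaussianPSFParams`.
    """

    sigma_r: float
    psi: float
    saturation: float
    sigma_z: float | None = None
    lorentz_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_r <= 0:
            raise PSFParameterError(f"sigma_r must be > 0, got {self.sigma_r}")
        if self.psi < 0:
            raise PSFParameterError(f"psi must be >= 0, got {self.psi}")
        if self.saturation < 0:
            raise PSFParameterError(
                f"saturation must be >= 0, got {self.saturation}"
            )
        if self.sigma_z is not None and self.sigma_z <= 0:
            raise PSFParameterError(f"sigma_z must be > 0, got {self.sigma_z}")


NormalizationMode = Literal["sum_to_one", "peak_preserving"]


@dataclass
class PSFKernel:
    """A rasterized PSF: nonnegative values on an odd-dimension grid.

    ``pixel_size`` gives the physical extent of one pixel per axis in nm,
    ordered like the array axes ((z,) y, x).
    """

    values: np.ndarray
    pixel_size: tuple[float, ...]
    normalization_mode: NormalizationMode

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise PSFParameterError("kernel values must be nonnegative")
        if len(self.pixel_size) != self.values.ndim:
            raise PSFGeometryError(
                "pixel_size must have one entry per kernel axis"
            )

    @property
    def center(self) -> tuple[int, ...]:
        return tuple(s // 2 for s in self.values.shape)

    @property
    def peak(self) -> float:
        return float(self.values[self.center])

    def sum(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "PSFKernel":
        """Return the sum-to-one version of this kernel (shape preserved)."""
        total = self.values.sum()
        if total <= 0:
            raise PSFParameterError("cannot normalize an all-zero kernel")
        return PSFKernel(self.values / total, self.pixel_size, "sum_to_one")


def fwhm_from_sigma(sigma: float) -> float:
    """Full width at half maximum of a Gaussian: 2*sqrt(2 ln 2)*sigma."""
    if sigma <= 0:
        raise PSFParameterError(f"sigma must be > 0, got {sigma}")
    return _FWHM_FACTOR * sigma


def sigma_from_fwhm(fwhm: float) -> float:
    """Inverse of :func:`fwhm_from_sigma`."""
    if fwhm <= 0:
        raise PSFParameterError(f"fwhm must be > 0, got {fwhm}")
    return fwhm / _FWHM_FACTOR


def _check_grid(shape: Sequence[int], pixel_size: Sequence[float], ndim_expected: int) -> None:
    if len(shape) != ndim_expected or len(pixel_size) != ndim_expected:
        raise PSFGeometryError(
            f"expected {ndim_expected}-dim shape and pixel_size, "
            f"got shape={tuple(shape)}, pixel_size={tuple(pixel_size)}"
        )
    for s in shape:
        if s < 1 or s % 2 == 0:
            raise PSFGeometryError(f"grid dims must be odd and positive, got {tuple(shape)}")
    for p in pixel_size:
        if p <= 0:
            raise PSFGeometryError(f"pixel sizes must be > 0, got {tuple(pixel_size)}")


def _axis_coords(shape: Sequence[int], pixel_size: Sequence[float]) -> list[np.ndarray]:
    # physical coordinates of pixel centres relative to the geometric centre
    return [
        (np.arange(n) - n // 2) * p for n, p in zip(shape, pixel_size)
    ]


def _normalize(values: np.ndarray, mode: NormalizationMode) -> np.ndarray:
    if mode == "sum_to_one":
        return values / values.sum()
    if mode == "peak_preserving":
        return values
    raise PSFParameterError(f"unknown normalization mode {mode!r}")


def gaussian_psf(
    params: GaussianPSFParams,
    shape: Sequence[int],
    pixel_size: Sequence[float],
    mode: NormalizationMode = "sum_to_one",
) -> PSFKernel:
    """Rasterize the confocal Gaussian PSF on an odd grid.

    2D when ``params.sigma_z`` is None (shape = (ny, nx)), 3D otherwise
    (shape = (nz, ny, nx)).  Values are the model evaluated at pixel centres.
    """
    ndim = 2 if params.sigma_z is None else 3
    _check_grid(shape, pixel_size, ndim)
    coords = _axis_coords(shape, pixel_size)
    if ndim == 2:
        y, x = np.meshgrid(*coords, indexing="ij")
        vals = np.exp(-(x**2 + y**2) / (2.0 * params.sigma_r**2))
    else:
        z, y, x = np.meshgrid(*coords, indexing="ij")
        vals = np.exp(-(x**2 + y**2) / (2.0 * params.sigma_r**2)) * np.exp(
            -(z**2) / (2.0 * params.sigma_z**2)
        )
    return PSFKernel(_normalize(vals, mode), tuple(pixel_size), mode)


def sted_psf(
    params: STEDPSFParams,
    shape: Sequence[int],
    pixel_size: Sequence[float],
    mode: NormalizationMode = "sum_to_one",
) -> PSFKernel:
    """Rasterize the CW-STED Gaussian-Lorentzian PSF.

    The Lorentzian suppression acts radially (in x, y) only; the axial
    profile stays Gaussian, since the depletion doughnut confines laterally.
    """
    ndim = 2 if params.sigma_z is None else 3
    _check_grid(shape, pixel_size, ndim)
    coords = _axis_coords(shape, pixel_size)
    if ndim == 2:
        y, x = np.meshgrid(*coords, indexing="ij")
        r2 = x**2 + y**2
        vals = np.exp(-r2 / (2.0 * params.sigma_r**2))
    else:
        z, y, x = np.meshgrid(*coords, indexing="ij")
        r2 = x**2 + y**2
        vals = np.exp(-r2 / (2.0 * params.sigma_r**2)) * np.exp(
            -(z**2) / (2.0 * params.sigma_z**2)
        )
    suppression = (1.0 + params.saturation * params.psi**2 * r2) ** params.lorentz_exponent
    vals = vals / suppression
    return PSFKernel(_normalize(vals, mode), tuple(pixel_size), mode)


def sted_fwhm(params: STEDPSFParams) -> float:
    """Lateral FWHM (nm) of the CW-STED model, by radial root solve."""
    from scipy.optimize import brentq

    def h(r: float) -> float:
        return math.exp(-(r**2) / (2 * params.sigma_r**2)) / (
            1.0 + params.saturation * params.psi**2 * r**2
        ) ** params.lorentz_exponent

    hi = fwhm_from_sigma(params.sigma_r)  # model is never wider than confocal
    return 2.0 * brentq(lambda r: h(r) - 0.5, 1e-9, hi)


def sted_lorentz_exponent_for_fwhm(
    sigma_r: float, psi: float, saturation: float, target_fwhm: float
) -> float:
    """Suppression exponent p that gives the model a prescribed FWHM.

    The model h(r) = exp(-r^2/(2 sigma_r^2)) (1 + saturation psi^2 r^2)^-p
    has a closed-form exponent for any target FWHM narrower than the
    confocal one:  p = ln(2 g(r_half)) / ln(1 + saturation psi^2 r_half^2)
    with g the Gaussian factor and r_half = target_fwhm / 2.  This is how a
    measured effective STED resolution is folded into the parametric model
    when saturation and psi alone do not pin the width down.
    """
    if target_fwhm <= 0:
        raise PSFParameterError("target_fwhm must be > 0")
    if target_fwhm >= fwhm_from_sigma(sigma_r):
        raise PSFParameterError(
            "target FWHM must be narrower than the confocal FWHM"
        )
    if psi <= 0 or saturation <= 0:
        raise PSFParameterError("psi and saturation must be > 0 to narrow the PSF")
    r_half = target_fwhm / 2.0
    g = math.exp(-(r_half**2) / (2.0 * sigma_r**2))
    return math.log(2.0 * g) / math.log(1.0 + saturation * psi**2 * r_half**2)


def _gauss_model(u, amplitude, u0, sigma, offset):
    return amplitude * np.exp(-((u - u0) ** 2) / (2.0 * sigma**2)) + offset


def estimate_gaussian_sigma(
    positions: np.ndarray, intensities: np.ndarray
) -> tuple[float, dict]:
    """Fit ``a*exp(-(u-u0)^2/(2 sigma^2)) + c`` to a 1D intensity profile.

    Returns the estimated sigma (> 0) and a diagnostics dict with the full
    parameter vector and the residual norm.  The initial guess comes from
    profile moments, so no user tuning is needed.  Degenerate (flat or
    all-zero) profiles raise :class:`ProfileFitError`.
    """
    u = np.asarray(positions, dtype=np.float64)
    v = np.asarray(intensities, dtype=np.float64)
    if u.ndim != 1 or u.shape != v.shape:
        raise ProfileFitError("positions and intensities must be equal-length 1D arrays")
    if u.size < 5:
        raise ProfileFitError("need at least 5 profile samples")
    span = float(v.max() - v.min())
    if span <= 0 or not np.isfinite(span):
        raise ProfileFitError("profile is flat; no peak to fit")

    offset0 = float(v.min())
    w = np.clip(v - offset0, 0.0, None)
    wsum = w.sum()
    u0_0 = float((u * w).sum() / wsum)
    var0 = float(((u - u0_0) ** 2 * w).sum() / wsum)
    sigma0 = math.sqrt(max(var0, (u[1] - u[0]) ** 2 if u.size > 1 else 1.0))
    p0 = [span, u0_0, sigma0, offset0]
    # Poisson-appropriate weights: var(count) = mean, approximated by the
    # observed value (floored at 1 to keep weights finite)
    w_sigma = np.sqrt(np.maximum(v, 1.0))
    try:
        popt, _ = curve_fit(_gauss_model, u, v, p0=p0, sigma=w_sigma, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise ProfileFitError(f"Gaussian fit failed: {exc}") from exc
    amplitude, u0, sigma, offset = popt
    sigma = abs(float(sigma))
    if sigma <= 0 or not np.isfinite(sigma):
        raise ProfileFitError("fit returned a degenerate sigma")
    residual = float(np.linalg.norm(_gauss_model(u, *popt) - v))
    diagnostics = {
        "amplitude": float(amplitude),
        "center": float(u0),
        "sigma": sigma,
        "offset": float(offset),
        "residual_norm": residual,
    }
    return sigma, diagnostics


def estimate_saturation(
    positions: np.ndarray,
    intensities: np.ndarray,
    sigma_r: float,
    psi: float,
    lorentz_exponent: float = 1.0,
) -> tuple[float, dict]:
    """Estimate the STED saturation factor from a 1D profile.

    ``sigma_r`` (from a confocal image of the same specimen) and ``psi``
    (from depletion-beam calibration) are fixed inputs; amplitude, centre
    and offset are free.  If the profile is broader than the confocal model
    allows, the fit pushes the saturation to its lower bound and the
    estimate is clamped at 0 (a warning flag is set in the diagnostics).
    """
    if sigma_r <= 0:
        raise PSFParameterError(f"sigma_r must be > 0, got {sigma_r}")
    if psi < 0:
        raise PSFParameterError(f"psi must be >= 0, got {psi}")
    u = np.asarray(positions, dtype=np.float64)
    v = np.asarray(intensities, dtype=np.float64)
    if u.ndim != 1 or u.shape != v.shape:
        raise ProfileFitError("positions and intensities must be equal-length 1D arrays")
    if u.size < 5:
        raise ProfileFitError("need at least 5 profile samples")
    span = float(v.max() - v.min())
    if span <= 0 or not np.isfinite(span):
        raise ProfileFitError("profile is flat; no peak to fit")

    def model(uu, amplitude, u0, log_s, offset):
        s = np.exp(log_s)
        r = uu - u0
        g = np.exp(-(r**2) / (2.0 * sigma_r**2))
        return amplitude * g / (1.0 + s * psi**2 * r**2) ** lorentz_exponent + offset

    offset0 = float(v.min())
    w = np.clip(v - offset0, 0.0, None)
    u0_0 = float((u * w).sum() / w.sum())
    best = None
    # log-parametrized saturation keeps the estimate positive; multi-start
    # over a coarse grid avoids the flat-gradient region at tiny saturation
    w_sigma = np.sqrt(np.maximum(v, 1.0))
    for s_start in (0.01, 0.5, 3.0, 10.0):
        p0 = [span, u0_0, math.log(s_start), offset0]
        try:
            popt, _ = curve_fit(model, u, v, p0=p0, sigma=w_sigma, maxfev=20000)
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(model(u, *popt) - v))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise ProfileFitError("saturation fit did not converge from any start")
    popt, residual = best
    saturation = float(np.exp(popt[2]))
    clamped = False
    if saturation < 1e-6:
        # broader-than-confocal profile: the Lorentzian cannot widen the
        # model, so the optimum sits at the saturation = 0 boundary
        saturation = 0.0
        clamped = True
    diagnostics = {
        "amplitude": float(popt[0]),
        "center": float(popt[1]),
        "saturation": saturation,
        "offset": float(popt[3]),
        "residual_norm": residual,
        "clamped_at_zero": clamped,
    }
    return saturation, diagnostics


# ---------------------------------------------------------------------------
# persistence

def save_psf_params(path, params: GaussianPSFParams | STEDPSFParams) -> None:
    import yaml

    if isinstance(params, STEDPSFParams):
        doc = {
            "model": "sted",
            "sigma_r_nm": params.sigma_r,
            "sigma_z_nm": params.sigma_z,
            "psi_per_nm": params.psi,
            "saturation": params.saturation,
        }
    else:
        doc = {
            "model": "gaussian",
            "sigma_r_nm": params.sigma_r,
            "sigma_z_nm": params.sigma_z,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_psf_params(path) -> GaussianPSFParams | STEDPSFParams:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = doc.get("model")
    if model == "gaussian":
        return GaussianPSFParams(
            sigma_r=float(doc["sigma_r_nm"]),
            sigma_z=None if doc.get("sigma_z_nm") is None else float(doc["sigma_z_nm"]),
        )
    if model == "sted":
        return STEDPSFParams(
            sigma_r=float(doc["sigma_r_nm"]),
            psi=float(doc["psi_per_nm"]),
            saturation=float(doc["saturation"]),
            sigma_z=None if doc.get("sigma_z_nm") is None else float(doc["sigma_z_nm"]),
        )
    raise PSFParameterError(f"unknown PSF model {model!r} in {path}")


def write_kernel_tiff(path, kernel: PSFKernel) -> None:
    import tifffile

    tifffile.imwrite(path, kernel.values.astype(np.float32))


def read_kernel_tiff(
    path, pixel_size: Sequence[float], normalization_mode: NormalizationMode = "sum_to_one"
) -> PSFKernel:
    import tifffile

    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    kernel = PSFKernel(values, tuple(pixel_size), "peak_preserving")
    if normalization_mode == "sum_to_one":
        return kernel.normalized()
    return kernel
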