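"""Pseudo-random microtubule-network phantoms.

Ground-truth objects mimic the microtubule cytoskeleton of a cell: a fixed
number of filaments start at uniform random positions, each grows step by
step in a direction that performs a wrapped-Gaussian random walk (turning
angle standard deviation 1/sqrt(direction_persistence) per step), and stops
when it leaves the arena or exhausts its length budget.  Each filament is a
tube of fixed radius (30 nm by default — the immunolabelled microtubule
scale) carrying a uniform random intensity in [0, 1], modelling
heterogeneous labelling density between filaments.  Overlapping tubes add,
since photon emission densities are additive.

Tubes are rasterized by supersampled distance-to-centerline coverage, so at
20 nm pixels a 30 nm-radius filament spans about three pixels across with
partial-coverage edges.

The default filament count scales with the arena area (constant filament
concentration), so the structural statistics of the phantom — and with them
the optimal iteration counts of the solvers — do not depend on image size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FilamentNetworkConfig",
    "Phantom",
    "generate_network",
    "rasterize_tube",
    "filament_count_for_area",
]

# default filament concentration: filaments per square micron of arena
DEFAULT_DENSITY_PER_UM2 = 0.6


class PhantomGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class FilamentNetworkConfig:
    """Configuration of the filament growth process.

    ``shape`` is (ny, nx) or (nz, ny, nx) in pixels; ``pixel_size`` nm per
    axis.  ``n_filaments = None`` derives the count from the arena area at
    the default concentration.  ``direction_persistence`` is the
    concentration of the turning-angle distribution: per-step turning-angle
    std = 1/sqrt(persistence) radians.  ``length_budget`` is the maximum
    filament length in nm.
    """

    shape: tuple[int, ...]
    pixel_size: tuple[float, ...]
    n_filaments: int | None = None
    radius: float = 30.0
    step_length: float = 40.0
    direction_persistence: float = 100.0
    intensity_range: tuple[float, float] = (0.0, 1.0)
    length_budget: float = 3000.0
    supersample: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3) or len(self.pixel_size) != len(self.shape):
            raise PhantomGeometryError("shape and pixel_size must be matched 2D/3D")
        if any(s <= 0 for s in self.shape) or any(p <= 0 for p in self.pixel_size):
            raise PhantomGeometryError("zero-area arena")
        if self.radius <= 0 or self.step_length <= 0 or self.length_budget <= 0:
            raise ValueError("radius, step_length and length_budget must be > 0")
        if self.n_filaments is not None and self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")
        lo, hi = self.intensity_range
        if not (0 <= lo <= hi):
            raise ValueError("intensity_range must satisfy 0 <= lo <= hi")

    @property
    def arena_nm(self) -> tuple[float, ...]:
        return tuple(s * p for s, p in zip(self.shape, self.pixel_size))

    def resolved_filaments(self) -> int:
        if self.n_filaments is not None:
            return self.n_filaments
        return filament_count_for_area(self.shape, self.pixel_size)


def filament_count_for_area(
    shape: Sequence[int],
    pixel_size: Sequence[float],
    density_per_um2: float = DEFAULT_DENSITY_PER_UM2,
) -> int:
    """Filament count proportional to lateral arena area (constant
    concentration across image sizes)."""
    ny, nx = shape[-2], shape[-1]
    py, px = pixel_size[-2], pixel_size[-1]
    area_um2 = (ny * py * 1e-3) * (nx * px * 1e-3)
    return max(1, round(density_per_um2 * area_um2))


@dataclass
class Phantom:
    """Ground-truth photon-emission density map plus filament metadata."""

    values: np.ndarray
    filaments: list[dict]
    config: FilamentNetworkConfig


def _reflect(pos: np.ndarray, direction: np.ndarray, bounds) -> None:
    """Reflect position and direction at the arena walls, in place.

    Filaments bounce instead of being truncated so every filament realizes
    its full length budget; this keeps the filament concentration (nonzero
    pixel fraction) independent of the arena size when the filament count
    scales with area.
    """
    for d, L in enumerate(bounds):
        if pos[d] < 0:
            pos[d] = -pos[d]
            direction[d] = -direction[d]
        elif pos[d] >= L:
            pos[d] = 2 * L - pos[d] - 1e-9
            direction[d] = -direction[d]


def _grow_filament_2d(rng, config) -> np.ndarray:
    """One filament centreline in nm coordinates (y, x)."""
    bounds = (config.arena_nm[-2], config.arena_nm[-1])
    pos = np.array([rng.uniform(0, bounds[0]), rng.uniform(0, bounds[1])])
    angle = rng.uniform(0, 2 * math.pi)
    v = np.array([math.sin(angle), math.cos(angle)])
    turn_std = 1.0 / math.sqrt(config.direction_persistence)
    n_steps = max(1, int(config.length_budget / config.step_length))
    points = [pos.copy()]
    for _ in range(n_steps):
        angle = math.atan2(v[0], v[1]) + rng.normal(0.0, turn_std)
        v = np.array([math.sin(angle), math.cos(angle)])
        pos = pos + config.step_length * v
        _reflect(pos, v, bounds)
        points.append(pos.copy())
    return np.asarray(points)


def _grow_filament_3d(rng, config) -> np.ndarray:
    """3D growth: direction performs a small random rotation per step."""
    bounds = config.arena_nm
    pos = np.array([rng.uniform(0, b) for b in bounds])
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    turn_std = 1.0 / math.sqrt(config.direction_persistence)
    n_steps = max(1, int(config.length_budget / config.step_length))
    points = [pos.copy()]
    for _ in range(n_steps):
        v = v + rng.normal(0.0, turn_std, size=3)
        v /= np.linalg.norm(v)
        pos = pos + config.step_length * v
        _reflect(pos, v, bounds)
        points.append(pos.copy())
    return np.asarray(points)


def rasterize_tube(
    polyline: np.ndarray,
    radius: float,
    intensity: float,
    shape: Sequence[int],
    pixel_size: Sequence[float],
    supersample: int = 4,
) -> np.ndarray:
    """Rasterize a tube of given radius around a centreline polyline.

    ``polyline`` is (n_points, ndim) in nm, axis order matching ``shape``.
    Pixel values are intensity times the supersampled coverage fraction of
    the tube cross-section, so edge pixels are partial.  An empty polyline
    yields an all-zero array.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    shape = tuple(shape)
    out = np.zeros(shape, dtype=np.float64)
    pts = np.asarray(polyline, dtype=np.float64)
    if pts.size == 0 or intensity == 0:
        return out
    if pts.ndim != 2 or pts.shape[1] != len(shape):
        raise ValueError("polyline must be (n, ndim) matching shape")
    px = np.asarray(pixel_size, dtype=np.float64)
    ss = int(supersample)

    # coverage accumulated on one boolean supersampled mask, so overlap
    # between segments of the same filament does not double-count
    global_mask = np.zeros(tuple(s * ss for s in shape), dtype=bool)
    segs = list(zip(pts[:-1], pts[1:])) if len(pts) > 1 else [(pts[0], pts[0])]
    for a, b in segs:
        lo_nm = np.minimum(a, b) - radius
        hi_nm = np.maximum(a, b) + radius
        lo_idx = np.maximum(np.floor(lo_nm / px).astype(int), 0)
        hi_idx = np.minimum(np.ceil(hi_nm / px).astype(int) + 1, np.asarray(shape))
        if np.any(lo_idx >= hi_idx):
            continue
        # supersampled sample coordinates (centres of subpixels), per axis
        grids = [
            (np.arange(lo_idx[d] * ss, hi_idx[d] * ss) + 0.5) * (px[d] / ss)
            for d in range(len(shape))
        ]
        mesh = np.meshgrid(*grids, indexing="ij")
        p = np.stack([m.ravel() for m in mesh], axis=1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            t = np.zeros(len(p))
        else:
            t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
        closest = a + t[:, None] * ab
        dist2 = ((p - closest) ** 2).sum(axis=1)
        inside = (dist2 <= radius**2).reshape([g.size for g in grids])
        slices = tuple(
            slice(lo_idx[d] * ss, lo_idx[d] * ss + inside.shape[d])
            for d in range(len(shape))
        )
        global_mask[slices] |= inside

    # downsample: mean over ss^ndim blocks = coverage fraction
    view = global_mask.astype(np.float64)
    for d in range(len(shape)):
        view = view.reshape(
            view.shape[:d] + (shape[d], ss) + view.shape[d + 1:]
        ).mean(axis=d + 1)
    out = intensity * view
    return out


def generate_network(config: FilamentNetworkConfig) -> Phantom:
    """Grow and rasterize a filament network; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    if len(config.shape) == 3 and config.shape[0] == 1:
        # a singleton axial axis is a 2D problem: grow and rasterize in-plane
        flat = FilamentNetworkConfig(
            shape=config.shape[1:],
            pixel_size=config.pixel_size[1:],
            n_filaments=config.n_filaments,
            radius=config.radius,
            step_length=config.step_length,
            direction_persistence=config.direction_persistence,
            intensity_range=config.intensity_range,
            length_budget=config.length_budget,
            supersample=config.supersample,
            seed=config.seed,
        )
        inner = generate_network(flat)
        return Phantom(inner.values[np.newaxis, ...], inner.filaments, config)
    n = config.resolved_filaments()
    ndim = len(config.shape)
    values = np.zeros(config.shape, dtype=np.float64)
    filaments: list[dict] = []
    lo, hi = config.intensity_range
    for _ in range(n):
        poly = (
            _grow_filament_2d(rng, config)
            if ndim == 2
            else _grow_filament_3d(rng, config)
        )
        intensity = float(rng.uniform(lo, hi))
        tube = rasterize_tube(
            poly, config.radius, intensity, config.shape, config.pixel_size,
            config.supersample,
        )
        values += tube  # overlapping filaments add photon density
        filaments.append({"polyline_nm": poly, "intensity": intensity})
    return Phantom(values=values, filaments=filaments, config=config)
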