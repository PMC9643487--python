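"""Synthetic inputs with known ground truth.

Everything downstream is exercised on landscapes and nuclide depth profiles
generated here: a shelf-and-archipelago landscape template (ocean in the
west, a lowland corridor in the centre, rough highlands in the east, one
interior depression), nuclide depth profiles drawn from the burial-dating
forward model, and a corridor resistance fixture for the walker.

Generators are pure functions of their scenario (seed included), so every
fixture is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import TerrainGrid
from . import tcn

__all__ = [
    "LandscapeScenario",
    "ProfileScenario",
    "make_landscape",
    "make_profiles",
    "make_fixture_resistance",
]


def _smoothed_noise(rng: np.random.Generator, shape, passes: int = 4, size: int = 9):
    """Gaussian white noise smoothed by an iterated uniform (box) filter,
    rescaled to unit standard deviation."""
    f = rng.standard_normal(shape)
    for _ in range(passes):
        f = ndimage.uniform_filter(f, size=size, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


@dataclass(frozen=True)
class LandscapeScenario:
    """Parameters of the synthetic shelf landscape.

    The template places the ocean along the western margin, a gently ramping
    lowland corridor through the centre, and steep highlands in the east;
    a closed depression is carved in the eastern corridor flank so that
    flow routing always meets at least one endorheic lake.
    """

    seed: int = 0
    nrows: int = 200
    ncols: int = 200
    cell_size: float = 1000.0  # m
    sea_level: float = -30.0  # m, Early Pleistocene highstand
    relief_amplitude: float = 300.0  # m, shelf ramp total rise
    uplift_pattern: str = "uniform"  # uniform | tilted | dome
    uplift_scale: float = 1.0e-4  # m/yr
    precip_mean: float = 2.0  # m/yr, humid tropics
    precip_gradient: float = 0.3  # fractional change across the domain height

    def __post_init__(self) -> None:
        if self.relief_amplitude <= 0 or self.precip_mean <= 0:
            raise ValueError("relief_amplitude and precip_mean must be positive")
        if self.uplift_pattern not in ("uniform", "tilted", "dome"):
            raise ValueError(f"unknown uplift_pattern {self.uplift_pattern!r}")


def make_landscape(
    scenario: LandscapeScenario,
) -> tuple[TerrainGrid, TerrainGrid, TerrainGrid]:
    """Generate (elevation, uplift, precipitation) grids for a scenario."""
    sc = scenario
    if sc.nrows < 16 or sc.ncols < 16:
        raise ValueError("landscape grids must be at least 16x16")
    rng = np.random.default_rng(sc.seed)
    y, x = np.mgrid[0 : sc.nrows, 0 : sc.ncols]
    xf = x / (sc.ncols - 1)  # 0 west -> 1 east
    yf = y / (sc.nrows - 1)  # 0 south -> 1 north

    # Long-wavelength shelf ramp: ocean floor in the west rising eastward
    # across sea level; the western ~30% of the domain stays submerged.
    z = sc.relief_amplitude * (xf - 0.30) / 0.70 + sc.sea_level

    # Eastern highlands: a smooth rise that puts slopes well above the
    # costless threshold on its rough flanks.
    mountain = np.clip((xf - 0.68) / 0.32, 0.0, 1.0) ** 2
    z = z + 8.0 * sc.relief_amplitude * mountain

    # Stochastic relief, rougher where the mountains rise.
    noise = _smoothed_noise(rng, (sc.nrows, sc.ncols))
    z = z + 0.12 * sc.relief_amplitude * noise * (1.0 + 8.0 * mountain)

    # One guaranteed interior depression on the corridor's eastern flank.
    r2 = ((xf - 0.62) / 0.05) ** 2 + ((yf - 0.72) / 0.06) ** 2
    z = z - 0.6 * sc.relief_amplitude * np.exp(-r2)

    elevation = TerrainGrid(z, sc.cell_size, variable="elevation")

    if sc.uplift_pattern == "uniform":
        u = np.full_like(z, sc.uplift_scale)
    elif sc.uplift_pattern == "tilted":
        u = sc.uplift_scale * xf
    else:  # dome
        u = sc.uplift_scale * np.exp(-(((xf - 0.5) ** 2 + (yf - 0.5) ** 2) / 0.08))
    uplift = TerrainGrid(u, sc.cell_size, variable="uplift")

    p = sc.precip_mean * (1.0 + sc.precip_gradient * (yf - 0.5))
    precipitation = TerrainGrid(p, sc.cell_size, variable="precipitation")
    return elevation, uplift, precipitation


@dataclass(frozen=True)
class ProfileScenario:
    """Ground truth for a synthetic nuclide depth profile.

    Defaults emulate the dated Javanese section: 15 depths over the upper
    6 m, a shared burial age of 1.78 Ma, per-sample source denudation in
    21-80 m/Ma, fast shared post-burial denudation of 436 m/Ma, and 5%
    relative (1-sigma) lognormal measurement noise.
    """

    seed: int = 0
    n_samples: int = 15
    depths: tuple[float, ...] | None = None  # m; default linspace(0.2, 5.8)
    true_burial_age: float = 1.78e6  # yr
    true_pre_denudation: tuple[float, ...] | None = None  # m/Ma, per sample
    pre_denudation_range: tuple[float, float] = (21.0, 80.0)
    true_post_denudation: float = 436.0  # m/Ma
    site_latitude: float = -7.466
    site_elevation: float = 99.0
    relative_noise: float = 0.05

    def resolved_depths(self) -> np.ndarray:
        if self.depths is not None:
            d = np.asarray(self.depths, dtype=float)
        else:
            d = np.linspace(0.2, 5.8, self.n_samples)
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        return d

    def __post_init__(self) -> None:
        if self.true_burial_age < 0:
            raise ValueError("burial age must be nonnegative")
        if self.true_post_denudation < 0:
            raise ValueError("denudation rates must be nonnegative")
        self.resolved_depths()


def make_profiles(
    scenario: ProfileScenario, constants: tcn.NuclideConstants | None = None
) -> pd.DataFrame:
    """Generate a synthetic nuclide sample table.

    Noiseless concentrations come from the burial forward model at the
    scenario's true parameters; measurements are multiplied by lognormal
    noise with the stated relative 1-sigma, and reported sigmas are
    relative_noise times the noiseless value.  Truth columns are carried
    along for recovery tests.
    """
    sc = scenario
    constants = constants or tcn.NuclideConstants()
    rng = np.random.default_rng(sc.seed)
    depths = sc.resolved_depths()
    n = len(depths)
    if sc.true_pre_denudation is not None:
        eps = np.asarray(sc.true_pre_denudation, dtype=float)
        if len(eps) != n:
            raise ValueError("true_pre_denudation length must match depths")
    else:
        lo, hi = sc.pre_denudation_range
        eps = rng.uniform(lo, hi, size=n)
    site = tcn.SiteContext(sc.site_latitude, sc.site_elevation)
    N10, N26 = tcn.forward_concentrations(
        depths, sc.true_burial_age, eps, sc.true_post_denudation, site, constants
    )
    if sc.relative_noise > 0:
        sd = sc.relative_noise
        noise10 = np.exp(rng.normal(0.0, sd, size=n))
        noise26 = np.exp(rng.normal(0.0, sd, size=n))
    else:
        noise10 = noise26 = np.ones(n)
    return pd.DataFrame(
        {
            "sample_id": [f"SYN-{i + 1}" for i in range(n)],
            "depth_m": depths,
            "N10_at_g": N10 * noise10,
            "N10_sigma": np.maximum(sc.relative_noise, 1e-6) * N10,
            "N26_at_g": N26 * noise26,
            "N26_sigma": np.maximum(sc.relative_noise, 1e-6) * N26,
            "true_N10_at_g": N10,
            "true_N26_at_g": N26,
            "true_burial_age_yr": sc.true_burial_age,
            "true_pre_denudation_m_per_Ma": eps,
            "true_post_denudation_m_per_Ma": sc.true_post_denudation,
        }
    )


def make_fixture_resistance(seed: int, nrows: int, ncols: int) -> TerrainGrid:
    """Resistance fixture: a full-height barrier wall with one open corridor.

    Background resistance is a smooth random field in [0, 0.4]; a vertical
    barrier strip of 1.0 spans the grid at mid-width except for a short,
    low-cost corridor at a seeded row, so exactly one cheap passage connects
    the left and right halves.
    """
    if nrows < 16 or ncols < 16:
        raise ValueError("fixture grids must be at least 16x16")
    rng = np.random.default_rng(seed)
    base = _smoothed_noise(rng, (nrows, ncols), passes=3, size=5)
    base = 0.2 + 0.2 * np.tanh(base)  # smooth, in (0, 0.4)
    wall_lo = ncols // 2 - 1
    wall_hi = ncols // 2 + 2
    gap_row = int(rng.integers(nrows // 4, 3 * nrows // 4))
    gap = slice(max(gap_row - 2, 0), min(gap_row + 3, nrows))
    values = base.copy()
    values[:, wall_lo:wall_hi] = 1.0
    values[gap, wall_lo:wall_hi] = 0.05
    return TerrainGrid(values, cell_size=1000.0, variable="resistance")
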