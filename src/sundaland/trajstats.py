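"""Ensemble statistics: distances, travel times, success rates, occupancy.

Travel times convert distances with the hunter-gatherer speed scenarios
(slow 1, medium 5, fast 10 km/yr).  Occupancy is a cost-weighted,
Gaussian-smoothed kernel density of the cells visited by successful
realizations, normalized to integrate to 1 over non-barrier cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from statsmodels.stats.proportion import proportion_confint

from .grids import TerrainGrid
from .walk import Trajectory, WalkEnsemble

__all__ = [
    "SpeedScenario",
    "SPEED_SCENARIOS",
    "OccupancyDensity",
    "travel_distance",
    "travel_time",
    "success_rate",
    "occupancy_kde",
    "ensemble_report",
]


@dataclass(frozen=True)
class SpeedScenario:
    """A named migration speed (km/yr)."""

    name: str
    speed: float

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError("speed must be positive")


SPEED_SCENARIOS = {
    "slow": SpeedScenario("slow", 1.0),
    "medium": SpeedScenario("medium", 5.0),
    "fast": SpeedScenario("fast", 10.0),
}


def travel_distance(trajectory: Trajectory) -> float:
    """Travelled distance in km, summed to first goal entry (or full path)."""
    pos = trajectory.positions
    if len(pos) < 2:
        raise ValueError("trajectory needs at least two positions")
    end = (
        trajectory.steps_to_goal + 1
        if trajectory.reached_goal and trajectory.steps_to_goal is not None
        else len(pos)
    )
    seg = np.diff(pos[:end], axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum()) / 1000.0


def travel_time(distance_km: float, scenario: SpeedScenario) -> float:
    """Travel time in kyr for a distance (km) at the scenario speed (km/yr)."""
    if distance_km < 0:
        raise ValueError("distance must be nonnegative")
    return distance_km / scenario.speed / 1000.0


def success_rate(ensemble: WalkEnsemble) -> tuple[float, tuple[float, float]]:
    """Fraction of realizations reaching the goal, with a Wilson 95% CI."""
    n = ensemble.n_realizations
    if n < 1:
        raise ValueError("empty ensemble")
    k = ensemble.n_success
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(lo), float(hi))


@dataclass
class OccupancyDensity:
    """Normalized occupancy surface (integrates to 1 over non-barrier cells)."""

    density: TerrainGrid
    bandwidth: float
    weighting: str

    def integral(self) -> float:
        cs = self.density.cell_size
        return float(self.density.values[self.density.mask_valid].sum()) * cs * cs


def occupancy_kde(
    ensemble: WalkEnsemble,
    resistance: TerrainGrid | None = None,
    bandwidth: float | None = None,
    weighting: str = "one-minus-cost",
) -> OccupancyDensity:
    """Cost-weighted kernel density of visits by successful realizations.

    Visit counts are multiplied by a decreasing function of the local cost
    ("one-minus-cost" gives weight 1 - cost; "inverse-offset" gives
    1 / (cost + 0.05)), smoothed with an isotropic Gaussian kernel of the
    given bandwidth (default two cell widths), zeroed on barrier cells, and
    normalized so the density integrates to 1.
    """
    resistance = resistance if resistance is not None else ensemble.grid
    if ensemble.n_success < 1:
        raise ValueError("occupancy requires at least one successful realization")
    if bandwidth is None:
        bandwidth = 2.0 * resistance.cell_size
    cost = np.where(resistance.mask_valid, resistance.values, 1.0)
    barrier = cost >= 1.0
    if weighting == "one-minus-cost":
        w = 1.0 - cost
    elif weighting == "inverse-offset":
        w = 1.0 / (cost + 0.05)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    field = ensemble.visit_counts * w
    field = ndimage.gaussian_filter(field, sigma=bandwidth / resistance.cell_size)
    field[barrier] = 0.0
    cs = resistance.cell_size
    total = field.sum() * cs * cs
    if total <= 0:
        raise ValueError("occupancy field vanished after masking barriers")
    return OccupancyDensity(
        density=resistance.like(field / total, variable="occupancy"),
        bandwidth=bandwidth,
        weighting=weighting,
    )


def ensemble_report(
    ensemble: WalkEnsemble,
    scenarios: dict[str, SpeedScenario] | None = None,
) -> dict:
    """Summary statistics of an ensemble as a JSON-serializable dict."""
    scenarios = scenarios or SPEED_SCENARIOS
    rate, (lo, hi) = success_rate(ensemble)
    ok = ensemble.success
    dist_km = ensemble.distance_m / 1000.0
    out = {
        "n_realizations": int(ensemble.n_realizations),
        "n_success": int(ensemble.n_success),
        "success_rate": rate,
        "success_ci95": [lo, hi],
        "distance_km": {
            "successful_mean": float(dist_km[ok].mean()) if ok.any() else None,
            "successful_quantiles": (
                {
                    q: float(np.quantile(dist_km[ok], float(q)))
                    for q in ("0.05", "0.5", "0.95")
                }
                if ok.any()
                else None
            ),
            "censored_mean_unsuccessful": (
                float(dist_km[~ok].mean()) if (~ok).any() else None
            ),
        },
    }
    if ok.any():
        mean_km = float(dist_km[ok].mean())
        out["travel_time_kyr"] = {
            name: travel_time(mean_km, sc) for name, sc in scenarios.items()
        }
    return out
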