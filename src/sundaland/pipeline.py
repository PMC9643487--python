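"""End-to-end corridor experiment on the synthetic shelf landscape.

This orchestrates the full chain at desk scale: generate the shelf
landscape, evolve it for 10 kyr with the landscape evolution model, convert
the physiography to a resistance surface, then move walkers from three
northern entry points toward a southern goal, reporting least-cost paths,
ensemble success statistics, and the cost-weighted occupancy density.

Scale notes: the synthetic domain is a 200 km miniature of a continental
shelf, so the Niger-scale river-crossing threshold of the full-scale cost
model would select no rivers here; the experiment uses a 50 m3/s threshold
(which picks out the trunk streams of the miniature drainage) and maps the
domain-maximum discharge to the maximum river cost.  Entry and goal sites
are fixed positions on the landscape template's lowland corridor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lem, resistance, synthetic, trajstats, walk
from .grids import PointSite, TerrainGrid

__all__ = ["CorridorExperiment", "CorridorResult", "run_corridor_experiment"]

#: entry points on the northern lowlands and goal on the southern corridor
#: (metres; fixed fixture design for the default landscape template)
ENTRY_POINTS = (
    PointSite(85_000.0, 180_000.0, "west"),
    PointSite(110_000.0, 185_000.0, "central"),
    PointSite(135_000.0, 180_000.0, "east"),
)
GOAL = PointSite(105_000.0, 40_000.0, "goal")


@dataclass(frozen=True)
class CorridorExperiment:
    """Configuration of the scaled-down dispersal experiment."""

    seed: int = 3
    nrows: int = 200
    ncols: int = 200
    n_walkers: int = 100  # per entry point
    max_steps: int = 200_000
    goal_radius: float = 10_000.0  # m
    lem_duration: float = 10_000.0  # yr
    river_threshold: float = 50.0  # m3/s, miniature-domain trunk streams


@dataclass
class CorridorResult:
    elevation: TerrainGrid
    resistance: TerrainGrid
    lcp: dict[str, walk.LeastCostPath]
    ensembles: dict[str, walk.WalkEnsemble]
    combined: walk.WalkEnsemble
    occupancy: trajstats.OccupancyDensity

    def report(self) -> dict:
        rate, ci = trajstats.success_rate(self.combined)
        per_entry = {
            name: trajstats.ensemble_report(ens) for name, ens in self.ensembles.items()
        }
        ok = self.combined.success
        mean_km = (
            float(self.combined.distance_m[ok].mean() / 1000.0) if ok.any() else None
        )
        return {
            "success_rate": rate,
            "success_ci95": list(ci),
            "per_entry": per_entry,
            "lcp_length_km": {
                name: p.length_m / 1000.0 for name, p in self.lcp.items()
            },
            "mean_successful_distance_km": mean_km,
        }


def run_corridor_experiment(
    config: CorridorExperiment = CorridorExperiment(),
    walker_seed: int = 0,
) -> CorridorResult:
    """Run the full synthetic pipeline and return all stage outputs."""
    scenario = synthetic.LandscapeScenario(
        seed=config.seed, nrows=config.nrows, ncols=config.ncols
    )
    elev0, uplift, precip = synthetic.make_landscape(scenario)
    params = lem.LemParams(duration=config.lem_duration)
    elev, flow, _ = lem.run_lem(elev0, uplift, precip, params)
    cost_params = resistance.CostParams(river_threshold=config.river_threshold)
    res = resistance.build_resistance(elev, flow, cost_params, auto_cap=True)

    lcps: dict[str, walk.LeastCostPath] = {}
    ensembles: dict[str, walk.WalkEnsemble] = {}
    combined: walk.WalkEnsemble | None = None
    for i, entry in enumerate(ENTRY_POINTS):
        lcps[entry.label] = walk.least_cost_path(res, entry, GOAL)
        wp = walk.WalkerParams(seed=walker_seed + 7919 * i, max_steps=config.max_steps)
        ens = walk.batch_simulate(
            res,
            entry,
            GOAL,
            n_realizations=config.n_walkers,
            params=wp,
            goal_radius=config.goal_radius,
        )
        ensembles[entry.label] = ens
        combined = ens if combined is None else combined.concat(ens)

    occupancy = trajstats.occupancy_kde(combined, res)
    return CorridorResult(
        elevation=elev,
        resistance=res,
        lcp=lcps,
        ensembles=ensembles,
        combined=combined,
        occupancy=occupancy,
    )
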