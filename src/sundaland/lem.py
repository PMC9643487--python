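"""Minimal landscape evolution: uplift, soil-creep diffusion, and
precipitation-modulated stream-power incision, with D8 flow routing.

The governing mass-continuity equation is

    dz/dt = U + kappa * laplacian(z) - eps * P^d * (PA)^m * S^n

with z elevation (m), U uplift (m/yr), kappa the hillslope diffusion
coefficient (m2/yr), P local precipitation (m/yr), PA the accumulated water
flux (m3/yr), S the downstream slope, and n fixed at 1 so the incision term
can be integrated implicitly along donor-receiver chains (unconditionally
stable).  Erosion lowers elevation; the eroded flux is captured by endorheic
lakes (deposited uniformly over the lake surface) or exported through the
ocean, whose cells are held fixed as the base-level boundary condition.

Defaults follow the Sundaland reconstruction: kappa 5e-3 m2/yr, erodibility
4e-6, m 0.5, n 1, precipitation exponent d 0.42, sea level -30 m, a 10-kyr
run.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import TerrainGrid

__all__ = [
    "LemParams",
    "FlowField",
    "StabilityError",
    "restore_paleoelevation",
    "route_flow",
    "run_lem",
    "water_bodies",
    "SECONDS_PER_YEAR",
]

SECONDS_PER_YEAR = 3.15576e7  # Julian year


class StabilityError(RuntimeError):
    """Explicit diffusion step violates the CFL bound."""


@dataclass(frozen=True)
class LemParams:
    kappa: float = 5.0e-3  # m2/yr soil creep
    erodibility: float = 4.0e-6  # stream-power coefficient (PA in m3/yr)
    m_exp: float = 0.5
    n_exp: float = 1.0
    d_exp: float = 0.42
    sea_level: float = -30.0  # m
    duration: float = 10_000.0  # yr
    dt: float = 100.0  # yr
    closed_boundaries: bool = False

    def __post_init__(self) -> None:
        for name in ("kappa", "erodibility", "m_exp", "d_exp", "duration", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_exp != 1.0:
            raise ValueError("only n_exp = 1 is supported (linear implicit solver)")


@dataclass
class FlowField:
    """D8 receivers, water-flux accumulation, and water-body masks.

    ``receiver`` holds, per cell (flattened row-major index), the index of
    the steepest downslope neighbour; pits, lake cells, and ocean cells are
    their own receivers.  ``discharge`` is in m3/s.
    """

    receiver: np.ndarray
    discharge: TerrainGrid
    lake_mask: TerrainGrid
    ocean_mask: TerrainGrid

    @property
    def shape(self) -> tuple[int, int]:
        return self.discharge.values.shape


def restore_paleoelevation(
    modern_dem: TerrainGrid, uplift: TerrainGrid, age: float
) -> TerrainGrid:
    """Back-strip vertical motion: z_paleo = z_modern - uplift * age."""
    if not modern_dem.congruent_with(uplift):
        raise ValueError("DEM and uplift grids are not congruent")
    z = modern_dem.values - uplift.values * age
    z = np.where(modern_dem.mask_valid & uplift.mask_valid, z, modern_dem.nodata)
    return modern_dem.like(z, variable="elevation")


# ---------------------------------------------------------------------------
# Routing internals
# ---------------------------------------------------------------------------

_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _ocean_mask(z: np.ndarray, sea_level: float, closed: bool) -> np.ndarray:
    """Cells at/below sea level connected (8-neighbour) to the grid edge."""
    below = z <= sea_level
    if closed or not below.any():
        return np.zeros_like(below)
    labels, _ = ndimage.label(below, structure=np.ones((3, 3), dtype=int))
    edge_labels = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    edge_labels = edge_labels[edge_labels != 0]
    return np.isin(labels, edge_labels)


def _priority_fill(z: np.ndarray, ocean: np.ndarray, closed: bool) -> np.ndarray:
    """Priority-flood fill level of every cell (>= z; > z inside depressions)."""
    nr, nc = z.shape
    fill = np.full_like(z, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    seeds = ocean.copy()
    if not closed:
        seeds[0], seeds[-1], seeds[:, 0], seeds[:, -1] = True, True, True, True
    if not seeds.any():
        seeds[np.unravel_index(np.argmin(z), z.shape)] = True
    for r, c in zip(*np.nonzero(seeds)):
        fill[r, c] = z[r, c]
        heapq.heappush(heap, (z[r, c], int(r), int(c)))
        visited[r, c] = True
    while heap:
        level, r, c = heapq.heappop(heap)
        for dr, dc in _D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                visited[rr, cc] = True
                fill[rr, cc] = max(z[rr, cc], level)
                heapq.heappush(heap, (fill[rr, cc], rr, cc))
    return fill


def _receivers(z: np.ndarray, ocean: np.ndarray, cell_size: float) -> np.ndarray:
    """Steepest-descent D8 receiver per cell on the raw surface.

    Pits (no lower neighbour) and ocean cells are their own receivers, so
    interior depressions behave endorheically: flow entering one terminates
    at its pit instead of crossing the rim.
    """
    nr, nc = z.shape
    zp = np.pad(z, 1, mode="constant", constant_values=np.inf)
    best_grad = np.zeros((nr, nc))
    best_idx = np.arange(nr * nc).reshape(nr, nc).copy()
    flat = np.arange(nr * nc).reshape(nr, nc)
    for dr, dc in _D8:
        zn = zp[1 + dr : 1 + dr + nr, 1 + dc : 1 + dc + nc]
        dist = cell_size * (math.sqrt(2.0) if dr and dc else 1.0)
        with np.errstate(invalid="ignore"):
            grad = (z - zn) / dist
        rn = np.clip(np.arange(nr)[:, None] + dr, 0, nr - 1)
        cn = np.clip(np.arange(nc)[None, :] + dc, 0, nc - 1)
        idx_n = flat[rn, cn]
        better = grad > best_grad
        best_grad = np.where(better, grad, best_grad)
        best_idx = np.where(better, idx_n, best_idx)
    best_idx[ocean] = flat[ocean]
    return best_idx.ravel()


def _accumulate(
    z: np.ndarray, receiver: np.ndarray, ocean: np.ndarray, precip: np.ndarray,
    cell_area: float,
) -> np.ndarray:
    """Downstream accumulation of precipitation * area, in m3/yr."""
    acc = np.where(ocean, 0.0, precip * cell_area).ravel()
    order = np.argsort(-z.ravel(), kind="stable")
    rcv = receiver
    acc_flat = acc
    for c in order:
        r = rcv[c]
        if r != c:
            acc_flat[r] += acc_flat[c]
    return acc_flat.reshape(z.shape)


def _route(z: np.ndarray, precip: np.ndarray, cell_size: float, sea_level: float,
           closed: bool):
    ocean = _ocean_mask(z, sea_level, closed)
    fill = _priority_fill(z, ocean, closed)
    lake = (fill > z + 1e-9) & ~ocean
    receiver = _receivers(z, ocean, cell_size)
    acc = _accumulate(z, receiver, ocean, precip, cell_size * cell_size)
    return receiver, acc, ocean, lake


def route_flow(
    elevation: TerrainGrid, precipitation: TerrainGrid, params: LemParams
) -> FlowField:
    """D8 flow routing with endorheic lakes and ocean detection.

    Discharge accumulates precipitation times cell area downstream and is
    reported in m3/s.  Interior depressions (from priority-flood filling)
    are lakes; flow entering them terminates at their pits.
    """
    if not elevation.congruent_with(precipitation):
        raise ValueError("elevation and precipitation grids are not congruent")
    receiver, acc, ocean, lake = _route(
        elevation.values,
        precipitation.values,
        elevation.cell_size,
        params.sea_level,
        params.closed_boundaries,
    )
    return FlowField(
        receiver=receiver,
        discharge=elevation.like(acc / SECONDS_PER_YEAR, variable="discharge"),
        lake_mask=elevation.like(lake.astype(float), variable="lake"),
        ocean_mask=elevation.like(ocean.astype(float), variable="ocean"),
    )


def water_bodies(
    flow: FlowField, river_threshold: float
) -> tuple[TerrainGrid, TerrainGrid, TerrainGrid]:
    """(ocean, lakes, rivers) boolean grids; rivers are land cells whose
    discharge meets the threshold (m3/s)."""
    if river_threshold <= 0:
        raise ValueError("river threshold must be positive")
    ocean = flow.ocean_mask.values.astype(bool)
    lake = flow.lake_mask.values.astype(bool)
    rivers = (flow.discharge.values >= river_threshold) & ~ocean & ~lake
    g = flow.discharge
    return (
        g.like(ocean.astype(float), variable="ocean"),
        g.like(lake.astype(float), variable="lake"),
        g.like(rivers.astype(float), variable="river"),
    )


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def _diffuse(z: np.ndarray, kappa: float, dt: float, cell_size: float) -> np.ndarray:
    """Explicit no-flux (mass-conserving) diffusion step."""
    if kappa == 0:
        return z
    dt_max = cell_size * cell_size / (4.0 * kappa)
    if dt > dt_max:
        raise StabilityError(
            f"diffusion CFL violated: dt={dt} exceeds max admissible dt={dt_max:.1f}"
        )
    zp = np.pad(z, 1, mode="edge")
    lap = (
        zp[:-2, 1:-1] + zp[2:, 1:-1] + zp[1:-1, :-2] + zp[1:-1, 2:] - 4.0 * z
    ) / (cell_size * cell_size)
    return z + kappa * dt * lap


def run_lem(
    elevation: TerrainGrid,
    uplift: TerrainGrid,
    precipitation: TerrainGrid,
    params: LemParams,
) -> tuple[TerrainGrid, FlowField, dict]:
    """Integrate the landscape evolution equation over ``params.duration``.

    Per step: uplift (explicit, on non-ocean cells — the ocean is the fixed
    base level), hillslope diffusion (explicit, CFL-checked, no-flux edges),
    re-routing, then implicit stream-power incision ordered
    receiver-before-donor.  Incision applies to land cells only; eroded
    volume is deposited uniformly over lake cells (or exported via the
    ocean when no lake exists).  Returns the final elevation, the final
    flow field, and a mass-balance dictionary (m3).
    """
    for g in (uplift, precipitation):
        if not elevation.congruent_with(g):
            raise ValueError("input grids are not congruent")
    z = elevation.values.astype(float).copy()
    U = uplift.values
    P = precipitation.values
    cs = elevation.cell_size
    area = cs * cs
    n_steps = max(int(round(params.duration / params.dt)), 0)
    dt = params.dt
    balance = {"uplift_m3": 0.0, "eroded_m3": 0.0, "deposited_m3": 0.0, "exported_m3": 0.0}

    nr, nc = z.shape
    sqrt2 = math.sqrt(2.0)
    cols = np.arange(nr * nc) % nc
    rows_idx = np.arange(nr * nc) // nc

    for _ in range(n_steps):
        # ocean cells are the base-level boundary: no uplift, no incision
        ocean0 = _ocean_mask(z, params.sea_level, params.closed_boundaries)
        z = np.where(ocean0, z, z + U * dt)
        balance["uplift_m3"] += float(U[~ocean0].sum()) * dt * area
        z = _diffuse(z, params.kappa, dt, cs)

        receiver, acc, ocean, lake = _route(
            z, P, cs, params.sea_level, params.closed_boundaries
        )
        if params.erodibility > 0:
            k_cell = (
                params.erodibility
                * np.power(np.maximum(P, 0.0), params.d_exp)
                * np.power(acc, params.m_exp)
            ).ravel()
            zf = z.ravel()
            erodible = (~ocean & ~lake).ravel()
            order = np.argsort(zf, kind="stable")  # receivers before donors
            rcv = receiver
            z_before = zf.copy()
            for c in order:
                r = rcv[c]
                if r != c and erodible[c]:
                    dist = cs * (
                        sqrt2
                        if (rows_idx[c] != rows_idx[r] and cols[c] != cols[r])
                        else 1.0
                    )
                    F = dt * k_cell[c] / dist
                    zf[c] = (zf[c] + F * zf[r]) / (1.0 + F)
            eroded = float((z_before - zf).sum()) * area
            balance["eroded_m3"] += eroded
            z = zf.reshape(nr, nc)
            n_lake = int(lake.sum())
            if n_lake > 0 and eroded > 0:
                z[lake] += eroded / (n_lake * area)
                balance["deposited_m3"] += eroded
            else:
                balance["exported_m3"] += eroded

    flow = route_flow(
        elevation.like(z, variable="elevation"), precipitation, params
    )
    return elevation.like(z, variable="elevation"), flow, balance
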