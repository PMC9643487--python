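"""Movement across a resistance surface.

Two movement end-members are provided:

* :func:`least_cost_path` — Dijkstra shortest path on the 8-connected cell
  graph (the "omniscient traveller" reference solution);
* :func:`simulate_walk` / :func:`batch_simulate` — a two-state Markov
  walker that alternates between a strongly correlated travelling state and
  an uncorrelated exploratory state, senses the mean resistance along
  discrete heading rays within its perceptual range, slows down in costly
  terrain, and treats cost-1 cells as impassable.

The walker operates in continuous coordinates over the raster; headings are
discretized to ``n_headings`` directions shared by the wrapped-normal
turning kernel and the perceptual-range weighting.  Random-number
consumption is exactly two uniforms per step from a per-walker stream seeded
by ``master_seed XOR walker_index``, which makes every realization bitwise
reproducible independent of batch composition or execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .grids import PointSite, TerrainGrid

__all__ = [
    "WalkerParams",
    "Trajectory",
    "WalkEnsemble",
    "LeastCostPath",
    "least_cost_path",
    "wrapped_normal_pmf",
    "heading_weights",
    "simulate_walk",
    "batch_simulate",
]


@dataclass(frozen=True)
class WalkerParams:
    """Two-state walker parameters.

    State 0 is the correlated travelling state (wrapped-normal turning
    concentration 0.99), state 1 the uncorrelated exploratory state.  The
    stationary fraction of time in state 0 is
    ``switch_prob_21 / (switch_prob_12 + switch_prob_21)`` (1/6 at the
    defaults 0.01 and 0.002).
    """

    step_length: float = 100.0  # m
    turn_concentration: tuple[float, float] = (0.99, 0.0)
    switch_prob_12: float = 0.01  # travelling -> exploratory
    switch_prob_21: float = 0.002  # exploratory -> travelling
    perceptual_range: float = 5000.0  # m
    max_steps: int = 5_000_000
    n_headings: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.switch_prob_12, self.switch_prob_21):
            if not 0.0 <= p <= 1.0:
                raise ValueError("switch probabilities must lie in [0, 1]")
        for c in self.turn_concentration:
            if not 0.0 <= c <= 1.0:
                raise ValueError("turn concentration must lie in [0, 1]")
        if not self.step_length < self.perceptual_range:
            raise ValueError("step_length must be smaller than perceptual_range")
        if self.n_headings < 4:
            raise ValueError("need at least 4 discrete headings")


@dataclass
class Trajectory:
    """One walker realization: positions, per-step states, and goal status."""

    positions: np.ndarray  # (n_steps+1, 2) x, y in metres
    states: np.ndarray  # (n_steps+1,) 0 = correlated, 1 = random
    reached_goal: bool
    steps_to_goal: int | None
    seed: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(len(self.states)),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "state": self.states,
            }
        )


@dataclass
class WalkEnsemble:
    """Batch of walker realizations with per-realization summaries.

    ``visit_counts`` accumulates end-of-step cell visits of *successful*
    realizations only (the occupancy statistic downstream); distances and
    success flags cover every realization.
    """

    seeds: np.ndarray
    success: np.ndarray  # bool
    steps_to_goal: np.ndarray  # float, NaN when unsuccessful
    distance_m: np.ndarray  # travelled distance (to goal entry or full run)
    visit_counts: np.ndarray  # (nrows, ncols) over successful realizations
    grid: TerrainGrid  # geometry/resistance reference
    goal: PointSite | None
    goal_radius: float

    @property
    def n_realizations(self) -> int:
        return len(self.success)

    @property
    def n_success(self) -> int:
        return int(self.success.sum())

    @classmethod
    def from_trajectories(
        cls,
        trajectories: list[Trajectory],
        grid: TerrainGrid,
        goal: PointSite | None = None,
        goal_radius: float = float("inf"),
    ) -> "WalkEnsemble":
        counts = np.zeros(grid.values.shape, dtype=np.float64)
        dist = []
        for tr in trajectories:
            seg = np.diff(tr.positions, axis=0)
            dist.append(float(np.hypot(seg[:, 0], seg[:, 1]).sum()))
            if tr.reached_goal:
                for x, y in tr.positions:
                    r, c = grid.index_of(x, y)
                    counts[r, c] += 1
        return cls(
            seeds=np.array([tr.seed for tr in trajectories]),
            success=np.array([tr.reached_goal for tr in trajectories]),
            steps_to_goal=np.array(
                [tr.steps_to_goal if tr.steps_to_goal is not None else np.nan
                 for tr in trajectories],
                dtype=float,
            ),
            distance_m=np.array(dist),
            visit_counts=counts,
            grid=grid,
            goal=goal,
            goal_radius=goal_radius,
        )

    def concat(self, other: "WalkEnsemble") -> "WalkEnsemble":
        return WalkEnsemble(
            seeds=np.concatenate([self.seeds, other.seeds]),
            success=np.concatenate([self.success, other.success]),
            steps_to_goal=np.concatenate([self.steps_to_goal, other.steps_to_goal]),
            distance_m=np.concatenate([self.distance_m, other.distance_m]),
            visit_counts=self.visit_counts + other.visit_counts,
            grid=self.grid,
            goal=self.goal,
            goal_radius=self.goal_radius,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "realization": np.arange(self.n_realizations),
                "seed": self.seeds,
                "success": self.success,
                "steps_to_goal": self.steps_to_goal,
                "distance_m": self.distance_m,
            }
        )


# ---------------------------------------------------------------------------
# Least-cost path
# ---------------------------------------------------------------------------

@dataclass
class LeastCostPath:
    """Dijkstra result: traversed cells, geometric length, accumulated cost."""

    cells: np.ndarray  # (n, 2) row, col
    length_m: float
    total_cost: float
    reachable: bool

    def xy(self, grid: TerrainGrid) -> np.ndarray:
        return np.array([grid.cell_center(r, c) for r, c in self.cells])


_DIAG = math.sqrt(2.0)


def least_cost_path(
    resistance: TerrainGrid,
    start: PointSite,
    goal: PointSite,
    base_move_cost: float = 0.01,
) -> LeastCostPath:
    """Least-cost route between two sites over the resistance surface.

    Edge weight between 8-connected cells a, b is
    ``(mean(r_a, r_b) + base_move_cost) * metric`` with metric 1 for rook
    moves and sqrt(2) for diagonal moves (in cell units); ``base_move_cost``
    keeps paths shortest-distance on uniform surfaces.  Cells of resistance
    1.0 (or nodata) are excluded from the graph.
    """
    r = resistance.values
    nr, nc = r.shape
    passable = (r < 1.0) & resistance.mask_valid
    for site, name in ((start, "start"), (goal, "goal")):
        row, col = resistance.index_of(site.x, site.y)
        if not passable[row, col]:
            raise ValueError(f"{name} site {site.label!r} lies on a barrier cell")
    s_idx = np.ravel_multi_index(resistance.index_of(start.x, start.y), (nr, nc))
    g_idx = np.ravel_multi_index(resistance.index_of(goal.x, goal.y), (nr, nc))

    flat = np.arange(nr * nc).reshape(nr, nc)
    rows_e, cols_e, weights = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a_sl = (slice(max(0, -dr), nr - max(0, dr)), slice(max(0, -dc), nc - max(0, dc)))
        b_sl = (slice(max(0, dr), nr + min(0, dr)), slice(max(0, dc), nc + min(0, dc)))
        a, b = flat[a_sl].ravel(), flat[b_sl].ravel()
        ok = passable.ravel()[a] & passable.ravel()[b]
        metric = _DIAG if dr and dc else 1.0
        w = (0.5 * (r.ravel()[a] + r.ravel()[b]) + base_move_cost) * metric
        rows_e.append(a[ok])
        cols_e.append(b[ok])
        weights.append(w[ok])
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_e), np.concatenate(cols_e))),
        shape=(nr * nc, nr * nc),
    ).tocsr()
    dist, pred = _dijkstra(
        graph, directed=False, indices=s_idx, return_predecessors=True
    )
    if not np.isfinite(dist[g_idx]):
        return LeastCostPath(np.empty((0, 2), dtype=int), math.inf, math.inf, False)
    path = [g_idx]
    while path[-1] != s_idx:
        path.append(pred[path[-1]])
    path = np.array(path[::-1])
    cells = np.column_stack(np.unravel_index(path, (nr, nc)))
    steps = np.abs(np.diff(cells, axis=0))
    length = float(
        ((steps.max(axis=1) == 1) * np.where(steps.sum(axis=1) == 2, _DIAG, 1.0)).sum()
        * resistance.cell_size
    )
    return LeastCostPath(cells, length, float(dist[g_idx]), True)


# ---------------------------------------------------------------------------
# Walker
# ---------------------------------------------------------------------------

def wrapped_normal_pmf(n_headings: int, concentration: float) -> np.ndarray:
    """Wrapped-normal turning kernel over discrete headings.

    ``concentration`` is the mean resultant length rho in [0, 1]; the
    density 1 + 2 sum_p rho^(p^2) cos(p dtheta) is evaluated at the
    discrete turning angles and normalized to a pmf.  rho = 0 gives the
    uniform kernel, rho -> 1 concentrates all mass on "keep heading".
    """
    if not 0.0 <= concentration <= 1.0:
        raise ValueError("concentration must lie in [0, 1]")
    dtheta = 2.0 * math.pi * np.arange(n_headings) / n_headings
    if concentration >= 1.0:
        pmf = np.zeros(n_headings)
        pmf[0] = 1.0
        return pmf
    f = np.ones(n_headings)
    p = 1
    while p <= 400:
        coef = concentration ** (p * p)
        if coef < 1e-14:
            break
        f += 2.0 * coef * np.cos(p * dtheta)
        p += 1
    f = np.clip(f, 0.0, None)
    return f / f.sum()


def heading_weights(resistance: TerrainGrid, params: WalkerParams) -> np.ndarray:
    """Perceptual-range weights w = 1 - mean resistance along each heading.

    For every cell and each of the ``n_headings`` directions, resistance is
    sampled along the ray of length ``perceptual_range`` at half-cell
    spacing (nearest-cell lookup, off-grid samples count as barriers).
    Returns an array of shape (n_headings, nrows, ncols) in [0, 1].
    """
    r = np.where(resistance.mask_valid, resistance.values, 1.0)
    nr, nc = r.shape
    cs = resistance.cell_size
    ds = cs / 2.0
    n_samp = max(int(params.perceptual_range // ds), 1)
    K = params.n_headings
    thetas = 2.0 * math.pi * np.arange(K) / K
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    W = np.empty((K, nr, nc), dtype=np.float32)
    for k, th in enumerate(thetas):
        acc = np.zeros((nr, nc))
        for s in range(1, n_samp + 1):
            dx, dy = s * ds * math.cos(th), s * ds * math.sin(th)
            cc = np.floor(cols + 0.5 + dx / cs).astype(int)
            rr = np.floor(rows + 0.5 + dy / cs).astype(int)
            inside = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
            vals = np.where(inside, r[np.clip(rr, 0, nr - 1), np.clip(cc, 0, nc - 1)], 1.0)
            acc += vals
        W[k] = 1.0 - acc / n_samp
    return np.clip(W, 0.0, 1.0)


class _BatchEngine:
    """Lockstep vectorized two-state walker over a shared resistance grid."""

    _CHUNK = 8192  # random-stream block length (steps)

    def __init__(self, resistance: TerrainGrid, params: WalkerParams):
        self.grid = resistance
        self.params = params
        self.res = np.where(resistance.mask_valid, resistance.values, 1.0)
        self.barrier = self.res >= 1.0
        self.W = heading_weights(resistance, params).reshape(params.n_headings, -1)
        K = params.n_headings
        self.units = np.column_stack(
            [
                np.cos(2.0 * math.pi * np.arange(K) / K),
                np.sin(2.0 * math.pi * np.arange(K) / K),
            ]
        )
        self.pmf = np.vstack(
            [wrapped_normal_pmf(K, c) for c in params.turn_concentration]
        )

    def run(
        self,
        starts: np.ndarray,
        seeds: np.ndarray,
        goal: PointSite | None,
        goal_radius: float,
        max_steps: int,
        record: bool = False,
        count_visits: bool = True,
    ):
        g = self.grid
        K = self.params.n_headings
        n = len(seeds)
        nr, nc = self.res.shape
        res_flat = self.res.ravel()
        x0, y0 = g.origin
        cs = g.cell_size
        L = self.params.step_length
        p12, p21 = self.params.switch_prob_12, self.params.switch_prob_21
        stat0 = p21 / (p12 + p21) if (p12 + p21) > 0 else 0.5

        pos = np.array(starts, dtype=float)
        cell = (
            np.floor((pos[:, 1] - y0) / cs).astype(np.int64) * nc
            + np.floor((pos[:, 0] - x0) / cs).astype(np.int64)
        )
        if np.any(self.barrier.ravel()[cell]):
            raise ValueError("walker started on a barrier cell")
        gens = [np.random.default_rng(int(s)) for s in seeds]
        init_u = np.array([gen.random(2) for gen in gens])
        heading = np.floor(init_u[:, 0] * K).astype(np.int64) % K
        state = (init_u[:, 1] >= stat0).astype(np.int64)  # 0 travelling, 1 random

        active = np.ones(n, dtype=bool)
        steps_to_goal = np.full(n, np.nan)
        distance = np.zeros(n)
        visits = (
            np.zeros((n, nr * nc), dtype=np.uint32) if count_visits else None
        )
        if count_visits:
            visits[np.arange(n), cell] += 1
        if record:
            rec_pos = np.empty((max_steps + 1, n, 2))
            rec_state = np.empty((max_steps + 1, n), dtype=np.int8)
            rec_pos[0] = pos
            rec_state[0] = state
        if goal is not None and np.isinf(goal_radius):
            steps_to_goal[:] = 1
            active[:] = False

        gx = goal.x if goal is not None else 0.0
        gy = goal.y if goal is not None else 0.0
        r2_goal = goal_radius * goal_radius
        k_idx = np.arange(K)

        step = 0
        last_recorded = 0
        while step < max_steps and active.any():
            chunk = min(self._CHUNK, max_steps - step)
            u = np.empty((n, chunk, 2))
            for i, gen in enumerate(gens):
                u[i] = gen.random((chunk, 2))
            for j in range(chunk):
                idx = np.nonzero(active)[0]
                if idx.size == 0:
                    break
                u1 = u[idx, j, 0]
                u2 = u[idx, j, 1]
                st = state[idx]
                flip = np.where(st == 0, u1 < p12, u1 < p21)
                st = np.where(flip, 1 - st, st)
                state[idx] = st

                r_loc = res_flat[cell[idx]]
                L_eff = L * (1.0 - r_loc)
                dest = pos[idx, None, :] + L_eff[:, None, None] * self.units[None, :, :]
                cc = np.floor((dest[:, :, 0] - x0) / cs).astype(np.int64)
                rr = np.floor((dest[:, :, 1] - y0) / cs).astype(np.int64)
                inside = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
                dcell = np.clip(rr, 0, nr - 1) * nc + np.clip(cc, 0, nc - 1)
                blocked = ~inside | (res_flat[dcell] >= 1.0)

                shift = (k_idx[None, :] - heading[idx][:, None]) % K
                probs = self.pmf[st][np.arange(idx.size)[:, None], shift]
                probs = probs * self.W[:, cell[idx]].T
                probs[blocked] = 0.0
                total = probs.sum(axis=1)
                movable = total > 0.0
                csum = np.cumsum(probs, axis=1)
                draw = u2 * total
                choice = (csum < draw[:, None]).sum(axis=1).clip(0, K - 1)

                move = idx[movable]
                ch = choice[movable]
                newpos = dest[movable, ch]
                distance[move] += L_eff[movable]
                pos[move] = newpos
                heading[move] = ch
                cell[move] = dcell[movable, ch]

                step_now = step + j + 1
                if count_visits:
                    visits[idx, cell[idx]] += 1
                if record:
                    rec_pos[step_now] = pos
                    rec_state[step_now] = state
                    last_recorded = step_now
                if goal is not None:
                    dx = pos[idx, 0] - gx
                    dy = pos[idx, 1] - gy
                    arrived = dx * dx + dy * dy <= r2_goal
                    if arrived.any():
                        hit = idx[arrived]
                        steps_to_goal[hit] = step_now
                        active[hit] = False
            step += chunk
        out = {
            "pos": pos,
            "state": state,
            "steps_to_goal": steps_to_goal,
            "distance": distance,
            "visits": visits,
        }
        if record:
            out["rec_pos"] = rec_pos[: last_recorded + 1]
            out["rec_state"] = rec_state[: last_recorded + 1]
        return out


def simulate_walk(
    resistance: TerrainGrid,
    start: PointSite,
    goal: PointSite | None = None,
    goal_radius: float = 10_000.0,
    params: WalkerParams | None = None,
    max_steps: int | None = None,
) -> Trajectory:
    """Simulate a single two-state walker realization.

    Per step the movement state evolves by the two-state Markov chain; a
    heading is drawn from the wrapped-normal kernel around the previous
    heading re-weighted by the perceptual-range ray weights; displacement is
    ``step_length * (1 - local resistance)``; headings into barrier cells
    get zero probability (the walker stays in place if every heading is
    blocked).  Terminates on first entry within ``goal_radius`` of the goal
    or after ``max_steps``.
    """
    params = params or WalkerParams()
    engine = _BatchEngine(resistance, params)
    out = engine.run(
        starts=np.array([[start.x, start.y]]),
        seeds=np.array([params.seed]),
        goal=goal,
        goal_radius=goal_radius,
        max_steps=max_steps if max_steps is not None else params.max_steps,
        record=True,
        count_visits=False,
    )
    reached = bool(np.isfinite(out["steps_to_goal"][0]))
    return Trajectory(
        positions=out["rec_pos"][:, 0, :].copy(),
        states=out["rec_state"][:, 0].copy(),
        reached_goal=reached,
        steps_to_goal=int(out["steps_to_goal"][0]) if reached else None,
        seed=params.seed,
    )


def batch_simulate(
    resistance: TerrainGrid,
    start: PointSite,
    goal: PointSite | None,
    n_realizations: int,
    params: WalkerParams | None = None,
    goal_radius: float = 10_000.0,
    max_steps: int | None = None,
) -> WalkEnsemble:
    """Run ``n_realizations`` independent walkers from one entry point.

    Realization ``i`` uses the random stream seeded by ``params.seed XOR i``;
    the ensemble is bitwise reproducible for a fixed master seed.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be at least 1")
    params = params or WalkerParams()
    engine = _BatchEngine(resistance, params)
    seeds = np.array([params.seed ^ i for i in range(n_realizations)])
    out = engine.run(
        starts=np.tile([[start.x, start.y]], (n_realizations, 1)),
        seeds=seeds,
        goal=goal,
        goal_radius=goal_radius,
        max_steps=max_steps if max_steps is not None else params.max_steps,
        record=False,
        count_visits=True,
    )
    success = np.isfinite(out["steps_to_goal"])
    counts = out["visits"][success].sum(axis=0).astype(np.float64)
    return WalkEnsemble(
        seeds=seeds,
        success=success,
        steps_to_goal=out["steps_to_goal"],
        distance_m=out["distance"],
        visit_counts=counts.reshape(resistance.values.shape),
        grid=resistance,
        goal=goal,
        goal_radius=goal_radius,
    )
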