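"""Continuous p-median site selection on a demand-point grid in 2-D NMDS space.

The continuous p-median formulation of environmental diversity places demand
uniformly throughout environmental space: each NMDS axis is divided into g
equal intervals (g = 50 by default, 2,500 demand points) and the cell
centroids are "demand points". The selector picks p sites minimizing the sum,
over demand points, of the distance to the nearest selected site. Demand
points in empty regions of ordination space are retained deliberately —
demand is uniform over the bounding box, not over the data.

The solver is a multistart hybrid heuristic: randomized greedy construction
(each addition drawn from the best-3 candidates), Whitaker-style vertex
substitution local search with first-improvement swaps, and pairwise
recombination of an elite pool (union of two local optima greedily reduced
back to p, then re-polished). Defaults are 32 starts and an elite pool of 10.
Everything is driven by one seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .env_space import OrdinationSpace
from .maxdisp import SelectionResult


@dataclass
class DemandGrid:
    """g x g grid-cell centroids over the bounding box of 2-D coordinates."""

    points: np.ndarray  # (g*g, 2)
    g: int
    bounds: np.ndarray  # (2, 2): per-axis (min, max)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class PMedianConfig:
    starts: int = 32
    elite_size: int = 10
    seed: int = 0
    max_swaps: int = 10_000

    def __post_init__(self) -> None:
        if self.starts < 1:
            raise ValueError("starts must be >= 1")
        if not (1 <= self.elite_size <= self.starts):
            raise ValueError("elite_size must be in [1, starts]")
        if self.max_swaps < 0:
            raise ValueError("max_swaps must be nonnegative")


def build_demand_grid(coords2d: OrdinationSpace, g: int = 50) -> DemandGrid:
    """All g^2 cell centroids of a uniform grid over the coordinate extrema.

    Bounds are the observed per-axis minima and maxima (no padding); centroids
    sit at half-interval offsets, strictly inside the bounding box. Cells
    containing no sites are kept.
    """
    if coords2d.kind != "nmds2d":
        raise ValueError("demand grid requires a 2-D NMDS ordination")
    if g < 1:
        raise ValueError("g must be >= 1")
    xy = coords2d.coordinates
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    if np.any(hi == lo):
        raise ValueError("degenerate axis: max equals min, grid undefined")
    step = (hi - lo) / g
    centers = [lo[a] + (np.arange(g) + 0.5) * step[a] for a in (0, 1)]
    gx, gy = np.meshgrid(centers[0], centers[1], indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    return DemandGrid(points=points, g=g, bounds=np.column_stack([lo, hi]).T)


def pmedian_cost(selected, demand: DemandGrid, coords2d: OrdinationSpace) -> float:
    """Sum over demand points of the distance to the nearest selected site."""
    idx = np.asarray(list(selected), dtype=int)
    if idx.size == 0:
        raise ValueError("p-median cost of an empty selection is undefined")
    d = cdist(demand.points, coords2d.coordinates[idx])
    return float(d.min(axis=1).sum())


# ---------------------------------------------------------------------------
# solver internals: all operate on D, the (n_demand x n_sites) distance matrix
# ---------------------------------------------------------------------------


def _cost(D: np.ndarray, sel: np.ndarray) -> float:
    return float(D[:, sel].min(axis=1).sum())


def _nearest_two(D: np.ndarray, sel: np.ndarray):
    """Per demand point: position (into sel) of nearest site, and the nearest
    and second-nearest distances (second = inf when p == 1)."""
    sub = D[:, sel]
    if sel.size == 1:
        d1 = sub[:, 0]
        return np.zeros(len(d1), dtype=int), d1, np.full(len(d1), np.inf)
    part = np.argpartition(sub, 1, axis=1)[:, :2]
    rows = np.arange(sub.shape[0])
    a, b = sub[rows, part[:, 0]], sub[rows, part[:, 1]]
    swap = a > b
    n1 = np.where(swap, part[:, 1], part[:, 0])
    d1 = np.where(swap, b, a)
    d2 = np.where(swap, a, b)
    return n1, d1, d2


def _greedy_construct(D: np.ndarray, p: int, rng: np.random.Generator) -> np.ndarray:
    """Randomized greedy: each addition drawn uniformly from the best-3
    candidates by cost reduction."""
    n = D.shape[1]
    sel: list[int] = []
    dmin = np.full(D.shape[0], np.inf)
    remaining = np.ones(n, dtype=bool)
    for _ in range(p):
        cand = np.flatnonzero(remaining)
        new_costs = np.minimum(dmin[:, None], D[:, cand]).sum(axis=0)
        k = min(3, cand.size)
        best = cand[np.argpartition(new_costs, k - 1)[:k]]
        pick = int(rng.choice(np.sort(best)))
        sel.append(pick)
        remaining[pick] = False
        dmin = np.minimum(dmin, D[:, pick])
    return np.asarray(sel, dtype=int)


def _local_search(
    D: np.ndarray, sel: np.ndarray, rng: np.random.Generator, max_swaps: int
) -> tuple[np.ndarray, float, int]:
    """First-improvement vertex substitution in seeded candidate order.

    For each out-of-solution candidate c the best paired removal is found in
    O(n_demand) using the nearest/second-nearest bookkeeping (Whitaker's
    profit computation); the first strictly improving swap is applied.
    """
    n = D.shape[1]
    sel = np.array(sel, dtype=int)
    p = sel.size
    swaps = 0
    if p == n:
        return sel, _cost(D, sel), 0
    n1, d1, d2 = _nearest_two(D, sel)
    improved = True
    while improved and swaps < max_swaps:
        improved = False
        out = np.setdiff1d(np.arange(n), sel)
        for c in rng.permutation(out):
            Dc = D[:, c]
            closer = Dc < d1
            gain_ins = float((Dc[closer] - d1[closer]).sum())  # <= 0
            # loss w(r): points served by r that c does not take over must fall
            # back to min(Dc, d2)
            contrib = np.where(closer, 0.0, np.minimum(Dc, d2) - d1)
            w = np.bincount(n1, weights=contrib, minlength=p)
            k = int(np.argmin(w))
            delta = gain_ins + float(w[k])
            if delta < -1e-9:
                sel[k] = c
                n1, d1, d2 = _nearest_two(D, sel)
                swaps += 1
                improved = True
                break
    return sel, _cost(D, sel), swaps


def _reduce_to_p(D: np.ndarray, pool: np.ndarray, p: int) -> np.ndarray:
    """Greedily drop from a pool of sites, each step removing the site whose
    removal increases cost least, until only p remain."""
    pool = np.array(sorted(set(pool.tolist())), dtype=int)
    while pool.size > p:
        n1, d1, d2 = _nearest_two(D, pool)
        increase = np.bincount(n1, weights=d2 - d1, minlength=pool.size)
        pool = np.delete(pool, int(np.argmin(increase)))
    return pool


def solve_pmedian(
    coords2d: OrdinationSpace,
    demand: DemandGrid,
    p: int,
    config: PMedianConfig | None = None,
) -> SelectionResult:
    """Multistart hybrid heuristic for the continuous p-median.

    Runs ``config.starts`` randomized constructions each followed by vertex
    substitution, recombines the ``config.elite_size`` best local optima
    pairwise (union reduced back to p, then re-polished), and returns the best
    solution found. Deterministic given ``config.seed``. The trajectory records
    the incumbent (best-so-far) cost after each start and recombination.
    """
    if config is None:
        config = PMedianConfig()
    n = coords2d.n_sites
    if not (1 <= p <= n):
        raise ValueError(f"p must satisfy 1 <= p <= n ({p} vs n={n})")
    D = cdist(demand.points, coords2d.coordinates)

    if p == n:
        sel = list(range(n))
        return SelectionResult(sel, _cost(D, np.arange(n)), [_cost(D, np.arange(n))])

    root = np.random.SeedSequence(config.seed)
    start_seeds = root.spawn(config.starts + 1)
    pool: list[tuple[float, tuple[int, ...]]] = []
    best_sel, best_cost = None, np.inf
    trajectory: list[float] = []

    for s in range(config.starts):
        rng = np.random.default_rng(start_seeds[s])
        sel = _greedy_construct(D, p, rng)
        sel, cost, _ = _local_search(D, sel, rng, config.max_swaps)
        pool.append((cost, tuple(sorted(sel.tolist()))))
        if cost < best_cost:
            best_cost, best_sel = cost, sel
        trajectory.append(best_cost)

    pool.sort(key=lambda t: (t[0], t[1]))
    elite = []
    seen = set()
    for cost, sel in pool:
        if sel not in seen:
            elite.append(np.asarray(sel, dtype=int))
            seen.add(sel)
        if len(elite) == config.elite_size:
            break

    rng = np.random.default_rng(start_seeds[-1])
    for a, b in combinations(range(len(elite)), 2):
        union = np.union1d(elite[a], elite[b])
        if union.size == p:
            continue
        sel = _reduce_to_p(D, union, p)
        sel, cost, _ = _local_search(D, sel, rng, config.max_swaps)
        if cost < best_cost:
            best_cost, best_sel = cost, sel
        trajectory.append(best_cost)

    return SelectionResult(sorted(int(i) for i in best_sel), best_cost, trajectory)
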