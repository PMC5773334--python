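"""Greedy maximum-dispersion (maxdisp) site selection.

Maxdisp picks m sites whose sum of inverse squared pairwise distances

    minimize  sum_{i<j selected} 1 / d_ij^2

is minimal, spreading the selection evenly through environmental space. It
works in the full retained-PCA space — no 2-D reduction is needed, unlike the
demand-grid p-median. The greedy heuristic adds one site at a time, each step
the site whose marginal contribution to the objective is smallest; this mimics
a decision-maker adding one protected site at a time.

Conventions (the objective alone does not pin these down):

* initialization is the maximum-distance pair, the exact optimum for m = 2;
* coincident sites (d_ij = 0) contribute a large finite sentinel 1/EPS^2
  instead of infinity, so objectives stay comparable;
* ties break toward the lowest site index, making the procedure deterministic;
* m = 1 has no pair term, so the convention is the site maximizing its minimum
  distance to all others (the most isolated site), objective 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .env_space import DistanceMatrix

#: Distance floor for coincident sites, in coordinate units.
EPS = 1e-12


@dataclass
class SelectionProblem:
    """Select m of n sites given their pairwise distances."""

    d: DistanceMatrix
    m: int

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.d.n_sites):
            raise ValueError(f"m must satisfy 1 <= m <= n ({self.m} vs n={self.d.n_sites})")

    @property
    def n(self) -> int:
        return self.d.n_sites


@dataclass
class SelectionResult:
    """Selected site indices in addition order with the objective trajectory."""

    selected: list[int]
    objective: float
    trajectory: list[float]


def _inverse_square_weights(d: np.ndarray) -> np.ndarray:
    w = 1.0 / np.maximum(d, EPS) ** 2
    np.fill_diagonal(w, 0.0)
    return w


def maxdisp_objective(selected, d: DistanceMatrix) -> float:
    """Sum of 1/d_ij^2 over unordered pairs of selected sites.

    A single site has no pairs (objective 0). Coincident pairs contribute the
    1/EPS^2 sentinel.
    """
    idx = np.asarray(list(selected), dtype=int)
    if idx.size < 2:
        return 0.0
    sub = d.d[np.ix_(idx, idx)]
    w = _inverse_square_weights(sub)
    return float(w[np.triu_indices(idx.size, k=1)].sum())


def greedy_maxdisp(problem: SelectionProblem) -> SelectionResult:
    """Greedy maxdisp: seed with the farthest pair, then add the site with the
    smallest marginal sum of inverse squared distances to the current set.

    Deterministic; ties resolve to the lowest site index. The trajectory holds
    the objective after the selection reaches each size 1..m and is
    non-decreasing (every addition adds nonnegative pair terms).
    """
    d = problem.d.d
    n, m = problem.n, problem.m

    if m == 1:
        # most isolated site: maximize min distance to all others
        if n == 1:
            return SelectionResult([0], 0.0, [0.0])
        off = d + np.diag(np.full(n, np.inf))
        pick = int(np.argmax(off.min(axis=1)))
        return SelectionResult([pick], 0.0, [0.0])

    w = _inverse_square_weights(d)

    # farthest pair; np.argmax returns the first (row-major) maximum, i.e. the
    # lexicographically smallest (i, j) among ties
    upper = np.triu(d, k=1)
    i, j = np.unravel_index(int(np.argmax(upper)), d.shape)
    selected = [int(i), int(j)]
    objective = float(w[i, j])
    trajectory = [0.0, objective]

    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    marginal = w[:, i] + w[:, j]

    while len(selected) < m:
        cand = np.where(in_set, np.inf, marginal)
        pick = int(np.argmin(cand))
        objective += float(marginal[pick])
        trajectory.append(objective)
        selected.append(pick)
        in_set[pick] = True
        marginal = marginal + w[:, pick]

    return SelectionResult(selected, objective, trajectory)
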