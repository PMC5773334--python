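"""Species Accumulation Index (SAI) evaluation of site-selection surrogates.

A surrogate selection of p sites represents S species (counted at least once).
Its quality is scaled between a random baseline R — the mean species count of
random p-site subsets — and a near-optimal count O:

    SAI = (S - R) / (O - R)

SAI = 1 means as good as the optimum, 0 means no better than random, negative
means worse than random. Performance is summarized as the median SAI over
selections of 15%, 20%, 25%, 30% and 35% of the sites.

R is estimated by Monte Carlo (1,000 replicates by default); the exact
expectation is also available in closed form from the hypergeometric
distribution and serves as an oracle. O defaults to a core-area reverse
stepwise ranking (each step removes the site least important to the species
for which it matters most, i.e. minimal max share of remaining occurrences),
the same idea as core-area Zonation restricted to binary occurrences with unit
weights and costs. Because that ranking is itself a heuristic, greedy maximum
coverage and exact enumeration are provided as alternatives and test oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import hypergeom

from .synthetic import PresenceAbsenceMatrix

DEFAULT_FRACTIONS = (0.15, 0.20, 0.25, 0.30, 0.35)

#: A selector maps the number of sites to pick to a sequence of site indices.
Selector = Callable[[int], Sequence[int]]


def species_represented(selected, pa: PresenceAbsenceMatrix) -> int:
    """Number of species with at least one presence among the selected sites."""
    idx = np.asarray(list(selected), dtype=int)
    if idx.size == 0:
        return 0
    return int(pa.occ[idx].any(axis=0).sum())


def expected_random_richness(pa: PresenceAbsenceMatrix, p: int) -> float:
    """Closed-form E[species represented] under uniform p-site selection.

    Species j occupying n_j sites is missed with hypergeometric probability
    C(n - n_j, p) / C(n, p), so the expectation is
    sum_j 1 - C(n - n_j, p) / C(n, p).
    """
    n = pa.n_sites
    if not (1 <= p <= n):
        raise ValueError("p must satisfy 1 <= p <= n")
    occupancy = pa.occ.sum(axis=0)
    p_miss = hypergeom.pmf(0, n, occupancy, p)
    return float(np.sum(1.0 - p_miss))


def random_richness_variance(pa: PresenceAbsenceMatrix, p: int) -> float:
    """Exact variance of the species count of a uniform random p-site subset.

    With miss indicators M_j (species j absent from the subset), richness is
    s - sum_j M_j, so the variance needs the joint miss probabilities:
    P(M_j M_k = 1) = C(n - u_jk, p) / C(n, p) with u_jk the number of sites
    hosting j or k. Together with ``expected_random_richness`` this gives the
    closed-form mean and standard error of the Monte-Carlo baseline.
    """
    n = pa.n_sites
    if not (1 <= p <= n):
        raise ValueError("p must satisfy 1 <= p <= n")
    occ = pa.occ.astype(bool)
    occupancy = occ.sum(axis=0)
    q = hypergeom.pmf(0, n, occupancy, p)  # marginal miss probabilities
    # |sites_j union sites_k| for every species pair
    inter = occ.T.astype(np.int64) @ occ.astype(np.int64)
    union = occupancy[:, None] + occupancy[None, :] - inter
    q_joint = hypergeom.pmf(0, n, union, p)
    cov = q_joint - np.outer(q, q)
    np.fill_diagonal(cov, q * (1.0 - q))
    return float(cov.sum())


def random_baseline_draws(
    pa: PresenceAbsenceMatrix, p: int, reps: int = 1000, seed: int = 0
) -> np.ndarray:
    """Species counts of ``reps`` seeded uniform random p-site subsets."""
    n = pa.n_sites
    if not (1 <= p <= n):
        raise ValueError("p must satisfy 1 <= p <= n")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty(reps, dtype=int)
    for r in range(reps):
        idx = rng.choice(n, size=p, replace=False)
        draws[r] = int(pa.occ[idx].any(axis=0).sum())
    return draws


def random_baseline(pa: PresenceAbsenceMatrix, p: int, reps: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo mean species count over random p-site subsets."""
    return float(random_baseline_draws(pa, p, reps=reps, seed=seed).mean())


def zonation_core_area_ranking(pa: PresenceAbsenceMatrix) -> np.ndarray:
    """Core-area reverse stepwise ranking of sites (highest priority first).

    At each step, every remaining site i scores
    delta_i = max over species j present at i of 1 / (remaining occurrences of j),
    and the site with the smallest delta is removed (ties to the lowest index).
    Removal order reversed is the priority ranking, so a species' last refuge
    is kept for as long as possible.
    """
    occ = pa.occ.astype(float)
    n = pa.n_sites
    remaining = np.ones(n, dtype=bool)
    counts = occ.sum(axis=0)
    removal_order: list[int] = []
    for _ in range(n):
        inv = np.divide(1.0, counts, out=np.zeros_like(counts), where=counts > 0)
        delta = (occ[remaining] * inv[None, :]).max(axis=1)
        live = np.flatnonzero(remaining)
        drop = int(live[int(np.argmin(delta))])  # argmin keeps the first (lowest) index
        removal_order.append(drop)
        remaining[drop] = False
        counts -= occ[drop]
    return np.asarray(removal_order[::-1], dtype=int)


def _greedy_max_coverage(pa: PresenceAbsenceMatrix, p: int) -> np.ndarray:
    occ = pa.occ.astype(bool)
    covered = np.zeros(pa.n_species, dtype=bool)
    chosen: list[int] = []
    available = np.ones(pa.n_sites, dtype=bool)
    for _ in range(p):
        gains = (occ & ~covered[None, :]).sum(axis=1)
        gains = np.where(available, gains, -1)
        pick = int(np.argmax(gains))
        chosen.append(pick)
        covered |= occ[pick]
        available[pick] = False
    return np.asarray(chosen, dtype=int)


EXACT_ENUMERATION_LIMIT = 1_000_000


def optimal_representation(
    pa: PresenceAbsenceMatrix, p: int, method: str = "zonation"
) -> int:
    """Largest (or heuristically near-largest) species count achievable with p sites.

    ``zonation``: species represented by the top-p prefix of the core-area
    ranking (the default). ``greedy_coverage``: classic greedy maximum
    coverage. ``exact``: exhaustive enumeration, only for C(n, p) <= 1e6.
    """
    n = pa.n_sites
    if not (1 <= p <= n):
        raise ValueError("p must satisfy 1 <= p <= n")
    if method == "zonation":
        ranking = zonation_core_area_ranking(pa)
        return species_represented(ranking[:p], pa)
    if method == "greedy_coverage":
        return species_represented(_greedy_max_coverage(pa, p), pa)
    if method == "exact":
        if comb(n, p, exact=True) > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                "exact enumeration infeasible for this instance; "
                "use method='zonation' or 'greedy_coverage'"
            )
        occ = pa.occ.astype(bool)
        best = 0
        for subset in combinations(range(n), p):
            s = int(occ[list(subset)].any(axis=0).sum())
            if s > best:
                best = s
        return best
    raise ValueError(f"unknown method {method!r}")


def sai(S: float, R: float, O: float) -> float:
    """Species Accumulation Index (S - R) / (O - R).

    Returns NaN (the explicit undefined flag) when O == R; raises when O < R,
    which signals an upstream failure of the optimum heuristic.
    """
    if O < R:
        raise ValueError(f"optimum O={O} below random baseline R={R}: heuristic failure")
    if O == R:
        return math.nan
    return (S - R) / (O - R)


@dataclass
class SAIReport:
    """Per-fraction SAI records plus the median-of-fractions summary."""

    records: list[dict]
    median_sai: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            self.records, columns=["fraction", "p", "S", "R", "O", "SAI", "flag"]
        )


def fraction_for_p(fraction: float, n: int) -> int:
    """Sites to select at a landscape fraction: nearest integer, minimum 1."""
    return max(1, int(math.floor(fraction * n + 0.5)))


def fraction_sweep(
    pa: PresenceAbsenceMatrix,
    selector: Selector,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    reps: int = 1000,
    seed: int = 0,
    optimum_method: str = "zonation",
    ranking: np.ndarray | None = None,
) -> SAIReport:
    """Evaluate a selector at each landscape fraction and summarize by median SAI.

    For each fraction: p = round(fraction * n) (floored at 1), S from the
    selector, R from a seeded Monte-Carlo baseline, O from the chosen optimum
    method. Fractions with an undefined SAI (O == R, or the rare O < R flagged
    as a heuristic failure) are excluded from the median with a warning.
    ``ranking`` may pass a precomputed core-area ranking to avoid recomputing
    it per sweep.
    """
    n = pa.n_sites
    if optimum_method == "zonation" and ranking is None:
        ranking = zonation_core_area_ranking(pa)
    records: list[dict] = []
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(len(fractions))
    for frac, sub_seed in zip(fractions, rep_seeds):
        p = fraction_for_p(frac, n)
        S = species_represented(selector(p), pa)
        R = random_baseline(pa, p, reps=reps, seed=sub_seed)
        if optimum_method == "zonation":
            O = species_represented(ranking[:p], pa)
        else:
            O = optimal_representation(pa, p, method=optimum_method)
        flag = ""
        if O < R:
            value = math.nan
            flag = "baseline_exceeds_optimum"
        else:
            value = sai(S, R, O)
            if math.isnan(value):
                flag = "undefined_O_equals_R"
        records.append(
            {"fraction": frac, "p": p, "S": S, "R": R, "O": O, "SAI": value, "flag": flag}
        )
    defined = [r["SAI"] for r in records if not math.isnan(r["SAI"])]
    if not defined:
        raise ValueError("SAI undefined at every fraction (O == R throughout)")
    if len(defined) < len(records):
        warnings.warn("some fractions had undefined SAI and were excluded from the median")
    return SAIReport(records=records, median_sai=float(np.median(defined)), seed=seed)
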