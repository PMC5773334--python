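"""Synthetic landscapes with unimodal species niches.

The pipeline's premise is that species composition is driven by position in a
low-dimensional environmental gradient space: sites close together in that
space share species. The generator makes that premise literally true so the
surrogate machinery can be tested end to end without field data:

* each site gets latent coordinates drawn from a standard multivariate normal
  (the "true" environmental gradients);
* observed variables are noisy linear readouts of the latent coordinates,
  organized in typed groups (temperature, precipitation, insolation, NDVI,
  topography) with stronger correlation within a group than between groups —
  mimicking a multicollinear predictor table;
* each species has a Gaussian (unimodal) niche in latent space: occurrence
  probability decays with squared distance from its niche center, and presence
  is a Bernoulli draw.

The latent coordinates are exposed for testing, but the analysis pipeline only
ever sees the noisy observed variables — it must rediscover the gradient
structure via PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .env_space import VARIABLE_TYPES, EnvironmentMatrix

#: Default variable counts per type, 38 variables in total, emulating a
#: typical global predictor stack (bioclim temperature + precipitation
#: summaries, monthly insolation, NDVI composites, terrain derivatives).
DEFAULT_VARIABLE_GROUPS: tuple[tuple[str, int], ...] = (
    ("temperature", 11),
    ("precipitation", 8),
    ("insolation", 8),
    ("ndvi", 4),
    ("topography", 7),
)


@dataclass
class LandscapeConfig:
    """Configuration of a synthetic environmental landscape."""

    n_sites: int = 300
    n_latent: int = 3
    variable_groups: tuple[tuple[str, int], ...] = DEFAULT_VARIABLE_GROUPS
    noise_sd: float = 0.3
    seed: int = 0
    #: Mixing weight of the per-variable random loading relative to the shared
    #: group loading; smaller values give stronger within-group correlation.
    loading_jitter: float = 0.5

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2 (distance matrices undefined otherwise)")
        if self.n_latent < 1:
            raise ValueError("n_latent must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        labels = [g for g, _ in self.variable_groups]
        unknown = set(labels) - set(VARIABLE_TYPES)
        if unknown:
            raise ValueError(f"unknown variable group labels: {sorted(unknown)}")
        if any(c < 1 for _, c in self.variable_groups):
            raise ValueError("every variable group needs a positive count")
        if sum(c for _, c in self.variable_groups) < self.n_latent:
            raise ValueError("total variable count must be >= n_latent")

    @property
    def n_vars(self) -> int:
        return sum(c for _, c in self.variable_groups)


@dataclass
class NicheConfig:
    """Configuration of the Gaussian-niche species generator."""

    n_species: int = 120
    breadth_range: tuple[float, float] = (0.5, 1.5)
    max_prevalence: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.breadth_range
        if not (0 < low <= high):
            raise ValueError("breadth_range must satisfy 0 < low <= high")
        if not (0 < self.max_prevalence <= 1):
            raise ValueError("max_prevalence must be in (0, 1]")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")


@dataclass
class Landscape:
    """A generated landscape: observed table plus the hidden truth."""

    environment: EnvironmentMatrix
    latent: np.ndarray  # (n_sites, n_latent), hidden from the pipeline
    loadings: np.ndarray  # (n_vars, n_latent)
    config: LandscapeConfig


@dataclass
class PresenceAbsenceMatrix:
    """Site x species binary occurrence table; every species occurs >= 1 time."""

    occ: np.ndarray  # (n_sites, n_species) in {0, 1}
    site_ids: list[str]
    species_ids: list[str]

    def __post_init__(self) -> None:
        self.occ = np.asarray(self.occ)
        if self.occ.ndim != 2:
            raise ValueError("occ must be 2-D")
        if not np.isin(self.occ, (0, 1)).all():
            raise ValueError("occurrence entries must be 0/1")
        self.occ = self.occ.astype(np.int8)
        n, s = self.occ.shape
        if len(self.site_ids) != n or len(self.species_ids) != s:
            raise ValueError("id lengths do not match matrix shape")
        if (self.occ.sum(axis=0) == 0).any():
            raise ValueError("every species must occur at least once")

    @property
    def n_sites(self) -> int:
        return self.occ.shape[0]

    @property
    def n_species(self) -> int:
        return self.occ.shape[1]


def _group_loadings(config: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Random loadings with shared direction per group plus per-variable jitter."""
    rows = []
    for _, count in config.variable_groups:
        shared = rng.normal(size=config.n_latent)
        shared /= np.linalg.norm(shared)
        for _ in range(count):
            own = rng.normal(size=config.n_latent)
            own /= np.linalg.norm(own)
            w = shared + config.loading_jitter * own
            rows.append(w / np.linalg.norm(w))
    return np.asarray(rows)


def generate_environment(
    config: LandscapeConfig, loadings: np.ndarray | None = None
) -> Landscape:
    """Generate a site x variable table from latent gradients.

    Each observed variable is a linear combination of the latent site
    coordinates plus independent Gaussian noise of s.d. ``noise_sd``.
    Variables within a type group share a common loading direction, so
    within-group correlations exceed between-group ones. Deterministic given
    ``config.seed``. Pass ``loadings`` to fix the mixing matrix explicitly
    (rows = variables, columns = latent axes).
    """
    rng = np.random.default_rng(config.seed)
    latent = rng.normal(size=(config.n_sites, config.n_latent))
    if loadings is None:
        loadings = _group_loadings(config, rng)
    else:
        loadings = np.asarray(loadings, dtype=float)
        if loadings.shape != (config.n_vars, config.n_latent):
            raise ValueError("loadings must be (n_vars, n_latent)")
    noise = rng.normal(scale=config.noise_sd, size=(config.n_sites, config.n_vars)) \
        if config.noise_sd > 0 else 0.0
    values = latent @ loadings.T + noise

    var_names, var_types = [], []
    for label, count in config.variable_groups:
        for i in range(count):
            var_names.append(f"{label}_{i + 1}")
            var_types.append(label)
    env = EnvironmentMatrix(
        values=values,
        site_ids=[f"site_{i + 1}" for i in range(config.n_sites)],
        var_names=var_names,
        var_types=var_types,
    )
    return Landscape(environment=env, latent=latent, loadings=loadings, config=config)


def occurrence_probabilities(
    latent: np.ndarray, centers: np.ndarray, breadths: np.ndarray, max_prevalence: float
) -> np.ndarray:
    """Gaussian-niche occurrence probability for every site x species pair.

    P(site i hosts species j) = max_prevalence * exp(-||z_i - c_j||^2 / (2 s_j^2)).
    """
    sq = ((latent[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return max_prevalence * np.exp(-sq / (2.0 * breadths[None, :] ** 2))


def generate_species(latent: np.ndarray, config: NicheConfig) -> PresenceAbsenceMatrix:
    """Draw a presence/absence matrix from Gaussian niches in latent space.

    Niche centers are sampled uniformly over the per-axis range of the latent
    coordinates; breadths uniformly from ``breadth_range``. Any species left
    with zero occurrences after the Bernoulli draw is assigned presence at the
    site nearest its niche center, so species counts are stable across seeds.
    """
    latent = np.asarray(latent, dtype=float)
    rng = np.random.default_rng(config.seed)
    lo, hi = latent.min(axis=0), latent.max(axis=0)
    centers = rng.uniform(lo, hi, size=(config.n_species, latent.shape[1]))
    breadths = rng.uniform(*config.breadth_range, size=config.n_species)
    prob = occurrence_probabilities(latent, centers, breadths, config.max_prevalence)
    occ = (rng.random(prob.shape) < prob).astype(np.int8)

    empty = np.flatnonzero(occ.sum(axis=0) == 0)
    for j in empty:
        dist = ((latent - centers[j]) ** 2).sum(axis=1)
        occ[int(np.argmin(dist)), j] = 1

    return PresenceAbsenceMatrix(
        occ=occ,
        site_ids=[f"site_{i + 1}" for i in range(latent.shape[0])],
        species_ids=[f"sp_{j + 1}" for j in range(config.n_species)],
    )
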