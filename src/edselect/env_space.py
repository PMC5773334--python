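"""Environmental ordination spaces for environmental-diversity (ED) selection.

ED surrogates operate on a geometric summary of a site-by-environment table:
variables are grouped into five types (temperature, precipitation, insolation,
NDVI, topography), subset into fixed combinations of variable types (CVTs),
standardized, and reduced by PCA with Kaiser retention (eigenvalue > 1 on the
correlation matrix). The maximum-dispersion selector works directly on
Euclidean distances in the retained PCA space; the continuous p-median
selector additionally requires a 2-D nonmetric multidimensional scaling (NMDS)
embedding of those distances, because its demand grid is two-dimensional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

VARIABLE_TYPES = ("temperature", "precipitation", "insolation", "ndvi", "topography")

#: The five fixed combinations of variable types (CVTs).
CVT_DEFINITIONS: dict[str, frozenset[str]] = {
    "CVT1": frozenset(VARIABLE_TYPES),
    "CVT2": frozenset({"temperature", "precipitation", "ndvi"}),
    "CVT3": frozenset({"temperature", "precipitation", "topography"}),
    "CVT4": frozenset({"temperature", "precipitation"}),
    "CVT5": frozenset({"insolation", "topography"}),
}


@dataclass
class EnvironmentMatrix:
    """Site x environmental-variable table with per-column type tags."""

    values: np.ndarray  # (n_sites, n_vars) float
    site_ids: list[str]
    var_names: list[str]
    var_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D site x variable matrix")
        n, v = self.values.shape
        if n < 2:
            raise ValueError("at least 2 sites are required")
        if len(self.site_ids) != n or len(self.var_names) != v or len(self.var_types) != v:
            raise ValueError("site_ids/var_names/var_types lengths do not match values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("environment table contains missing or non-finite values")
        unknown = set(self.var_types) - set(VARIABLE_TYPES)
        if unknown:
            raise ValueError(f"unknown variable type tags: {sorted(unknown)}")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def zero_variance_columns(self) -> list[int]:
        sd = self.values.std(axis=0)
        return [int(i) for i in np.flatnonzero(sd == 0.0)]

    def drop_zero_variance(self) -> "EnvironmentMatrix":
        """Return a copy without constant columns (PCA requires variance)."""
        bad = set(self.zero_variance_columns())
        keep = [i for i in range(self.n_vars) if i not in bad]
        if len(keep) == self.n_vars:
            return self
        return EnvironmentMatrix(
            self.values[:, keep],
            list(self.site_ids),
            [self.var_names[i] for i in keep],
            [self.var_types[i] for i in keep],
        )


@dataclass(frozen=True)
class CVTDefinition:
    name: str
    included_types: frozenset[str]

    @classmethod
    def from_name(cls, name: str) -> "CVTDefinition":
        key = name.upper()
        if key not in CVT_DEFINITIONS:
            raise KeyError(f"unknown CVT {name!r}; expected one of {sorted(CVT_DEFINITIONS)}")
        return cls(key, CVT_DEFINITIONS[key])


@dataclass
class OrdinationSpace:
    """Site coordinates in a reduced environmental space.

    ``kind`` is ``"pca"`` (k = number of retained components) or ``"nmds2d"``
    (k = 2, with a Kruskal stress-1 value).
    """

    coordinates: np.ndarray  # (n_sites, k)
    kind: str  # "pca" | "nmds2d"
    eigenvalues: np.ndarray | None = None  # all eigenvalues, pca only
    stress: float | None = None  # nmds only
    kaiser_fallback: bool = False  # True if no eigenvalue exceeded 1.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.kind not in ("pca", "nmds2d"):
            raise ValueError("kind must be 'pca' or 'nmds2d'")
        if self.kind == "nmds2d" and self.coordinates.shape[1] != 2:
            raise ValueError("nmds2d space must be two-dimensional")
        if self.stress is not None and self.stress < 0:
            raise ValueError("stress must be nonnegative")

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise site distances with zero diagonal."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n, m = self.d.shape
        if n != m:
            raise ValueError("distance matrix must be square")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n_sites(self) -> int:
        return self.d.shape[0]


def subset_by_cvt(env: EnvironmentMatrix, cvt: CVTDefinition | str) -> EnvironmentMatrix:
    """Return the columns whose type tag belongs to the CVT, order preserved."""
    if isinstance(cvt, str):
        cvt = CVTDefinition.from_name(cvt)
    present = set(env.var_types)
    missing = cvt.included_types - present
    if missing:
        raise ValueError(
            f"{cvt.name} requires variable types {sorted(missing)} absent from the table"
        )
    keep = [i for i, t in enumerate(env.var_types) if t in cvt.included_types]
    return EnvironmentMatrix(
        env.values[:, keep],
        list(env.site_ids),
        [env.var_names[i] for i in keep],
        [env.var_types[i] for i in keep],
    )


def pca_kaiser(env: EnvironmentMatrix) -> OrdinationSpace:
    """Correlation-matrix PCA retaining components with eigenvalue > 1.0.

    Variables are standardized to zero mean and unit variance, so eigenvalues
    are those of the correlation matrix and the Kaiser rule ("more variance
    than a single original variable") applies. If no eigenvalue exceeds 1.0
    the single largest component is retained and flagged rather than failing.
    Component signs are fixed so the largest-magnitude loading is positive,
    making scores deterministic.
    """
    bad = env.zero_variance_columns()
    if bad:
        names = [env.var_names[i] for i in bad]
        raise ValueError(f"zero-variance columns {names}: drop them before PCA")
    if env.n_vars < 2:
        raise ValueError("PCA requires at least 2 variables")
    x = env.values
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = (xs.T @ xs) / (env.n_sites - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # deterministic sign convention
    flip = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    k = int(np.sum(eigval > 1.0))
    fallback = k == 0
    if fallback:
        warnings.warn("no eigenvalue exceeds 1.0; retaining the single largest component")
        k = 1
    scores = xs @ eigvec[:, :k]
    return OrdinationSpace(
        coordinates=scores, kind="pca", eigenvalues=eigval, kaiser_fallback=fallback
    )


def euclidean_distances(space: OrdinationSpace) -> DistanceMatrix:
    """Pairwise Euclidean distances between site coordinates."""
    return DistanceMatrix(squareform(pdist(space.coordinates, metric="euclidean")))


def kruskal_stress1(d: DistanceMatrix | np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities.

    Disparities come from isotonic (monotone) regression of configuration
    distances on the rank order of the input dissimilarities, the same loss
    the nonmetric SMACOF refinement minimizes; used as an independent quality
    check on embeddings.
    """
    dm = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    iu = np.triu_indices(dm.shape[0], k=1)
    diss = dm[iu]
    conf = squareform(pdist(np.asarray(coordinates, dtype=float)))[iu]
    disp = IsotonicRegression().fit_transform(diss, conf)
    denom = float(np.sum(conf**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((conf - disp) ** 2) / denom))


def _classical_scaling_init(dm: np.ndarray, seed: int) -> np.ndarray:
    """Metric (Torgerson) scaling to 2-D plus a small seeded jitter."""
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:2]
    lam = np.clip(eigval[order], 0.0, None)
    init = eigvec[:, order] * np.sqrt(lam)
    scale = dm.max() if dm.max() > 0 else 1.0
    rng = np.random.default_rng(seed)
    return init + rng.normal(scale=1e-4 * scale, size=init.shape)


def nmds_2d(d: DistanceMatrix, seed: int = 0, max_iter: int = 300) -> OrdinationSpace:
    """Two-dimensional nonmetric MDS of a site distance matrix.

    Nonmetric SMACOF minimizing Kruskal stress-1, initialized from classical
    metric scaling with a seeded jitter to break degeneracy; deterministic
    given the seed. Intended input is the Euclidean distance matrix in
    retained-PCA space, so that 2-D intersite distance reflects distance in
    the full PCA space.
    """
    if d.n_sites < 3:
        raise ValueError("NMDS requires at least 3 sites")
    init = _classical_scaling_init(d.d, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, stress = smacof(
            d.d,
            metric=False,
            n_components=2,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            normalized_stress=True,
            random_state=seed,
        )
    return OrdinationSpace(coordinates=coords, kind="nmds2d", stress=float(stress))
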