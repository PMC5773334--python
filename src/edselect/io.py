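"""Delimited-text readers/writers, run configuration, and the end-to-end pipeline.

All tables are CSV. The environment table carries a second header line
(prefixed ``#type,``) tagging each variable column with its type, so CVT
subsetting survives a round trip. One root seed fans out to per-stage seeds by
fixed offsets, making every stage independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmark, env_space, maxdisp, pmedian, synthetic
from .env_space import DistanceMatrix, EnvironmentMatrix, OrdinationSpace
from .synthetic import LandscapeConfig, NicheConfig, PresenceAbsenceMatrix

logger = logging.getLogger("edselect")

#: Fixed seed offsets per pipeline stage (added to the root seed mod 2**31).
STAGE_SEED_OFFSETS = {
    "environment": 11,
    "species": 23,
    "nmds": 37,
    "pmedian": 53,
    "baseline": 71,
}


def stage_seed(root_seed: int, stage: str) -> int:
    return (int(root_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_environment(env: EnvironmentMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("site_id," + ",".join(env.var_names) + "\n")
        fh.write("#type," + ",".join(env.var_types) + "\n")
        for sid, row in zip(env.site_ids, env.values):
            fh.write(sid + "," + ",".join(format(v, ".10g") for v in row) + "\n")


def read_environment(path: str | Path) -> EnvironmentMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(",")
        type_line = fh.readline().rstrip("\n").split(",")
    if type_line[0] != "#type":
        raise ValueError(f"{path}: second line must be the '#type,...' tag row")
    df = pd.read_csv(path, skiprows=[1])
    return EnvironmentMatrix(
        values=df[header[1:]].to_numpy(dtype=float),
        site_ids=df[header[0]].astype(str).tolist(),
        var_names=header[1:],
        var_types=[t.lower() for t in type_line[1:]],
    )


def write_presence_absence(pa: PresenceAbsenceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(pa.occ, index=pd.Index(pa.site_ids, name="site_id"),
                      columns=pa.species_ids)
    df.to_csv(path)


def read_presence_absence(path: str | Path) -> PresenceAbsenceMatrix:
    df = pd.read_csv(path, index_col=0)
    return PresenceAbsenceMatrix(
        occ=df.to_numpy(),
        site_ids=df.index.astype(str).tolist(),
        species_ids=[str(c) for c in df.columns],
    )


def write_ordination(space: OrdinationSpace, path: str | Path,
                     site_ids: list[str] | None = None) -> None:
    n, k = space.coordinates.shape
    idx = pd.Index(site_ids if site_ids is not None else range(n), name="site_id")
    df = pd.DataFrame(space.coordinates, index=idx,
                      columns=[f"axis_{i + 1}" for i in range(k)])
    df.to_csv(path)


def write_selection(result: maxdisp.SelectionResult, path: str | Path,
                    site_ids: list[str] | None = None) -> None:
    rows = []
    for order, idx in enumerate(result.selected):
        rows.append({
            "order": order,
            "site_index": idx,
            "site_id": site_ids[idx] if site_ids else str(idx),
            "objective": result.trajectory[order] if order < len(result.trajectory) else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sai_report(report: benchmark.SAIReport, path: str | Path, **labels) -> None:
    df = report.to_frame()
    for key, value in labels.items():
        df.insert(0, key, value)
    df["median_sai"] = report.median_sai
    df.to_csv(path, index=False)


def write_provenance(path: str | Path, payload: dict) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass
class RunConfig:
    """End-to-end run: either file inputs or a synthetic-generation block."""

    environment_path: str | None = None
    presence_path: str | None = None
    synthetic: dict | None = None  # kwargs for LandscapeConfig / NicheConfig
    cvt: str = "CVT1"
    approach: str = "maxdisp"  # "maxdisp" | "pmedian"
    fractions: tuple[float, ...] = benchmark.DEFAULT_FRACTIONS
    reps: int = 1000
    seed: int = 0
    grid_divisions: int = 50
    pmedian_starts: int = 32
    pmedian_elite: int = 10
    output_dir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.environment_path is not None and self.presence_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError("exactly one of {file inputs, synthetic block} must be given")
        if self.approach not in ("maxdisp", "pmedian"):
            raise ValueError("approach must be 'maxdisp' or 'pmedian'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        return cls(**raw)


def simulate_inputs(block: dict, root_seed: int):
    """Generate a landscape + species matrix from a synthetic config block."""
    land_kwargs = dict(block.get("landscape", {}))
    niche_kwargs = dict(block.get("niche", {}))
    land_kwargs.setdefault("seed", stage_seed(root_seed, "environment"))
    niche_kwargs.setdefault("seed", stage_seed(root_seed, "species"))
    if "variable_groups" in land_kwargs:
        land_kwargs["variable_groups"] = tuple(
            (str(t), int(c)) for t, c in land_kwargs["variable_groups"]
        )
    landscape = synthetic.generate_environment(LandscapeConfig(**land_kwargs))
    pa = synthetic.generate_species(landscape.latent, NicheConfig(**niche_kwargs))
    return landscape.environment, pa


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> benchmark.SAIReport:
    """Execute subset -> PCA -> (distances | NMDS + demand grid) -> selection
    at each fraction -> SAI report; optionally write artifacts."""
    with _stage("inputs"):
        if config.synthetic is not None:
            env, pa = simulate_inputs(config.synthetic, config.seed)
        else:
            env = read_environment(config.environment_path)
            pa = read_presence_absence(config.presence_path)
        if env.n_sites != pa.n_sites:
            raise ValueError("environment and presence tables disagree on site count")

    with _stage("cvt_subset"):
        env_cvt = env_space.subset_by_cvt(env, config.cvt)
        dropped = env_cvt.zero_variance_columns()
        if dropped:
            logger.info("dropping %d zero-variance columns before PCA", len(dropped))
            env_cvt = env_cvt.drop_zero_variance()

    with _stage("pca"):
        pca = env_space.pca_kaiser(env_cvt)
        logger.info("retained %d PCA components (kaiser_fallback=%s)",
                    pca.k, pca.kaiser_fallback)

    nmds = None
    with _stage("distances"):
        dist = env_space.euclidean_distances(pca)

    if config.approach == "maxdisp":
        def selector(p: int):
            return maxdisp.greedy_maxdisp(maxdisp.SelectionProblem(dist, p)).selected
    else:
        with _stage("nmds"):
            nmds = env_space.nmds_2d(dist, seed=stage_seed(config.seed, "nmds"))
            logger.info("NMDS stress-1 = %.4f", nmds.stress)
        with _stage("demand_grid"):
            grid = pmedian.build_demand_grid(nmds, g=config.grid_divisions)
        pm_config = pmedian.PMedianConfig(
            starts=config.pmedian_starts,
            elite_size=config.pmedian_elite,
            seed=stage_seed(config.seed, "pmedian"),
        )

        def selector(p: int):
            return pmedian.solve_pmedian(nmds, grid, p, pm_config).selected

    with _stage("evaluate"):
        report = benchmark.fraction_sweep(
            pa,
            selector,
            fractions=config.fractions,
            reps=config.reps,
            seed=stage_seed(config.seed, "baseline"),
        )

    if config.output_dir is not None:
        with _stage("write_artifacts"):
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_ordination(pca, out / "pca_coordinates.csv", env.site_ids)
            if nmds is not None:
                write_ordination(nmds, out / "nmds_coordinates.csv", env.site_ids)
            write_sai_report(report, out / "sai_report.csv",
                             approach=config.approach, cvt=config.cvt)
            write_provenance(out / "provenance.yaml", {
                "seed": config.seed,
                "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_SEED_OFFSETS},
                "cvt": config.cvt,
                "approach": config.approach,
                "fractions": list(config.fractions),
                "reps": config.reps,
                "pca_components": int(pca.k),
                "nmds_stress": None if nmds is None else float(nmds.stress),
            })

    return report
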