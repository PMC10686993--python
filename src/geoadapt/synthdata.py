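"""Synthetic genotype/climate bundles with known adaptive ground truth.

The generator emulates the study design the pipeline is built for: a dozen
sampling sites strung along a one-dimensional geographic gradient formed by
the admixture of two colonization waves, a handful of correlated bioclimatic
variables varying smoothly over a raster, and a minority of loci whose
allele frequencies are coupled to one of those variables.  Neutral
population structure follows the Balding-Nichols model: subpopulation
(here, ancestral-source) allele frequencies are Beta-distributed around a
shared ancestral frequency with differentiation parameter ``fst_drift``,
and each individual's expected frequency mixes the source frequencies by
its ancestry proportions.  Environmental coupling acts on the logit of the
individual-level expected frequency so that frequencies stay in (0, 1)
smoothly.

A single numpy Generator seeded from ``config.seed`` drives every draw, so
one config yields one bit-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genio import (
    EnvTable,
    GenotypeMatrix,
    PopMap,
    RasterGrid,
    write_env_table,
    write_popmap,
    write_raster,
    write_vcf,
)

logger = logging.getLogger(__name__)

# offset/scale giving each variable bioclim-like units (deg C, %, deg C, mm)
_VAR_UNITS = [(9.0, 3.0), (55.0, 8.0), (22.0, 4.0), (900.0, 250.0)]
_VAR_NAMES = ["bio01", "bio03", "bio05", "bio12"]
# mixing weights of four standardized latent spatial fields (N-S ramp,
# radial bowl, a 1.5-cycle N-S wave, a tilted E-W ramp) per variable; chosen
# so that site-level pairwise correlations are moderate (|r| ~ 0.4-0.5),
# i.e. all variables survive an r < 0.7 collinearity screen, as is typical
# of a curated bioclim subset
_VAR_MIX = [
    (1.0, 0.151, 0.0, 0.0),
    (0.446, -0.461, 0.179, 0.806),
    (-0.993, 0.772, 0.954, -0.047),
    (0.345, 0.196, -0.19, 0.738),
]


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic bundle.

    Defaults mirror the emulated design: 12 populations of 10 diploids on a
    two-source admixture cline, 2000 unlinked SNPs of which 100 are coupled
    to one of 4 correlated bioclimatic variables with logit-scale slope
    ``beta`` per environmental SD.
    """

    n_pops: int = 12
    n_per_pop: int = 10
    L: int = 2000
    L_adaptive: int = 100
    K_anc: int = 2
    fst_drift: float = 0.2
    beta: float = 1.5
    env_vars: int = 4
    grid_shape: tuple[int, int] = (20, 20)
    future_shift: float | tuple[float, ...] = 1.0
    future_pattern: str = "uniform"  # or "gradient": shift scales with latitude
    climate_pattern: str = "correlated"  # or "ramp": pure north-south, no noise
    missing_rate: float = 0.02
    cline_steepness: float = 8.0
    dirichlet_conc: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst_drift < 1):
            raise ValueError("fst_drift must lie in (0, 1)")
        if self.L_adaptive > self.L:
            raise ValueError("L_adaptive cannot exceed L")
        if self.n_pops < 2:
            raise ValueError("need at least two populations")
        for name in ("n_per_pop", "L", "K_anc", "env_vars"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if min(self.grid_shape) < 2:
            raise ValueError("grid_shape must be at least 2 x 2 in each dimension")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.future_pattern not in ("uniform", "gradient"):
            raise ValueError("future_pattern must be 'uniform' or 'gradient'")
        if self.climate_pattern not in ("correlated", "ramp"):
            raise ValueError("climate_pattern must be 'correlated' or 'ramp'")

    @property
    def n(self) -> int:
        return self.n_pops * self.n_per_pop

    def shifts(self) -> np.ndarray:
        s = np.asarray(self.future_shift, dtype=float)
        if s.ndim == 0:
            s = np.full(self.env_vars, float(s))
        if s.size != self.env_vars:
            raise ValueError("future_shift must be scalar or one value per variable")
        return s

    def var_names(self) -> list[str]:
        names = list(_VAR_NAMES)
        while len(names) < self.env_vars:
            names.append(f"env{len(names) + 1:02d}")
        return names[: self.env_vars]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        if isinstance(d["future_shift"], tuple):
            d["future_shift"] = list(d["future_shift"])
        return d


@dataclasses.dataclass
class ClimateBundle:
    grid_current: RasterGrid
    grid_future: RasterGrid
    env_current: EnvTable
    env_future: EnvTable
    sites: pd.DataFrame  # pop, lat, lon, row, col
    correlations: pd.DataFrame


@dataclasses.dataclass
class SimBundle:
    """One complete synthetic data set plus its ground truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    popmap: PopMap
    climate: ClimateBundle
    q_true: np.ndarray
    truth: pd.DataFrame  # locus_id, is_adaptive, coupled_var, beta


def simulate_climate(config: SimulationConfig, rng: np.random.Generator) -> ClimateBundle:
    """Smooth correlated climate fields on a raster, sampled at the sites.

    Each variable is a fixed mixture of three latent spatial fields (a
    north-south ramp, an east-west ramp, a radial bowl) plus white noise,
    rescaled to bioclim-like units.  The future grid adds
    ``future_shift`` (in units of each variable's spatial SD) per variable,
    either uniformly or scaled by latitude (``future_pattern='gradient'``)
    so the shift itself varies over space.
    """
    nrows, ncols = config.grid_shape
    if min(config.grid_shape) < 2:
        raise ValueError("degenerate grid: each dimension must be >= 2")
    # normalized coordinates: yn grows northwards, row 0 is the northern edge
    yn = (nrows - 1 - np.arange(nrows))[:, None] / (nrows - 1) * np.ones((1, ncols))
    xn = np.ones((nrows, 1)) * np.arange(ncols)[None, :] / (ncols - 1)
    latent = [yn, (xn - 0.5) ** 2 + (yn - 0.5) ** 2,
              np.sin(3 * np.pi * yn), xn - 0.5 * yn]
    fields = [(f - f.mean()) / f.std() for f in latent]

    names = config.var_names()
    data_cur: dict[str, np.ndarray] = {}
    for v, name in enumerate(names):
        if config.climate_pattern == "ramp":
            raw = -yn  # warm south, cold north; strictly monotone in latitude
        else:
            w = _VAR_MIX[v % len(_VAR_MIX)]
            raw = sum(wi * fi for wi, fi in zip(w, fields))
            raw = raw + rng.normal(0.0, 0.05 * raw.std(), size=raw.shape)
        offset, scale = _VAR_UNITS[v % len(_VAR_UNITS)]
        z = (raw - raw.mean()) / raw.std()
        data_cur[name] = offset + scale * z

    # Britain-like georeference: square cells, lower-left at (50N, 6W)
    cellsize = 8.0 / max(nrows, ncols)
    grid_cur = RasterGrid(data_cur, xllcorner=-6.0, yllcorner=50.0,
                          cellsize=cellsize, epoch="current")

    shifts = config.shifts()
    if config.future_pattern == "gradient":
        factor = 0.25 + 1.5 * yn  # stronger warming towards the north
    else:
        factor = np.ones((nrows, ncols))
    data_fut = {
        name: data_cur[name] + shifts[v] * data_cur[name].std() * factor
        for v, name in enumerate(names)
    }
    grid_fut = RasterGrid(data_fut, xllcorner=-6.0, yllcorner=50.0,
                          cellsize=cellsize, epoch="future")

    # sites along a south-to-north transect with a gentle east-west wiggle
    t = np.linspace(0.0, 1.0, config.n_pops)
    yn_site = 0.06 + 0.88 * t
    xn_site = 0.30 + 0.40 * t + 0.15 * np.sin(2 * np.pi * t)
    rows = np.clip(np.round((1 - yn_site) * (nrows - 1)).astype(int), 0, nrows - 1)
    cols = np.clip(np.round(xn_site * (ncols - 1)).astype(int), 0, ncols - 1)
    pops = [f"P{j + 1:02d}" for j in range(config.n_pops)]
    lat = np.array([grid_cur.cell_center(r, c)[0] for r, c in zip(rows, cols)])
    lon = np.array([grid_cur.cell_center(r, c)[1] for r, c in zip(rows, cols)])
    sites = pd.DataFrame({"pop": pops, "lat": lat, "lon": lon,
                          "row": rows, "col": cols}).set_index("pop")

    env_cur = EnvTable(pd.DataFrame(
        {name: data_cur[name][rows, cols] for name in names}, index=pops))
    env_fut = EnvTable(pd.DataFrame(
        {name: data_fut[name][rows, cols] for name in names}, index=pops))
    correlations = env_cur.frame.corr() if config.env_vars > 1 else pd.DataFrame(
        np.ones((1, 1)), index=names, columns=names)
    return ClimateBundle(grid_cur, grid_fut, env_cur, env_fut, sites, correlations)


def simulate_ancestry(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Individual ancestry proportions along a logistic cline.

    Population mean ancestry follows a softmax of negative distances to
    ``K_anc`` evenly spaced cline centers (for two sources this is exactly a
    logistic cline in the site index); individuals draw Dirichlet around the
    population mean with concentration ``dirichlet_conc``.
    """
    K = config.K_anc
    n = config.n
    if K == 1:
        return np.ones((n, 1))
    t = np.linspace(0.0, 1.0, config.n_pops)
    centers = np.linspace(0.0, 1.0, K)
    logits = -config.cline_steepness * np.abs(t[:, None] - centers[None, :])
    logits -= logits.max(axis=1, keepdims=True)
    means = np.exp(logits)
    means /= means.sum(axis=1, keepdims=True)
    Q = np.empty((n, K))
    for j in range(config.n_pops):
        alpha = config.dirichlet_conc * means[j] + 1e-3
        Q[j * config.n_per_pop:(j + 1) * config.n_per_pop] = rng.dirichlet(
            alpha, size=config.n_per_pop)
    return Q


def simulate_genotypes(
    config: SimulationConfig,
    q_true: np.ndarray,
    env: EnvTable,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Balding-Nichols genotypes with environment-coupled adaptive loci.

    Ancestral frequencies per source are Beta-distributed around a shared
    p_l ~ U(0.05, 0.95) with differentiation ``fst_drift``; an individual's
    neutral expected frequency mixes the source frequencies by its ancestry.
    Adaptive loci additionally shift the logit of that frequency by
    ``beta`` times the site-standardized value of their coupled variable.
    Genotypes are Binomial(2, frequency); missingness is injected uniformly.
    """
    n, L, K = config.n, config.L, config.K_anc
    if q_true.shape != (n, K):
        raise ValueError("q_true misaligned with config")
    F = config.fst_drift
    p_anc = rng.uniform(0.05, 0.95, size=L)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    f_sources = rng.beta(a[None, :], b[None, :], size=(K, L))
    freq = q_true @ f_sources  # (n, L)

    # environment coupling: per-site z-scores broadcast to individuals
    names = env.variables
    z_site = (env.frame - env.frame.mean()) / env.frame.std(ddof=0)
    pop_of_ind = np.repeat(np.arange(config.n_pops), config.n_per_pop)
    adaptive = rng.choice(L, size=config.L_adaptive, replace=False)
    adaptive.sort()
    coupled = [names[i % len(names)] for i in range(config.L_adaptive)]
    n_clipped = 0
    if config.L_adaptive and config.beta != 0.0:
        eta = logit(np.clip(freq[:, adaptive], 1e-9, 1 - 1e-9))
        for i, (l_pos, var) in enumerate(zip(range(config.L_adaptive), coupled)):
            zi = z_site[var].to_numpy()[pop_of_ind]
            eta[:, i] = eta[:, i] + config.beta * zi
        shifted = expit(eta)
        n_clipped = int(((shifted < 1e-6) | (shifted > 1 - 1e-6)).sum())
        freq[:, adaptive] = np.clip(shifted, 1e-6, 1 - 1e-6)
        if n_clipped:
            logger.info("simulate_genotypes: clipped %d shifted frequencies", n_clipped)

    dosage = rng.binomial(2, freq).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(size=dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    loci = pd.DataFrame({
        "chrom": "1",
        "pos": 100 * (np.arange(L) + 1),
        "id": [f"snp{l + 1:06d}" for l in range(L)],
        "ref": "A",
        "alt": "G",
    })
    samples = [
        f"P{j + 1:02d}_i{i + 1:02d}"
        for j in range(config.n_pops)
        for i in range(config.n_per_pop)
    ]
    G = GenotypeMatrix(samples, loci, dosage)

    is_adaptive = np.zeros(L, dtype=bool)
    is_adaptive[adaptive] = True
    coupled_full = np.array([None] * L, dtype=object)
    coupled_full[adaptive] = coupled
    truth = pd.DataFrame({
        "locus_id": loci["id"],
        "is_adaptive": is_adaptive,
        "coupled_var": coupled_full,
        "beta": np.where(is_adaptive, config.beta, 0.0),
    })
    return G, truth


def simulate(config: SimulationConfig) -> SimBundle:
    """Generate a full bundle from one seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    climate = simulate_climate(config, rng)
    q_true = simulate_ancestry(config, rng)
    G, truth = simulate_genotypes(config, q_true, climate.env_current, rng)
    sites = climate.sites
    popmap = PopMap(pd.DataFrame({
        "sample": G.samples,
        "pop": [s.split("_")[0] for s in G.samples],
        "lat": [sites.loc[s.split("_")[0], "lat"] for s in G.samples],
        "lon": [sites.loc[s.split("_")[0], "lon"] for s in G.samples],
    }))
    return SimBundle(config, G, popmap, climate, q_true, truth)


def write_fixture_bundle(bundle: SimBundle, directory: str | Path) -> dict[str, object]:
    """Write VCF, popmap, env tables, rasters, truth table and a manifest.

    Everything round-trips losslessly through the readers in
    :mod:`geoadapt.genio`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}")
    paths: dict[str, object] = {}
    paths["vcf"] = directory / "genotypes.vcf"
    write_vcf(bundle.genotypes, paths["vcf"])
    paths["popmap"] = directory / "popmap.tsv"
    write_popmap(bundle.popmap, paths["popmap"])
    paths["env_current"] = directory / "env_current.csv"
    write_env_table(bundle.climate.env_current, paths["env_current"])
    paths["env_future"] = directory / "env_future.csv"
    write_env_table(bundle.climate.env_future, paths["env_future"])
    paths["rasters_current"] = write_raster(bundle.climate.grid_current, directory)
    paths["rasters_future"] = write_raster(bundle.climate.grid_future, directory)
    paths["truth"] = directory / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["q_true"] = directory / "q_true.tsv"
    pd.DataFrame(
        bundle.q_true,
        index=bundle.genotypes.samples,
        columns=[f"anc{k + 1}" for k in range(bundle.q_true.shape[1])],
    ).to_csv(paths["q_true"], sep="\t")
    manifest = {
        "config": bundle.config.to_dict(),
        "seed": bundle.config.seed,
        "env_correlations": bundle.climate.correlations.round(4).to_dict(),
        "n_samples": bundle.genotypes.n,
        "n_loci": bundle.genotypes.L,
    }
    paths["manifest"] = directory / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
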