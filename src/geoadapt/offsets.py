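"""Forward projection of adaptive composition: adaptive index, genomic and
geographic offsets, standing genetic variation (SGV), and the population
adaptive index (PAI).

The adaptively enriched SNP set is ordinated against the retained climate
variables; the environmental-variable scores on the leading canonical axes
define a linear "adaptive index" that can be evaluated at any climate
pixel (standardized with the fit-time parameters).  The genomic offset at
a pixel aggregates the per-axis displacement of the adaptive index between
current and future climate; the geographic offset is the great-circle
distance to the nearest location whose current adaptive composition
matches the pixel's future requirement.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .genio import EnvTable, GenotypeMatrix, RasterGrid
from .ordination import RDAFit, fit_rda

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclasses.dataclass
class AdaptiveSpace:
    """Environmental axis scores plus the standardization that produced them."""

    env_scores: pd.DataFrame     # variables x axes (correlation biplot scores)
    eigenvalues: np.ndarray      # per retained axis, non-increasing
    means: pd.Series             # fit-time per-variable mean
    sds: pd.Series               # fit-time per-variable SD
    frac_constrained: float
    axis_var_fractions: np.ndarray  # share of constrained variance per axis

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            raise ValueError("standardization SDs must be positive")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("axes must be ordered by non-increasing eigenvalue")

    @property
    def n_axes(self) -> int:
        return self.env_scores.shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.env_scores.index)


def fit_enriched_rda(
    G_enriched: GenotypeMatrix | np.ndarray,
    env: EnvTable,
    sample_sites: list[str] | None = None,
    Z=None,
    n_axes: int = 3,
) -> tuple[AdaptiveSpace, RDAFit]:
    """Ordinate the adaptively enriched SNP set on the climate variables.

    ``env`` holds one row per site; with ``sample_sites`` given (one site
    label per genotype row) the site values are broadcast to individuals.
    The default second model is unconditioned; pass ``Z`` for a
    conditioned variant.  Fit-time standardization parameters are stored
    so grids can later be projected on the same scale.
    """
    dosage = (G_enriched.dosage if isinstance(G_enriched, GenotypeMatrix)
              else np.asarray(G_enriched, dtype=float))
    if dosage.shape[1] < n_axes:
        raise ValueError(
            f"only {dosage.shape[1]} enriched SNPs for {n_axes} requested axes")
    Xz = env.standardize()
    if sample_sites is not None:
        X = Xz.loc[sample_sites].to_numpy(dtype=float)
    else:
        X = Xz.to_numpy(dtype=float)
    if X.shape[0] != dosage.shape[0]:
        raise ValueError("environment rows not aligned to genotype rows")
    Y = dosage.copy()
    col_mean = np.nanmean(Y, axis=0)
    inds = np.where(np.isnan(Y))
    Y[inds] = np.take(col_mean, inds[1])
    fit = fit_rda(Y, X, Z=Z, n_axes=n_axes, x_names=env.variables)
    k = fit.n_axes
    eig = fit.eigenvalues[:k]
    space = AdaptiveSpace(
        env_scores=fit.env_scores.iloc[:, :k],
        eigenvalues=eig,
        means=env.means.copy(),
        sds=env.sds.copy(),
        frac_constrained=fit.frac_constrained,
        axis_var_fractions=fit.eigenvalues[:k] / fit.eigenvalues.sum(),
    )
    return space, fit


def adaptive_index(space: AdaptiveSpace, grid: RasterGrid) -> np.ndarray:
    """Per-pixel adaptive index on each retained axis.

    AI_a(pixel) = sum_v score_{v,a} * z_v(pixel) with z computed from the
    fit-time standardization; returns an (axes, rows, cols) array with NaN
    where any variable is NODATA.
    """
    missing = [v for v in space.variables if v not in grid.data]
    if missing:
        raise ValueError(f"grid lacks fitted variables: {missing}")
    mask = grid.valid_mask()
    out = np.full((space.n_axes,) + grid.shape, np.nan)
    scores = space.env_scores.to_numpy()
    for a in range(space.n_axes):
        acc = np.zeros(grid.shape)
        for j, var in enumerate(space.variables):
            z = (grid.data[var] - space.means[var]) / space.sds[var]
            acc += scores[j, a] * z
        out[a][mask] = acc[mask]
    return out


def site_adaptive_index(space: AdaptiveSpace, env_values: pd.DataFrame) -> np.ndarray:
    """Adaptive index of tabulated sites (rows) on each axis (columns)."""
    z = (env_values[space.variables] - space.means) / space.sds
    return z.to_numpy(dtype=float) @ space.env_scores.to_numpy()


def genomic_offset(
    ai_current: np.ndarray,
    ai_future: np.ndarray,
    weights: np.ndarray | None = None,
    agg: str = "l1",
) -> np.ndarray:
    """Aggregate per-axis adaptive-index displacement into one offset map.

    Per axis the displacement is |AI_future - AI_current|; the default
    aggregation sums these absolute displacements across axes (L1), with
    ``agg='l2'`` (Euclidean over axes) and per-axis ``weights``
    (e.g. eigenvalue-proportional) selectable.  NaN propagates.
    """
    ai_current = np.asarray(ai_current, dtype=float)
    ai_future = np.asarray(ai_future, dtype=float)
    if ai_current.shape != ai_future.shape:
        raise ValueError("current/future adaptive-index shapes differ")
    d = np.abs(ai_future - ai_current)
    if weights is None:
        w = np.ones(d.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (d.shape[0],):
            raise ValueError("one weight per axis required")
    if agg == "l1":
        return np.tensordot(w, d, axes=(0, 0))
    if agg == "l2":
        return np.sqrt(np.tensordot(w, d**2, axes=(0, 0)))
    raise ValueError("agg must be 'l1' or 'l2'")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometers (inputs in degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclasses.dataclass
class GeographicOffsetResult:
    offset_km: np.ndarray   # per pixel; NaN = NODATA or no-match sentinel
    no_match: np.ndarray    # boolean, True where no location fell within tolerance
    tolerance: float


def geographic_offset(
    ai_current: np.ndarray,
    ai_future: np.ndarray,
    grid: RasterGrid,
    tolerance: float | None = None,
    match_sites: pd.DataFrame | None = None,
    site_ai_current: np.ndarray | None = None,
) -> GeographicOffsetResult:
    """Distance to the nearest location already matching the future optimum.

    For each valid pixel, the match set holds the locations (all valid
    pixels by default; the sampled populations when ``match_sites`` with
    ``site_ai_current`` is given) whose *current* adaptive-index vector is
    within Euclidean distance ``tolerance`` of the pixel's *future* vector;
    the offset is the minimal great-circle distance to that set, or NaN
    (flagged in ``no_match``) when the set is empty.  The default
    tolerance is 5% of the mean per-axis range of the current index.
    """
    ai_current = np.asarray(ai_current, dtype=float)
    ai_future = np.asarray(ai_future, dtype=float)
    n_axes = ai_current.shape[0]
    mask = np.isfinite(ai_current).all(axis=0) & np.isfinite(ai_future).all(axis=0)
    cur = ai_current[:, mask].T   # (P, axes)
    fut = ai_future[:, mask].T
    if tolerance is None:
        ranges = cur.max(axis=0) - cur.min(axis=0)
        tolerance = 0.05 * float(ranges.mean())
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    lat_rows, lon_cols = grid.latlon_arrays()
    rr, cc = np.where(mask)
    plat = lat_rows[rr]
    plon = lon_cols[cc]

    if match_sites is not None:
        if site_ai_current is None:
            raise ValueError("site_ai_current required with match_sites")
        tgt = np.asarray(site_ai_current, dtype=float)
        tlat = match_sites["lat"].to_numpy(dtype=float)
        tlon = match_sites["lon"].to_numpy(dtype=float)
    else:
        tgt = cur
        tlat, tlon = plat, plon

    dist_ai = cdist(fut, tgt)
    geo = haversine_km(plat[:, None], plon[:, None], tlat[None, :], tlon[None, :])
    geo_masked = np.where(dist_ai <= tolerance, geo, np.inf)
    best = geo_masked.min(axis=1)
    no_match_flat = ~np.isfinite(best)
    if no_match_flat.any():
        logger.info("geographic_offset: %d pixels without a match within "
                    "tolerance %.4g", int(no_match_flat.sum()), tolerance)

    offset = np.full(grid.shape, np.nan)
    offset[rr, cc] = np.where(no_match_flat, np.nan, best)
    no_match = np.zeros(grid.shape, dtype=bool)
    no_match[rr, cc] = no_match_flat
    return GeographicOffsetResult(offset, no_match, float(tolerance))


# ---------------------------------------------------------------------------
# per-population summaries
# ---------------------------------------------------------------------------


def _select_loci(P: pd.DataFrame, candidate_loci) -> pd.DataFrame:
    """Columns of P named or masked by ``candidate_loci`` (labels or boolean)."""
    arr = np.asarray(candidate_loci)
    sub = P.loc[:, arr]  # boolean arrays act as masks, label arrays as names
    if sub.shape[1] == 0:
        raise ValueError("candidate locus set is empty")
    return sub


def sgv(P: pd.DataFrame, candidate_loci: np.ndarray, mode: str = "binomial") -> pd.Series:
    """Standing genetic variation per population at candidate loci.

    Default convention: mean over candidate loci of the per-locus binomial
    allele variance p(1-p), bounded in [0, 0.25].  ``mode='across'``
    instead averages, over loci, each locus's across-population variance of
    allele frequency (and therefore returns the same value for every
    population's pool context; exposed for comparison).  All-missing loci
    are excluded from a population's mean.
    """
    sub = _select_loci(P, candidate_loci)
    if mode == "binomial":
        v = sub * (1 - sub)
        return v.mean(axis=1, skipna=True)
    if mode == "across":
        across = sub.var(axis=0, ddof=1)
        return pd.Series(float(across.mean()), index=P.index)
    raise ValueError("mode must be 'binomial' or 'across'")


def pai(P: pd.DataFrame, candidate_loci: np.ndarray) -> pd.Series:
    """Population adaptive index: mean |p_jl - pbar_l| over candidate loci.

    pbar_l is the unweighted mean allele frequency across populations;
    high values flag populations near fixation at adaptive loci, with
    little room for further response to selection.
    """
    if P.shape[0] < 2:
        raise ValueError("PAI needs at least two populations")
    sub = _select_loci(P, candidate_loci)
    pbar = sub.mean(axis=0, skipna=True)
    return (sub - pbar).abs().mean(axis=1, skipna=True)


def fixed_fraction(P: pd.DataFrame, candidate_loci: np.ndarray,
                   threshold: float = 0.01) -> pd.Series:
    """Fraction of candidate loci (nearly) fixed per population."""
    sub = _select_loci(P, candidate_loci)
    fixed = (sub <= threshold) | (sub >= 1 - threshold)
    return fixed.sum(axis=1) / sub.notna().sum(axis=1)


def average_future_grids(grids: list[RasterGrid]) -> RasterGrid:
    """Average several model projections variable-by-variable.

    Helper for combining general-circulation-model grids into one future
    climate surface; all grids must share variables and georeference.
    """
    if not grids:
        raise ValueError("no grids to average")
    ref = grids[0]
    for g in grids[1:]:
        if set(g.variables) != set(ref.variables) or g.shape != ref.shape:
            raise ValueError("grids must share variables and shape")
        if not (np.isclose(g.cellsize, ref.cellsize)
                and np.isclose(g.xllcorner, ref.xllcorner)
                and np.isclose(g.yllcorner, ref.yllcorner)):
            raise ValueError("grids must share georeference")
    data = {
        v: np.mean([g.data[v] for g in grids], axis=0) for v in ref.variables
    }
    return RasterGrid(data, ref.xllcorner, ref.yllcorner, ref.cellsize,
                      ref.nodata, epoch="future")
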