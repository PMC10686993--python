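"""Genome scans for candidate adaptive loci and their three-way intersection.

Three complementary scans are combined: (1) a per-SNP Weir-Cockerham F_ST
scan flagging loci above an empirical percentile; (2) a PCA-based scan in
the style of pcadapt — z-statistics of each SNP against the leading K
principal components, summarized by a robust Mahalanobis distance and
converted to chi-square p-values after genomic-inflation rescaling; and
(3) the analogous scan on the SNP loadings of a (partial) RDA.  SNPs
flagged by all three methods form the candidate set; a stricter
RDA q-value cutoff defines the adaptively enriched set used for offset
projection.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.covariance import LedoitWolf, MinCovDet

from .genio import GenotypeMatrix, PopMap
from .ordination import RDAFit
from .popstruct import _pop_summaries, patterson_scale, wc_variance_components

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# F_ST scan
# ---------------------------------------------------------------------------


def per_snp_fst(G: GenotypeMatrix, popmap: PopMap) -> np.ndarray:
    """Per-locus multi-population Weir-Cockerham theta.

    NaN where the estimator is undefined (monomorphic locus or empty
    denominator); such loci are excluded from percentile flagging.
    """
    pops, n, p, h = _pop_summaries(G, popmap)
    if len(pops) < 2:
        raise ValueError("per-SNP F_ST needs at least two populations")
    a, b, c = wc_variance_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    denom = a + b + c
    theta[~np.isfinite(denom) | (denom <= 0)] = np.nan
    return theta


def fst_outliers(fst: np.ndarray, pct: float = 95.0) -> np.ndarray:
    """Flag loci strictly above the empirical ``pct``-th percentile.

    The percentile is computed over defined values only; boundary ties are
    resolved by the strict inequality (logged when present).
    """
    defined = np.isfinite(fst)
    if not defined.any():
        return np.zeros_like(fst, dtype=bool)
    threshold = np.percentile(fst[defined], pct)
    flags = defined & (fst > threshold)
    ties = defined & (fst == threshold)
    if ties.sum() > 1:
        logger.info("fst_outliers: %d loci tied at the %.0fth percentile "
                    "boundary excluded by strict inequality", int(ties.sum()), pct)
    return flags


# ---------------------------------------------------------------------------
# Mahalanobis machinery shared by the PCA and RDA scans
# ---------------------------------------------------------------------------


def _robust_mahalanobis(Z: np.ndarray, robust: str = "mad") -> np.ndarray:
    """Squared Mahalanobis distances of row vectors with a robust center/scatter.

    Default: columns centered by the median and scaled by 1.4826*MAD, then a
    Ledoit-Wolf shrinkage covariance of the standardized vectors.  ``robust=
    'mcd'`` uses the minimum covariance determinant instead.
    """
    Z = np.asarray(Z, dtype=float)
    if robust == "mcd":
        est = MinCovDet(random_state=0).fit(Z)
        return est.mahalanobis(Z)
    med = np.median(Z, axis=0)
    mad = 1.4826 * np.median(np.abs(Z - med), axis=0)
    mad = np.where(mad > 0, mad, 1.0)
    Zs = (Z - med) / mad
    if np.allclose(Zs, 0):
        return np.zeros(len(Z))
    cov = LedoitWolf().fit(Zs).covariance_
    cov_inv = np.linalg.pinv(cov)
    centered = Zs - Zs.mean(axis=0)
    return np.einsum("ij,jk,ik->i", centered, cov_inv, centered)


def _inflation_and_pvalues(d2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Rescale squared distances by the genomic inflation factor and convert
    to upper-tail chi-square p-values.

    lambda = median(D^2) / median(chi^2_df); a degenerate all-zero scan
    (lambda = 0) yields p = 1 everywhere by convention.
    """
    lam = float(np.median(d2)) / chi2.ppf(0.5, df)
    if lam <= 0:
        return np.ones_like(d2), 0.0
    p = chi2.sf(d2 / lam, df)
    return p, lam


@dataclasses.dataclass
class ScanResult:
    d2: np.ndarray          # squared Mahalanobis distances (NaN = excluded)
    p: np.ndarray
    q: np.ndarray
    inflation: float
    df: int
    tested: np.ndarray      # boolean mask of tested loci


# ---------------------------------------------------------------------------
# pcadapt-style scan
# ---------------------------------------------------------------------------


def choose_K_scree(eigenvalues: np.ndarray) -> tuple[int, bool]:
    """Elbow heuristic on a scree of eigenvalues (Cattell's rule).

    K is the last index (1-based) whose drop to the next eigenvalue is at
    least 10% of the first drop; a flat spectrum returns K=1 with a
    warning flag, and a spectrum whose drops never fall below the 10%
    cutoff within the window (no elbow) is flagged too.
    Returns (K, warned).
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size < 3:
        raise ValueError("need at least three eigenvalues")
    gaps = -np.diff(eig)
    first = gaps[0]
    if first <= 0 or not np.isfinite(first):
        logger.warning("choose_K_scree: flat spectrum, defaulting to K=1")
        return 1, True
    big = np.where(gaps >= 0.1 * first)[0]
    K = int(big.max()) + 1
    warned = False
    if K == eig.size - 1:
        logger.warning("choose_K_scree: no elbow within the provided spectrum")
        warned = True
    return K, warned


def pcadapt_scan(
    G: GenotypeMatrix,
    K: int,
    robust: str = "mad",
    qvalue_method: str = "storey",
) -> ScanResult:
    """PCA-based outlier scan (pcadapt-style).

    Each scaled SNP is regressed on the first K PC score vectors; the
    K-vector of regression z-statistics is summarized by a robust squared
    Mahalanobis distance across SNPs, rescaled by the genomic inflation
    factor, and referred to a chi-square with K degrees of freedom.
    Constant SNPs are excluded (NaN in all outputs).
    """
    X, kept = patterson_scale(G.dosage)
    n = X.shape[0]
    if K >= min(n, X.shape[1]):
        raise ValueError("K too large for the data")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    Uk = U[:, :K]  # orthonormal scores
    coef = Uk.T @ X                       # (K, L_kept)
    ss_tot = (X**2).sum(axis=0)
    ss_fit = (coef**2).sum(axis=0)
    df_resid = n - K - 1
    sigma2 = np.maximum(ss_tot - ss_fit, 0.0) / df_resid
    sigma = np.sqrt(np.where(sigma2 > 0, sigma2, np.inf))
    Zmat = (coef / sigma).T               # (L_kept, K)

    d2_kept = _robust_mahalanobis(Zmat, robust=robust)
    p_kept, lam = _inflation_and_pvalues(d2_kept, K)
    q_kept = qvalues(p_kept, method=qvalue_method)

    L = G.L
    d2 = np.full(L, np.nan)
    p = np.full(L, np.nan)
    q = np.full(L, np.nan)
    d2[kept], p[kept], q[kept] = d2_kept, p_kept, q_kept
    return ScanResult(d2, p, q, lam, K, kept)


# ---------------------------------------------------------------------------
# RDA-loading scan
# ---------------------------------------------------------------------------


def rdadapt_scan(
    rda_fit: RDAFit,
    n_axes: int = 3,
    robust: str = "mad",
    qvalue_method: str = "storey",
) -> ScanResult:
    """Mahalanobis outlier scan on (p)RDA SNP loadings.

    Loadings on the first ``n_axes`` canonical axes are standardized per
    axis, summarized by a robust squared Mahalanobis distance, rescaled by
    the genomic inflation factor and referred to chi-square with
    ``n_axes`` degrees of freedom.
    """
    if n_axes > rda_fit.n_axes:
        raise ValueError(
            f"requested {n_axes} axes but the fit retains {rda_fit.n_axes}")
    load = rda_fit.loadings[:, :n_axes]
    sd = load.std(axis=0, ddof=1)
    Z = np.where(sd > 0, (load - load.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    if np.allclose(Z, 0.0):
        d2 = np.zeros(len(load))
        p = np.ones(len(load))
        return ScanResult(d2, p, np.ones(len(load)), 0.0, n_axes,
                          np.ones(len(load), dtype=bool))
    d2 = _robust_mahalanobis(Z, robust=robust)
    p, lam = _inflation_and_pvalues(d2, n_axes)
    q = qvalues(p, method=qvalue_method)
    return ScanResult(d2, p, q, lam, n_axes, np.ones(len(load), dtype=bool))


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """Convert p-values to q-values.

    ``storey``: pi0 estimated at lambda = 0.5 (bounded to <= 1), then the
    step-up minimum q_i = min over ranks >= i of pi0 * p * m / rank.
    ``bh``: Benjamini-Hochberg, i.e. the same formula with pi0 = 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if method == "storey":
        pi0 = min(1.0, float((p > 0.5).mean()) / 0.5)
        pi0 = max(pi0, 1e-8)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError("method must be 'storey' or 'bh'")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CandidateSet:
    """Per-SNP statistics from all three scans plus the intersection flags."""

    table: pd.DataFrame  # locus_id, fst, d2_pc, p_pc, q_pc, d2_rda, p_rda,
                         # q_rda, flag_fst, flag_pc, flag_rda, three_way, enriched
    inflation_pc: float
    inflation_rda: float
    fdr: float
    enriched_fdr: float

    @property
    def three_way(self) -> np.ndarray:
        return self.table["three_way"].to_numpy()

    @property
    def enriched(self) -> np.ndarray:
        return self.table["enriched"].to_numpy()

    def counts(self) -> dict[str, int]:
        t = self.table
        return {
            "fst": int(t["flag_fst"].sum()),
            "pcadapt": int(t["flag_pc"].sum()),
            "rda": int(t["flag_rda"].sum()),
            "three_way": int(t["three_way"].sum()),
            "enriched": int(t["enriched"].sum()),
        }


def intersect_candidates(
    locus_ids: pd.Series | np.ndarray,
    fst: np.ndarray,
    pc_scan: ScanResult,
    rda_scan: ScanResult,
    fdr: float = 0.1,
    enriched_fdr: float = 0.05,
    fst_pct: float = 95.0,
) -> CandidateSet:
    """Three-way intersection of the F_ST, PCA and RDA outlier sets.

    The candidate set is {F_ST above the ``fst_pct`` percentile} AND
    {q_pc < fdr} AND {q_rda < fdr}.  The adaptively enriched set, used for
    the second (enriched) ordination and offset projection, is
    {q_rda < enriched_fdr} and is nested in the RDA set by construction.
    """
    flag_fst = fst_outliers(fst, pct=fst_pct)
    with np.errstate(invalid="ignore"):
        flag_pc = np.isfinite(pc_scan.q) & (pc_scan.q < fdr)
        flag_rda = np.isfinite(rda_scan.q) & (rda_scan.q < fdr)
        enriched = np.isfinite(rda_scan.q) & (rda_scan.q < enriched_fdr)
    three_way = flag_fst & flag_pc & flag_rda
    table = pd.DataFrame({
        "locus_id": np.asarray(locus_ids),
        "fst": fst,
        "d2_pc": pc_scan.d2,
        "p_pc": pc_scan.p,
        "q_pc": pc_scan.q,
        "d2_rda": rda_scan.d2,
        "p_rda": rda_scan.p,
        "q_rda": rda_scan.q,
        "flag_fst": flag_fst,
        "flag_pc": flag_pc,
        "flag_rda": flag_rda,
        "three_way": three_way,
        "enriched": enriched,
    })
    return CandidateSet(table, pc_scan.inflation, rda_scan.inflation,
                        fdr, enriched_fdr)
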