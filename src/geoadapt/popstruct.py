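"""Population structure: PCA, pairwise F_ST, and admixture ancestry.

The admixture estimator maximizes the standard binomial likelihood
l(Q, F) = sum_il [ g_il log h_il + (2 - g_il) log(1 - h_il) ],
h_il = sum_k q_ik f_kl, by EM block updates of Q and F — the same
stationary points as ADMIXTURE's block relaxation, reimplemented
behaviorally (not bit-compatibly) with restarts against local optima.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, PopMap

logger = logging.getLogger(__name__)

_EPS = 1e-9


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray        # (n, k)
    loadings: np.ndarray      # (L_kept, k)
    eigenvalues: np.ndarray   # (k,)
    var_fraction: np.ndarray  # (k,) of total scaled variance
    kept_loci: np.ndarray     # boolean mask over input loci
    all_eigenvalues: np.ndarray


def patterson_scale(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center dosages by 2*p_hat and scale by sqrt(p_hat(1-p_hat)).

    Missing entries are mean-imputed (zero after centering).  Returns the
    scaled matrix restricted to polymorphic loci and the kept-locus mask.
    """
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosage, axis=0) / 2.0
    kept = np.isfinite(p) & (p > 0) & (p < 1)
    if not kept.all():
        logger.info("patterson_scale: dropped %d zero-variance loci",
                    int((~kept).sum()))
    X = dosage[:, kept] - 2.0 * p[kept]
    X[~np.isfinite(X)] = 0.0
    X /= np.sqrt(p[kept] * (1 - p[kept]))
    return X, kept


def run_pca(G: GenotypeMatrix, k: int = 10) -> PCAResult:
    """SVD-based PCA of the Patterson-scaled dosage matrix."""
    if k >= min(G.n, G.L):
        raise ValueError("k must be smaller than min(n_samples, n_loci)")
    X, kept = patterson_scale(G.dosage)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eig = S**2 / (G.n - 1)
    frac = eig / eig.sum()
    return PCAResult(
        scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        eigenvalues=eig[:k],
        var_fraction=frac[:k],
        kept_loci=kept,
        all_eigenvalues=eig,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def _pop_summaries(G: GenotypeMatrix, popmap: PopMap):
    """Per-population, per-locus sample sizes, ALT frequencies and het freqs."""
    idx = popmap.indices(G.samples)
    pops = list(idx)
    n = np.zeros((len(pops), G.L))
    p = np.zeros((len(pops), G.L))
    h = np.zeros((len(pops), G.L))
    for j, rows in enumerate(idx.values()):
        sub = G.dosage[rows]
        valid = np.isfinite(sub)
        nj = valid.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[j] = np.nansum(sub, axis=0) / (2 * nj)
            h[j] = np.nansum(sub == 1, axis=0) / nj
        n[j] = nj
    return pops, n, p, h


def wc_variance_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-locus variance components a, b, c.

    ``n``, ``p``, ``h`` are (r populations x L loci) arrays of sample
    sizes, ALT frequencies and observed heterozygote frequencies.  Loci
    where any population has no data yield NaN components.
    """
    r = n.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = (n < 1).any(axis=0) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def pairwise_fst(G: GenotypeMatrix, popmap: PopMap) -> pd.DataFrame:
    """Weir-Cockerham two-population F_ST, ratio of sums across loci."""
    pops, n, p, h = _pop_summaries(G, popmap)
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    for j, pop in enumerate(pops):
        if (n[j] > 0).sum() and n[j][n[j] > 0].min() < 2:
            logger.warning("population %s has loci with <2 genotyped samples", pop)
    out = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b, c = wc_variance_components(n[[i, j]], p[[i, j]], h[[i, j]])
            ok = np.isfinite(a + b + c)
            denom = (a + b + c)[ok].sum()
            theta = a[ok].sum() / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = theta
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# admixture
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AncestryFit:
    Q: np.ndarray              # (n, K), rows on the simplex
    F: np.ndarray              # (K, L) source allele frequencies
    loglik_trace: np.ndarray
    K: int
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _admixture_loglik(g, two_minus_g, mask, Q, F) -> float:
    h = np.clip(Q @ F, _EPS, 1 - _EPS)
    ll = g * np.log(h) + two_minus_g * np.log1p(-h)
    return float(ll[mask].sum())


def _em_run(g, two_minus_g, mask, Q, F, tol, max_iter):
    n, L = g.shape
    n_valid = mask.sum(axis=1).astype(float)  # loci observed per individual
    trace = [_admixture_loglik(g, two_minus_g, mask, Q, F)]
    converged = False
    K = Q.shape[1]
    for _ in range(max_iter):
        h = np.clip(Q @ F, _EPS, 1 - _EPS)
        ga = g / h
        gb = two_minus_g / (1 - h)
        Q_new = np.empty_like(Q)
        F_new = np.empty_like(F)
        for k in range(K):
            A = Q[:, k][:, None] * F[k][None, :] * ga
            B = Q[:, k][:, None] * (1 - F[k])[None, :] * gb
            A[~mask] = 0.0
            B[~mask] = 0.0
            colA = A.sum(axis=0)
            colAB = colA + B.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                F_new[k] = np.where(colAB > 0, colA / colAB, F[k])
            Q_new[:, k] = (A + B).sum(axis=1) / (2.0 * n_valid)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        F_new = np.clip(F_new, _EPS, 1 - _EPS)
        Q, F = Q_new, F_new
        trace.append(_admixture_loglik(g, two_minus_g, mask, Q, F))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    return Q, F, np.array(trace), converged


def fit_admixture(
    G: GenotypeMatrix | np.ndarray,
    K: int,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
    seed: int = 0,
) -> AncestryFit:
    """Maximum-likelihood ancestry proportions by EM with restarts.

    Missing genotypes are skipped in both likelihood and updates.  The
    log-likelihood trace is non-decreasing (an EM guarantee); the best of
    ``n_restarts`` random initializations is returned.
    """
    dosage = G.dosage if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    mask = np.isfinite(dosage)
    g = np.nan_to_num(dosage)
    two_minus_g = np.where(mask, 2.0 - g, 0.0)

    if K == 1:
        with np.errstate(invalid="ignore"):
            f = np.nansum(dosage, axis=0) / (2.0 * np.maximum(mask.sum(axis=0), 1))
        Q = np.ones((dosage.shape[0], 1))
        F = np.clip(f[None, :], _EPS, 1 - _EPS)
        ll = _admixture_loglik(g, two_minus_g, mask, Q, F)
        return AncestryFit(Q, F, np.array([ll]), 1, True)

    rng = np.random.default_rng(seed)
    best: AncestryFit | None = None
    with np.errstate(invalid="ignore"):
        p_hat = np.nansum(dosage, axis=0) / (2.0 * np.maximum(mask.sum(axis=0), 1))
    for _ in range(n_restarts):
        Q0 = rng.dirichlet(np.ones(K), size=dosage.shape[0])
        F0 = np.clip(
            p_hat[None, :] + rng.normal(0.0, 0.1, size=(K, dosage.shape[1])),
            0.01, 0.99,
        )
        Q, F, trace, converged = _em_run(g, two_minus_g, mask, Q0, F0, tol, max_iter)
        fit = AncestryFit(Q, F, trace, K, converged)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    if not best.converged:
        logger.warning("fit_admixture: best restart did not converge in %d iters",
                       max_iter)
    return best


def align_ancestry(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Greedy column permutation of ``Q`` best matching ``Q_ref``.

    Handles label switching when comparing an estimate with a reference
    (truth or another run); columns are matched by maximal correlation-free
    agreement (minimal mean absolute difference), greedily.
    """
    K = Q.shape[1]
    if Q_ref.shape[1] != K:
        raise ValueError("column counts differ")
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(Q[:, i] - Q_ref[:, j]).mean()
    perm = [-1] * K
    used = set()
    for _ in range(K):
        i, j = np.unravel_index(
            np.argmin(np.where(
                np.isinf(cost), np.inf, cost)), cost.shape)
        perm[j] = i
        cost[i, :] = np.inf
        cost[:, j] = np.inf
        used.add(i)
    return Q[:, perm]


def choose_K(
    G: GenotypeMatrix,
    K_range: list[int],
    n_replicates: int = 10,
    mask_fraction: float = 0.10,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Masked-entry cross-validation over candidate K.

    Each replicate hides a random ``mask_fraction`` of the non-missing
    genotype entries, refits every K on the masked matrix, and scores the
    hidden entries by mean binomial deviance under the fitted h_il
    (clipped away from {0, 1} so the deviance is always finite).  Returns a
    (replicate x K) table of mean deviances; lower is better.
    """
    if not K_range:
        raise ValueError("K_range must be non-empty")
    rng = np.random.default_rng(seed)
    dosage = G.dosage if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    observed = np.argwhere(np.isfinite(dosage))
    results = np.zeros((n_replicates, len(K_range)))
    for rep in range(n_replicates):
        hide = observed[
            rng.random(len(observed)) < mask_fraction
        ]
        masked = dosage.copy()
        masked[hide[:, 0], hide[:, 1]] = np.nan
        g_hidden = dosage[hide[:, 0], hide[:, 1]]
        for kk, K in enumerate(K_range):
            fit = fit_admixture(
                masked, K,
                seed=int(rng.integers(2**31 - 1)),
                **fit_kwargs,
            )
            h = np.clip(fit.Q @ fit.F, _EPS, 1 - _EPS)
            h_hidden = h[hide[:, 0], hide[:, 1]]
            dev = -2.0 * (
                g_hidden * np.log(h_hidden)
                + (2 - g_hidden) * np.log1p(-h_hidden)
            )
            results[rep, kk] = dev.mean()
    return pd.DataFrame(results, columns=[f"K={K}" for K in K_range])
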