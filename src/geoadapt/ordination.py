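"""Constrained ordination: RDA and partial RDA, variance partitioning,
permutation significance, and greedy environmental-variable selection.

Redundancy analysis regresses a centered multivariate response Y on
predictors X (after both are residualized on conditioning covariates Z, if
any) and takes the SVD of the fitted values; the canonical eigenvalues are
the squared singular values divided by n - 1, and the constrained /
conditioned / residual fractions decompose trace(Y'Y) exactly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RDAFit:
    eigenvalues: np.ndarray       # canonical eigenvalues, non-increasing
    site_scores: np.ndarray       # (n, n_axes) fitted ("lc") site scores
    loadings: np.ndarray          # (L, n_axes) response loadings
    env_scores: pd.DataFrame | None  # predictor-axis correlations (biplot scores)
    frac_constrained: float
    frac_conditioned: float
    frac_residual: float
    rank: int
    n_axes: int
    total_inertia: float

    def __post_init__(self) -> None:
        checks = self.frac_constrained + self.frac_conditioned + self.frac_residual
        if abs(checks - 1.0) > 1e-8:
            raise ValueError("variance fractions do not sum to 1")


@dataclasses.dataclass
class VariancePartition:
    full: float
    pure_climate: float
    pure_structure: float
    pure_geography: float
    confounded: float
    unexplained: float

    def as_series(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self))


def _as_2d(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after least squares on [1, Z]."""
    design = np.column_stack([np.ones(len(M)), Z])
    coef, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ coef


def fit_rda(
    Y,
    X,
    Z=None,
    n_axes: int = 3,
    x_names: list[str] | None = None,
) -> RDAFit:
    """(Partial) redundancy analysis of response Y on predictors X given Z.

    ``Z=None`` (or an empty matrix) gives plain RDA: conditioning on
    nothing is the identity operation.  Rank-deficient predictors are
    handled through the least-squares pseudo-inverse; the reported rank is
    that of the residualized predictor matrix.
    """
    Y = _as_2d(Y)
    X = _as_2d(X)
    n = Y.shape[0]
    if X.shape[0] != n or (Z is not None and _as_2d(Z).size and _as_2d(Z).shape[0] != n):
        raise ValueError("Y, X and Z must have aligned rows")

    Yc = Y - Y.mean(axis=0)
    total = float((Yc**2).sum())
    if total == 0:
        raise ValueError("response has zero variance")

    have_Z = Z is not None and _as_2d(Z).size > 0
    if have_Z:
        Zm = _as_2d(Z)
        Yres = _residualize(Yc, Zm)
        Xres = _residualize(X, Zm)
        rank_Z = np.linalg.matrix_rank(Zm - Zm.mean(axis=0))
    else:
        Yres = Yc
        Xres = X - X.mean(axis=0)
        rank_Z = 0

    rank_X = int(np.linalg.matrix_rank(Xres))
    if rank_X < Xres.shape[1]:
        logger.info("fit_rda: predictor matrix rank-deficient (rank %d of %d cols)",
                    rank_X, Xres.shape[1])
    if n <= rank_X + rank_Z + 1:
        raise ValueError(
            f"too few rows (n={n}) for rank(X)={rank_X} + rank(Z)={rank_Z} predictors"
        )

    B, *_ = np.linalg.lstsq(Xres, Yres, rcond=None)
    Yhat = Xres @ B
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if S.size and S[0] > 0 else 0
    n_axes_eff = min(n_axes, rank) if rank else 0

    eig = S**2 / (n - 1)
    constrained = float((S**2).sum())
    conditioned = total - float((Yres**2).sum())
    residual = total - conditioned - constrained

    site_scores = U[:, :n_axes_eff] * S[:n_axes_eff]
    loadings = Vt[:n_axes_eff].T

    env_scores = None
    if n_axes_eff:
        names = x_names if x_names is not None else [f"x{j + 1}" for j in range(X.shape[1])]
        corr = np.zeros((Xres.shape[1], n_axes_eff))
        for j in range(Xres.shape[1]):
            xc = Xres[:, j] - Xres[:, j].mean()
            sx = np.sqrt((xc**2).sum())
            for a in range(n_axes_eff):
                sc = site_scores[:, a] - site_scores[:, a].mean()
                ss = np.sqrt((sc**2).sum())
                corr[j, a] = float(xc @ sc) / (sx * ss) if sx > 0 and ss > 0 else 0.0
        env_scores = pd.DataFrame(
            corr, index=names, columns=[f"RDA{a + 1}" for a in range(n_axes_eff)]
        )

    return RDAFit(
        eigenvalues=eig[:rank],
        site_scores=site_scores,
        loadings=loadings,
        env_scores=env_scores,
        frac_constrained=constrained / total,
        frac_conditioned=conditioned / total,
        frac_residual=residual / total,
        rank=rank,
        n_axes=n_axes_eff,
        total_inertia=total,
    )


def permutation_test(
    Y,
    X,
    Z=None,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation ANOVA of the (p)RDA: returns (p-value, F-statistic).

    F = (constrained SS / rank(X)) / (residual SS / residual df); rows of
    the conditioned response residuals are permuted, so under conditioning
    the test is of X given Z.  p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    Y = _as_2d(Y)
    X = _as_2d(X)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    have_Z = Z is not None and _as_2d(Z).size > 0
    if have_Z:
        Zm = _as_2d(Z)
        Yres = _residualize(Yc, Zm)
        Xres = _residualize(X, Zm)
        rank_Z = int(np.linalg.matrix_rank(Zm - Zm.mean(axis=0)))
    else:
        Yres = Yc
        Xres = X - X.mean(axis=0)
        rank_Z = 0
    Qx, _ = np.linalg.qr(Xres)
    rank_X = int(np.linalg.matrix_rank(Xres))
    Qx = Qx[:, :rank_X]
    df_resid = n - 1 - rank_Z - rank_X
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def f_stat(Ymat: np.ndarray) -> float:
        fitted = (Qx.T @ Ymat)
        ss_fit = float((fitted**2).sum())
        ss_res = float((Ymat**2).sum()) - ss_fit
        if ss_res <= 0:
            return np.inf  # exact fit: maximal evidence
        return (ss_fit / rank_X) / (ss_res / df_resid)

    F_obs = f_stat(Yres)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(Yres[perm]) >= F_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return p, F_obs


def variance_partition(Y, climate, structure, geography) -> VariancePartition:
    """Partition response variance among three predictor blocks.

    Fits the full RDA (all blocks as predictors) and three pRDAs, each
    block conditioned on the other two; the confounded fraction is
    full minus the sum of pure fractions and may legitimately be negative
    (suppression), in which case it is reported, not clamped.
    """
    blocks = [_as_2d(climate), _as_2d(structure), _as_2d(geography)]
    full = fit_rda(Y, np.column_stack(blocks)).frac_constrained
    pure = []
    for i in range(3):
        others = np.column_stack([blocks[j] for j in range(3) if j != i])
        pure.append(fit_rda(Y, blocks[i], Z=others).frac_constrained)
    confounded = full - sum(pure)
    if confounded < 0:
        logger.info("variance_partition: negative confounded fraction %.4g "
                    "(suppression); reported as-is", confounded)
    return VariancePartition(
        full=full,
        pure_climate=pure[0],
        pure_structure=pure[1],
        pure_geography=pure[2],
        confounded=confounded,
        unexplained=1.0 - full,
    )


def select_env_vars(
    env_frame: pd.DataFrame,
    r_max: float = 0.7,
    vif_max: float = 10.0,
) -> tuple[list[str], list[str]]:
    """Greedy collinearity filter: pairwise |r| then variance inflation.

    While any pair correlates at |r| >= ``r_max``, the member of the worst
    pair with the larger mean |r| to all other variables is dropped; then
    the variable with the largest VIF is dropped until all VIF < ``vif_max``.
    Returns (retained variables, elimination log).
    """
    if env_frame.shape[1] < 2:
        raise ValueError("need at least two candidate variables")
    cols = list(env_frame.columns)
    log: list[str] = []

    def corr_step(cols: list[str]) -> str | None:
        if len(cols) < 2:
            return None
        R = env_frame[cols].corr().abs()
        np.fill_diagonal(R.values, 0.0)
        if R.values.max() < r_max:
            return None
        i, j = np.unravel_index(np.argmax(R.values), R.shape)
        a, b = cols[i], cols[j]
        mean_r = R.mean()
        drop = a if mean_r[a] >= mean_r[b] else b
        log.append(f"corr: dropped {drop} (|r|={R.values[i, j]:.3f} with "
                   f"{b if drop == a else a})")
        return drop

    while (drop := corr_step(cols)) is not None:
        cols.remove(drop)
        if not cols:
            raise ValueError("all variables eliminated by correlation filter")

    def vifs(cols: list[str]) -> pd.Series:
        X = env_frame[cols].to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        out = {}
        for j, c in enumerate(cols):
            others = np.delete(X, j, axis=1)
            if others.shape[1] == 0:
                out[c] = 1.0
                continue
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(X)), others]), X[:, j], rcond=None)
            resid = X[:, j] - np.column_stack([np.ones(len(X)), others]) @ coef
            r2 = 1 - (resid**2).sum() / (X[:, j] ** 2).sum()
            out[c] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    while len(cols) >= 2:
        v = vifs(cols)
        if (v < vif_max).all():
            break
        drop = v.idxmax()
        log.append(f"vif: dropped {drop} (VIF={v[drop]:.2f})")
        cols.remove(drop)
    if not cols:
        raise ValueError("all variables eliminated")
    return cols, log
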