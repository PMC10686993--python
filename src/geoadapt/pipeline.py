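"""End-to-end orchestration: simulate/ingest -> filter -> structure ->
pRDA + scans -> intersection -> enriched RDA -> offsets, with every
intermediate persisted and a manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genio import (
    EnvTable,
    PopMap,
    RasterGrid,
    allele_freq_by_pop,
    filter_snps,
    read_env_table,
    read_popmap,
    read_raster,
    read_vcf,
    write_ascii_grid,
)
from .gea_outliers import (
    CandidateSet,
    intersect_candidates,
    pcadapt_scan,
    per_snp_fst,
    rdadapt_scan,
)
from .offsets import (
    adaptive_index,
    fit_enriched_rda,
    genomic_offset,
    geographic_offset,
    pai,
    sgv,
    site_adaptive_index,
)
from .ordination import fit_rda, permutation_test, select_env_vars, variance_partition
from .popstruct import fit_admixture, pairwise_fst, run_pca
from .synthdata import SimBundle, SimulationConfig, simulate, write_fixture_bundle

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All thresholds and knobs of one pipeline run.

    Defaults follow the standard protocol: MAF > 5%, missingness < 10%,
    per-population HWE at 0.001, outlier FDR 0.1 with the stricter 0.05
    cutoff defining the adaptively enriched set, F_ST percentile 95, and
    three retained ordination axes.
    """

    # data source: either a SimulationConfig or paths to on-disk inputs
    sim: SimulationConfig | None = None
    vcf: str | None = None
    popmap: str | None = None
    env_current: str | None = None
    env_future: str | None = None
    rasters_current: dict[str, str] | None = None
    rasters_future: dict[str, str] | None = None

    maf_min: float = 0.05
    miss_max: float = 0.10
    hwe_alpha: float = 0.001
    fdr: float = 0.1
    enriched_fdr: float = 0.05
    fst_pct: float = 95.0
    K: int = 2
    pcadapt_K: int | None = None  # default: same as K
    n_axes: int = 3
    n_perm: int = 199
    admixture_restarts: int = 3
    admixture_tol: float = 1e-4
    admixture_max_iter: int = 500
    offset_agg: str = "l1"
    geo_tolerance: float | None = None
    run_offsets: bool = True
    select_vars: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (("maf_min", 0, 0.5), ("miss_max", 0, 1),
                             ("hwe_alpha", 0, 1), ("fdr", 0, 1),
                             ("enriched_fdr", 0, 1), ("fst_pct", 0, 100)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.sim is None:
            if not (self.vcf and self.popmap and self.env_current):
                raise ValueError(
                    "either a simulation config or vcf+popmap+env_current paths "
                    "are required")
            if self.run_offsets and not (self.rasters_current and self.rasters_future):
                raise ValueError(
                    "offsets requested but current/future rasters are missing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclasses.dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    candidates: CandidateSet
    pop_summary: pd.DataFrame
    partition: pd.Series
    offsets: dict | None


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        bundle: SimBundle = simulate(config.sim)
        return (bundle.genotypes, bundle.popmap, bundle.climate.env_current,
                bundle.climate.env_future, bundle.climate.grid_current,
                bundle.climate.grid_future, bundle)
    G = read_vcf(config.vcf)
    popmap = read_popmap(config.popmap)
    env_cur = read_env_table(config.env_current)
    env_fut = read_env_table(config.env_future) if config.env_future else None
    grid_cur = (read_raster(config.rasters_current, "current")
                if config.rasters_current else None)
    grid_fut = (read_raster(config.rasters_future, "future")
                if config.rasters_future else None)
    return G, popmap, env_cur, env_fut, grid_cur, grid_fut, None


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every stage in order, writing intermediates and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    t_start = time.time()

    def stage(name: str, **info):
        stages.append({"stage": name, "elapsed_s": round(time.time() - t_start, 2),
                       **info})
        logger.info("stage %s: %s", name, info)

    try:
        G, popmap, env_cur, env_fut, grid_cur, grid_fut, bundle = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc
    stage("ingest", n_samples=G.n, n_snps=G.L)
    if bundle is not None:
        write_fixture_bundle(bundle, outdir / "fixture")

    # ---- filtering ----
    G, filter_report = filter_snps(G, popmap, config.maf_min, config.miss_max,
                                   config.hwe_alpha)
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(filter_report, fh, indent=2)
    stage("filter", **{k: v for k, v in filter_report.items()
                       if isinstance(v, int)})

    # ---- variable selection ----
    if config.select_vars and env_cur.frame.shape[1] >= 2:
        retained, sel_log = select_env_vars(env_cur.frame)
    else:
        retained, sel_log = list(env_cur.frame.columns), []
    env_cur = EnvTable(env_cur.frame[retained])
    if env_fut is not None:
        env_fut = EnvTable(env_fut.frame[retained])
    stage("select_vars", retained=retained, eliminated=len(sel_log))

    # ---- population structure ----
    pca = run_pca(G, k=min(10, G.n - 1, G.L - 1))
    fst_matrix = pairwise_fst(G, popmap)
    fst_matrix.to_csv(outdir / "pairwise_fst.csv")
    adm = fit_admixture(G, config.K, tol=config.admixture_tol,
                        max_iter=config.admixture_max_iter,
                        n_restarts=config.admixture_restarts, seed=config.seed)
    pd.DataFrame(adm.Q, index=G.samples,
                 columns=[f"Q{k + 1}" for k in range(config.K)]).to_csv(
        outdir / "ancestry_Q.tsv", sep="\t")
    stage("structure", K=config.K, loglik=round(adm.loglik, 2),
          converged=adm.converged)

    # ---- design matrices (site covariates broadcast to individuals) ----
    pop_of_sample = [popmap.frame.set_index("sample").loc[s, "pop"]
                     for s in G.samples]
    env_std = env_cur.standardize()
    X_env = env_std.loc[pop_of_sample].to_numpy(dtype=float)
    coords = popmap.frame.set_index("sample").loc[G.samples, ["lat", "lon"]]
    X_geo = coords.to_numpy(dtype=float)
    X_anc = adm.Q[:, :-1] if config.K > 1 else np.empty((G.n, 0))

    Y = G.dosage.copy()
    col_mean = np.nanmean(Y, axis=0)
    inds = np.where(np.isnan(Y))
    Y[inds] = np.take(col_mean, inds[1])

    # ---- variance partitioning + pRDA significance ----
    if X_anc.shape[1] > 0:
        part = variance_partition(Y, X_env, X_anc, X_geo).as_series()
        Z_cond = X_anc
    else:
        full = fit_rda(Y, np.column_stack([X_env, X_geo]))
        part = pd.Series({"full": full.frac_constrained,
                          "unexplained": full.frac_residual})
        Z_cond = None
    part.to_csv(outdir / "variance_partition.csv", header=["fraction"])
    p_rda_model, f_rda_model = permutation_test(
        Y, X_env, Z=Z_cond, n_perm=config.n_perm, seed=config.seed)
    stage("variance_partition", full=round(float(part.get("full", np.nan)), 4),
          model_p=p_rda_model)

    # ---- outlier scans ----
    # the scan ordination standardizes loci (Patterson scaling) so loadings
    # are comparable across allele frequencies; variance partitioning above
    # stays on centered raw dosages
    from .popstruct import patterson_scale

    Y_scaled, kept_scan = patterson_scale(G.dosage)
    if not kept_scan.all():
        G = G.subset_loci(kept_scan)
        Y = Y[:, kept_scan]
    prda = fit_rda(Y_scaled, X_env, Z=Z_cond, n_axes=config.n_axes,
                   x_names=list(env_std.columns))
    fst_vec = per_snp_fst(G, popmap)
    pc_scan = pcadapt_scan(G, K=config.pcadapt_K or config.K)
    rda_scan = rdadapt_scan(prda, n_axes=min(config.n_axes, prda.n_axes))
    candidates = intersect_candidates(
        G.loci["id"], fst_vec, pc_scan, rda_scan,
        fdr=config.fdr, enriched_fdr=config.enriched_fdr,
        fst_pct=config.fst_pct)
    candidates.table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    stage("scan", **candidates.counts(),
          lambda_pc=round(pc_scan.inflation, 3),
          lambda_rda=round(rda_scan.inflation, 3))

    # ---- population summaries on the three-way candidate set ----
    P = allele_freq_by_pop(G, popmap)
    cand_ids = candidates.table.loc[candidates.three_way, "locus_id"].to_numpy()
    neutral_pool = candidates.table.loc[
        ~(candidates.table[["flag_fst", "flag_pc", "flag_rda"]].any(axis=1)),
        "locus_id"].to_numpy()
    rng = np.random.default_rng(config.seed)
    summary_loci = cand_ids if len(cand_ids) else np.asarray(G.loci["id"])
    pop_summary = pd.DataFrame({
        "sgv": sgv(P, summary_loci),
        "pai": pai(P, summary_loci),
    })
    if len(neutral_pool) >= len(summary_loci):
        neutral_sample = rng.choice(neutral_pool, size=len(summary_loci),
                                    replace=False)
        pop_summary["sgv_neutral"] = sgv(P, neutral_sample)
    pop_summary.to_csv(outdir / "population_summary.csv")
    stage("pop_summary", candidates_used=int(len(summary_loci)))

    # ---- enriched ordination and offsets ----
    offsets_out: dict | None = None
    enriched_ids = candidates.table.loc[candidates.enriched, "locus_id"]
    if (config.run_offsets and grid_cur is not None and grid_fut is not None
            and len(enriched_ids) >= config.n_axes):
        keep = G.loci["id"].isin(enriched_ids).to_numpy()
        G_enr = G.subset_loci(keep)
        env_for_fit = EnvTable(env_cur.frame.copy())
        space, enr_fit = fit_enriched_rda(
            G_enr, env_for_fit, sample_sites=pop_of_sample,
            n_axes=min(config.n_axes, len(enriched_ids)))
        ai_cur = adaptive_index(space, grid_cur)
        ai_fut = adaptive_index(space, grid_fut)
        go = genomic_offset(ai_cur, ai_fut, agg=config.offset_agg)
        geo = geographic_offset(ai_cur, ai_fut, grid_cur,
                                tolerance=config.geo_tolerance)
        site_ai = site_adaptive_index(space, env_cur.frame)
        for a in range(space.n_axes):
            write_ascii_grid(ai_cur[a], outdir / f"ai_current_axis{a + 1}.asc",
                             grid_cur.xllcorner, grid_cur.yllcorner,
                             grid_cur.cellsize)
        write_ascii_grid(go, outdir / "genomic_offset.asc",
                         grid_cur.xllcorner, grid_cur.yllcorner,
                         grid_cur.cellsize)
        write_ascii_grid(geo.offset_km, outdir / "geographic_offset_km.asc",
                         grid_cur.xllcorner, grid_cur.yllcorner,
                         grid_cur.cellsize)
        offsets_out = {
            "space": space,
            "ai_current": ai_cur,
            "ai_future": ai_fut,
            "genomic_offset": go,
            "geographic_offset": geo,
            "site_ai": site_ai,
            "enriched_fit": enr_fit,
        }
        stage("offsets", n_enriched=int(len(enriched_ids)),
              axes=space.n_axes,
              median_genomic_offset=float(np.nanmedian(go)))
    elif config.run_offsets:
        stage("offsets", skipped=True,
              reason="no grids or too few enriched SNPs")

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": stages,
        "retained_variables": retained,
        "model_p_value": p_rda_model,
        "model_F": f_rda_model,
        "candidate_counts": candidates.counts(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(outdir, manifest, candidates, pop_summary, part,
                          offsets_out)


def report(outdir: str | Path) -> str:
    """Human-readable summary assembled from persisted intermediates."""
    outdir = Path(outdir)
    lines = ["geoadapt pipeline report", "=" * 32]
    warnings = []

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"config digest: {manifest['config_digest']}  "
                     f"seed: {manifest['seed']}")
        counts = manifest.get("candidate_counts", {})
        lines.append("candidates per method: "
                     + ", ".join(f"{k}={v}" for k, v in counts.items()))
        if counts.get("three_way", 0) == 0:
            lines.append("note: three-way candidate set is empty")
        if counts.get("enriched", 0) == 0:
            lines.append("note: enriched set empty; offset stage skipped")
    else:
        warnings.append("manifest.json missing (incomplete run)")

    vp = outdir / "variance_partition.csv"
    if vp.exists():
        part = pd.read_csv(vp, index_col=0)["fraction"]
        lines.append("variance partition:")
        for k, v in part.items():
            lines.append(f"  {k:>14s}: {v:.4f}")
    else:
        warnings.append("variance partition missing")

    ps = outdir / "population_summary.csv"
    if ps.exists():
        lines.append("per-population SGV / PAI:")
        lines.append(pd.read_csv(ps, index_col=0).round(4).to_string())
    else:
        warnings.append("population summary missing")

    go = outdir / "genomic_offset.asc"
    if go.exists():
        from .genio import read_ascii_grid
        arr, _ = read_ascii_grid(go)
        vals = arr[arr != -9999.0]
        qs = np.percentile(vals, [5, 50, 95])
        lines.append(f"genomic offset percentiles (5/50/95): "
                     f"{qs[0]:.3f} / {qs[1]:.3f} / {qs[2]:.3f}")
    for w in warnings:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines)
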