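"""Readers/writers for the formats the pipeline touches, SNP filtering, and
per-population allele frequencies.

The in-memory genotype container is a dense dosage matrix (samples x loci,
values 0/1/2 with NaN for missing) rather than a compressed call set: every
downstream analysis (PCA, RDA, admixture EM) consumes the dense matrix
directly, and the target scale (hundreds of samples, tens of thousands of
biallelic SNPs) fits comfortably in memory.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

NODATA_DEFAULT = -9999.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GenotypeMatrix:
    """Biallelic diploid dosages for ``n`` samples at ``L`` loci.

    ``dosage`` holds the count of the ALT allele per genotype call
    (0/0 -> 0, 0/1 -> 1, 1/1 -> 2) as float64 with NaN marking missing
    calls.  ``loci`` is a DataFrame with columns
    ``chrom, pos, id, ref, alt`` aligned to the dosage columns.
    """

    samples: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.loci["id"].duplicated().any():
            raise ValueError("duplicate locus ids")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def L(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples,
            self.loci.loc[np.asarray(mask)].reset_index(drop=True)
            if mask.dtype == bool
            else self.loci.iloc[mask].reset_index(drop=True),
            self.dosage[:, mask],
        )

    def missing_rate(self) -> float:
        return float(np.isnan(self.dosage).mean())


@dataclasses.dataclass
class PopMap:
    """sample -> (population, latitude, longitude) assignment."""

    frame: pd.DataFrame  # columns: sample, pop, lat, lon

    def __post_init__(self) -> None:
        required = {"sample", "pop", "lat", "lon"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"popmap needs columns {sorted(required)}")
        if self.frame["sample"].duplicated().any():
            raise ValueError("duplicate samples in popmap")

    @property
    def pops(self) -> list[str]:
        # preserve first-appearance order (site order along the transect)
        return list(dict.fromkeys(self.frame["pop"]))

    def indices(self, samples: list[str]) -> dict[str, np.ndarray]:
        """Row indices into ``samples`` per population, requiring coverage."""
        lookup = {s: i for i, s in enumerate(samples)}
        missing = [s for s in samples if s not in set(self.frame["sample"])]
        if missing:
            raise ValueError(f"{len(missing)} genotype samples absent from popmap")
        out: dict[str, np.ndarray] = {}
        for pop in self.pops:
            members = self.frame.loc[self.frame["pop"] == pop, "sample"]
            idx = np.array([lookup[s] for s in members if s in lookup], dtype=int)
            if idx.size == 0:
                raise ValueError(f"population {pop!r} has no genotyped samples")
            out[pop] = idx
        return out

    def site_coords(self) -> pd.DataFrame:
        """One (lat, lon) row per population (first sample's coordinates)."""
        return (
            self.frame.groupby("pop", sort=False)[["lat", "lon"]].first().loc[self.pops]
        )


@dataclasses.dataclass
class EnvTable:
    """Per-site environmental variables with fit-time standardization.

    ``standardize()`` records the mean/SD of each variable and returns the
    z-scored table; the stored parameters are what pixel projection uses
    later so that grids are scored on the same scale as the fitted sites.
    """

    frame: pd.DataFrame  # index: site/pop id, columns: variables
    means: pd.Series | None = None
    sds: pd.Series | None = None

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    def standardize(self) -> pd.DataFrame:
        self.means = self.frame.mean()
        self.sds = self.frame.std(ddof=1)
        if (self.sds <= 0).any():
            bad = list(self.sds.index[self.sds <= 0])
            raise ValueError(f"zero-variance environmental variables: {bad}")
        return (self.frame - self.means) / self.sds

    def zscore(self, values: pd.DataFrame) -> pd.DataFrame:
        """Apply the fit-time standardization to new values (e.g. a future table)."""
        if self.means is None:
            raise ValueError("standardize() must be called before zscore()")
        return (values[self.means.index] - self.means) / self.sds


@dataclasses.dataclass
class RasterGrid:
    """A stack of gridded variables sharing one georeference.

    Plain-text Esri ASCII grid conventions: row 0 is the northern edge,
    ``(xllcorner, yllcorner)`` is the lower-left corner of the lower-left
    cell, and coordinates refer to cell centers.
    """

    data: dict[str, np.ndarray]
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = NODATA_DEFAULT
    epoch: str = "current"

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) > 1:
            raise ValueError(f"variables have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.data.values())).shape

    @property
    def variables(self) -> list[str]:
        return list(self.data)

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.shape, dtype=bool)
        for arr in self.data.values():
            mask &= arr != self.nodata
            mask &= np.isfinite(arr)
        return mask

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of a cell center; row 0 is the northern row."""
        nrows = self.shape[0]
        lat = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        return lat, lon

    def latlon_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.shape
        rows = np.arange(nrows)
        cols = np.arange(ncols)
        lat = self.yllcorner + (nrows - rows - 0.5) * self.cellsize
        lon = self.xllcorner + (cols + 0.5) * self.cellsize
        return lat, lon


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (minimal, GT-only) VCF into a dosage matrix.

    Multiallelic records are skipped with a logged count; genotypes are
    mapped 0/0 -> 0, 0/1 or 1/0 -> 1 (phase ignored), 1/1 -> 2, ./. -> NaN.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reader = VCF(str(path), gts012=True)
    samples = list(reader.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    skipped_multiallelic = 0
    try:
        for var in reader:
            if len(var.ALT) != 1:
                skipped_multiallelic += 1
                continue
            gt = var.gt_types.astype(float)  # 0,1,2 dosage; 3 = unknown
            gt[gt == 3] = np.nan
            rows.append(gt)
            meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                         var.REF, var.ALT[0]))
    except Exception as exc:  # cyvcf2 raises on malformed records
        raise ValueError(f"malformed VCF record near record {len(rows) + 1}: {exc}")
    if skipped_multiallelic:
        logger.info("read_vcf: skipped %d multiallelic records", skipped_multiallelic)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    loci = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    G = GenotypeMatrix(samples, loci, np.column_stack(rows) if len(samples) else np.empty((0, 0)))
    G.skipped_multiallelic = skipped_multiallelic  # type: ignore[attr-defined]
    return G


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an unphased GT-only VCF v4.2."""
    path = Path(path)
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=geoadapt\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(G.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for l, locus in enumerate(G.loci.itertuples(index=False)):
            calls = "\t".join(
                gt_strings.get(d, "./.") if np.isfinite(d) else "./."
                for d in G.dosage[:, l]
            )
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t{locus.id}\t{locus.ref}\t"
                f"{locus.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_popmap(path: str | Path) -> PopMap:
    frame = pd.read_csv(path, sep="\t")
    return PopMap(frame)


def write_popmap(popmap: PopMap, path: str | Path) -> None:
    popmap.frame.to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path) -> EnvTable:
    return EnvTable(pd.read_csv(path, index_col=0))


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.frame.to_csv(path)


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------


def global_allele_freq(dosage: np.ndarray) -> np.ndarray:
    """ALT allele frequency per locus, missing calls excluded."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosage, axis=0) / 2.0


def hwe_chi2_pvalues(dosage: np.ndarray, min_n: int = 5) -> np.ndarray:
    """One-df chi-square Hardy-Weinberg test per locus on one population.

    Returns NaN where the test is not applicable (fewer than ``min_n``
    genotyped individuals or a monomorphic locus).
    """
    valid = np.isfinite(dosage)
    n = valid.sum(axis=0).astype(float)
    obs_hom_ref = ((dosage == 0) & valid).sum(axis=0).astype(float)
    obs_het = ((dosage == 1) & valid).sum(axis=0).astype(float)
    obs_hom_alt = ((dosage == 2) & valid).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (obs_het + 2 * obs_hom_alt) / (2 * n)
        e0 = n * (1 - p) ** 2
        e1 = n * 2 * p * (1 - p)
        e2 = n * p**2
        x2 = (obs_hom_ref - e0) ** 2 / e0 + (obs_het - e1) ** 2 / e1 + (
            obs_hom_alt - e2
        ) ** 2 / e2
        pvals = chi2.sf(x2, df=1)
    testable = (n >= min_n) & (p > 0) & (p < 1)
    pvals = np.where(testable, pvals, np.nan)
    return pvals


def filter_snps(
    G: GenotypeMatrix,
    popmap: PopMap,
    maf_min: float = 0.05,
    miss_max: float = 0.10,
    hwe_alpha: float = 0.001,
    hwe_mode: str = "drop",
) -> tuple[GenotypeMatrix, dict]:
    """Apply MAF, missingness and per-population HWE filters.

    A SNP is kept when its global minor allele frequency exceeds
    ``maf_min`` and its missing fraction is below ``miss_max``.  HWE is
    tested within each population; with ``hwe_mode='drop'`` (default) a SNP
    out of HWE (p < ``hwe_alpha``) in any population is removed genome-wide,
    which preserves a rectangular matrix for ordination.  With
    ``hwe_mode='mask'`` only the offending population's genotypes are set
    missing.  Each removed SNP is attributed to the first criterion it
    fails, so report counts sum to input minus output.
    """
    if hwe_mode not in ("drop", "mask"):
        raise ValueError("hwe_mode must be 'drop' or 'mask'")
    idx = popmap.indices(G.samples)
    freq = global_allele_freq(G.dosage)
    maf = np.minimum(freq, 1 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    miss = np.isnan(G.dosage).mean(axis=0)

    fail_maf = ~(maf > maf_min)
    fail_miss = ~(miss < miss_max)

    hwe_fail = np.zeros((len(idx), G.L), dtype=bool)
    for j, (pop, rows) in enumerate(idx.items()):
        p = hwe_chi2_pvalues(G.dosage[rows])
        hwe_fail[j] = np.isfinite(p) & (p < hwe_alpha)
    fail_hwe_any = hwe_fail.any(axis=0)

    dosage = G.dosage
    n_masked = 0
    if hwe_mode == "drop":
        keep = ~(fail_maf | fail_miss | fail_hwe_any)
        removed_hwe = int((fail_hwe_any & ~fail_maf & ~fail_miss).sum())
    else:
        dosage = dosage.copy()
        for j, rows in enumerate(idx.values()):
            bad = hwe_fail[j]
            if bad.any():
                dosage[np.ix_(rows, bad)] = np.nan
                n_masked += int(rows.size * bad.sum())
        keep = ~(fail_maf | fail_miss)
        removed_hwe = 0

    report = {
        "input_snps": G.L,
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int((fail_miss & ~fail_maf).sum()),
        "removed_hwe": removed_hwe,
        "masked_genotypes_hwe": n_masked,
        "output_snps": int(keep.sum()),
        "maf_min": maf_min,
        "miss_max": miss_max,
        "hwe_alpha": hwe_alpha,
        "hwe_mode": hwe_mode,
    }
    if not keep.any():
        raise ValueError(
            "all SNPs removed by filtering; relax maf_min/miss_max/hwe_alpha"
        )
    out = GenotypeMatrix(G.samples, G.loci.loc[keep].reset_index(drop=True),
                         dosage[:, keep])
    return out, report


def allele_freq_by_pop(G: GenotypeMatrix, popmap: PopMap) -> pd.DataFrame:
    """ALT allele frequency per population (rows) and locus (columns).

    Missing genotypes are excluded from the denominator; a locus with no
    genotyped individuals in a population yields NaN there and should be
    excluded from downstream per-population summaries.
    """
    idx = popmap.indices(G.samples)
    out = np.full((len(idx), G.L), np.nan)
    for j, rows in enumerate(idx.values()):
        sub = G.dosage[rows]
        counts = np.isfinite(sub).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[j] = np.nansum(sub, axis=0) / (2.0 * counts)
        out[j, counts == 0] = np.nan
    return pd.DataFrame(out, index=list(idx), columns=G.loci["id"])


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.5) -> GenotypeMatrix:
    """Greedy r^2 pruning: scan loci in order, drop any locus whose squared
    correlation with an already-kept locus exceeds ``r2_max``.

    Synthetic loci are unlinked, so this is an optional pass; it makes no
    attempt to reproduce plink's positional window dialect.
    """
    X = G.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    keep: list[int] = []
    for l in range(G.L):
        if norms[l] == 0:
            continue
        ok = True
        for k in keep:
            r = float(X[:, l] @ X[:, k]) / (norms[l] * norms[k])
            if r * r > r2_max:
                ok = False
                break
        if ok:
            keep.append(l)
    return G.subset_loci(np.array(keep, dtype=int))


# ---------------------------------------------------------------------------
# Esri ASCII rasters
# ---------------------------------------------------------------------------


def write_ascii_grid(
    array: np.ndarray,
    path: str | Path,
    xllcorner: float,
    yllcorner: float,
    cellsize: float,
    nodata: float = NODATA_DEFAULT,
) -> None:
    array = np.asarray(array, dtype=float)
    out = np.where(np.isfinite(array), array, nodata)
    nrows, ncols = array.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(xllcorner)!r}\n")
        fh.write(f"yllcorner {float(yllcorner)!r}\n")
        fh.write(f"cellsize {float(cellsize)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, value = line.split()
        header[key.lower()] = float(value)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    array = np.loadtxt(lines[6:])
    array = np.atleast_2d(array)
    if array.shape != (nrows, ncols):
        raise ValueError(f"{path}: grid shape {array.shape} != header ({nrows},{ncols})")
    return array, header


def write_raster(grid: RasterGrid, directory: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write one ``<prefix><epoch>_<var>.asc`` file per variable."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for var, arr in grid.data.items():
        path = directory / f"{prefix}{grid.epoch}_{var}.asc"
        write_ascii_grid(arr, path, grid.xllcorner, grid.yllcorner,
                         grid.cellsize, grid.nodata)
        paths[var] = path
    return paths


def read_raster(paths: dict[str, str | Path], epoch: str = "current") -> RasterGrid:
    """Assemble a RasterGrid from per-variable ASCII grid files.

    All files must agree on shape and georeference.
    """
    data: dict[str, np.ndarray] = {}
    ref: dict | None = None
    for var, path in paths.items():
        arr, header = read_ascii_grid(path)
        if ref is None:
            ref = header
        else:
            for key in ("xllcorner", "yllcorner", "cellsize", "ncols", "nrows"):
                if not np.isclose(header[key], ref[key]):
                    raise ValueError(f"{path}: {key} mismatch across raster variables")
        nodata = header.get("nodata_value", NODATA_DEFAULT)
        arr = np.where(arr == nodata, np.nan, arr)
        data[var] = arr
    assert ref is not None
    return RasterGrid(
        data,
        xllcorner=ref["xllcorner"],
        yllcorner=ref["yllcorner"],
        cellsize=ref["cellsize"],
        nodata=NODATA_DEFAULT,
        epoch=epoch,
    )
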