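"""Shared fixtures: seeded synthetic bundles and the scan chain helper."""

from __future__ import annotations

import numpy as np
import pytest

from geoadapt.genio import filter_snps
from geoadapt.gea_outliers import (
    intersect_candidates,
    pcadapt_scan,
    per_snp_fst,
    rdadapt_scan,
)
from geoadapt.ordination import fit_rda
from geoadapt.popstruct import patterson_scale
from geoadapt.synthdata import SimulationConfig, simulate

DEFAULT_SEED = 1
NULL_SEED = 101


@pytest.fixture(scope="session")
def default_bundle():
    """Default adaptive fixture: 12 pops x 10, L=2000, 100 adaptive, beta=1.5."""
    return simulate(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def null_bundle():
    """Same design with beta=0: adaptive loci are statistically neutral."""
    return simulate(SimulationConfig(beta=0.0, seed=NULL_SEED))


@pytest.fixture(scope="session")
def k3_bundle():
    """Strong three-source block structure for K selection tests."""
    return simulate(SimulationConfig(
        n_pops=6, n_per_pop=10, L=300, L_adaptive=0, K_anc=3,
        fst_drift=0.35, beta=0.0, cline_steepness=12.0, seed=77))


def scan_chain(bundle, K: int = 2, fdr: float = 0.1, enriched_fdr: float = 0.05):
    """Filter -> pRDA (conditioned on known ancestry) -> three scans -> intersection.

    Uses the bundle's true ancestry for conditioning so the chain is cheap
    and deterministic; the full pipeline estimates ancestry instead.
    """
    G, report = filter_snps(bundle.genotypes, bundle.popmap)
    z = bundle.climate.env_current.standardize()
    pop_of = [s.split("_")[0] for s in G.samples]
    X = z.loc[pop_of].to_numpy(dtype=float)
    Z = bundle.q_true[:, :-1] if bundle.q_true.shape[1] > 1 else None
    Y, kept = patterson_scale(G.dosage)
    G = G.subset_loci(kept)
    prda = fit_rda(Y, X, Z=Z, n_axes=3)
    fst = per_snp_fst(G, bundle.popmap)
    pc = pcadapt_scan(G, K=K)
    rd = rdadapt_scan(prda, n_axes=3)
    candidates = intersect_candidates(
        G.loci["id"], fst, pc, rd, fdr=fdr, enriched_fdr=enriched_fdr)
    truth = bundle.truth.set_index("locus_id")["is_adaptive"]
    is_true = truth.loc[candidates.table["locus_id"]].to_numpy()
    return {
        "G": G,
        "popmap": bundle.popmap,
        "prda": prda,
        "fst": fst,
        "pc": pc,
        "rd": rd,
        "candidates": candidates,
        "is_true": is_true,
        "filter_report": report,
    }


@pytest.fixture(scope="session")
def default_chain(default_bundle):
    return scan_chain(default_bundle)


@pytest.fixture(scope="session")
def null_chain(null_bundle):
    return scan_chain(null_bundle)


def precision_tpr(flags: np.ndarray, is_true: np.ndarray) -> tuple[float, float]:
    flags = np.asarray(flags, dtype=bool)
    n_true = int(is_true.sum())
    tp = int((flags & is_true).sum())
    precision = tp / flags.sum() if flags.sum() else np.nan
    tpr = tp / n_true if n_true else np.nan
    return precision, tpr
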