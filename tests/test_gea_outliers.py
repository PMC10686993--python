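"""Outlier scans, q-values, scree-based K choice, and the intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from geoadapt.gea_outliers import (
    choose_K_scree,
    fst_outliers,
    intersect_candidates,
    pcadapt_scan,
    per_snp_fst,
    qvalues,
    rdadapt_scan,
)
from geoadapt.ordination import RDAFit

from test_genio import toy_matrix, toy_popmap
from test_popstruct import brute_force_wc_two_pops


class TestPerSnpFst:
    def test_matches_brute_force_multipop(self):
        """Three populations at printed frequencies vs a scalar re-derivation."""
        # pops at p = 0.1, 0.5, 0.9; n = 20 each; explicit genotype counts
        counts = [(16, 4, 0), (5, 10, 5), (0, 4, 16)]
        dosage = np.concatenate([
            np.array([0.0] * c[0] + [1.0] * c[1] + [2.0] * c[2])
            for c in counts])[:, None]
        G = toy_matrix(dosage)
        popmap = toy_popmap(G.samples, ["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        theta = per_snp_fst(G, popmap)[0]

        # independent scalar computation generalizing the two-pop oracle
        r = 3
        ns = [20.0] * 3
        ps = [(c[1] + 2 * c[2]) / 40 for c in counts]
        hs = [c[1] / 20 for c in counts]
        nbar = 20.0
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        np.testing.assert_allclose(theta, a / (a + b + c), atol=1e-10)

    def test_monomorphic_locus_undefined(self):
        G = toy_matrix(np.column_stack([np.zeros(20), np.ones(20)]))
        popmap = toy_popmap(G.samples, ["a"] * 10 + ["b"] * 10)
        theta = per_snp_fst(G, popmap)
        assert np.isnan(theta[0]) and np.isfinite(theta[1])

    def test_fixed_difference_top_ranked(self):
        rng = np.random.default_rng(0)
        neutral = rng.binomial(2, 0.5, size=(40, 50)).astype(float)
        fixed = np.concatenate([np.zeros(20), np.full(20, 2.0)])
        G = toy_matrix(np.column_stack([neutral, fixed]))
        popmap = toy_popmap(G.samples, ["a"] * 20 + ["b"] * 20)
        theta = per_snp_fst(G, popmap)
        assert np.nanargmax(theta) == 50


class TestFstOutliers:
    def test_percentile_arithmetic(self):
        rng = np.random.default_rng(1)
        values = rng.permutation(np.linspace(0.0, 0.5, 1000))
        flags = fst_outliers(values, pct=95)
        assert flags.sum() == 50
        assert values[flags].min() > np.percentile(values, 95)

    def test_nan_excluded(self):
        values = np.array([0.1, 0.2, np.nan, 0.4])
        flags = fst_outliers(values, pct=50)
        assert not flags[2]


class TestScree:
    def test_worked_example(self):
        K, warned = choose_K_scree(np.array([5, 3, 1, 0.1, 0.09, 0.08]))
        assert K == 3 and not warned

    def test_two_cluster_spectrum_gives_one(self):
        K, _ = choose_K_scree(np.array([10.0, 0.5, 0.45, 0.42, 0.41, 0.40]))
        assert K == 1

    def test_geometric_decay_warns(self):
        eig = 10 * 0.9 ** np.arange(20)
        K, warned = choose_K_scree(eig)
        assert warned

    def test_flat_spectrum_defaults_to_one_with_warning(self):
        K, warned = choose_K_scree(np.ones(6))
        assert K == 1 and warned


class TestQvalues:
    def test_bh_step_up_hand_example(self):
        # q_i = min_{j >= i} p_(j) * m / j: (.04, .04, .04, .04)
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        np.testing.assert_allclose(q, 0.04)

    def test_all_ones(self):
        np.testing.assert_array_equal(qvalues(np.ones(5)), np.ones(5))

    def test_storey_never_exceeds_bh_when_pi0_below_one(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(0, 0.05, 50), rng.uniform(0, 1, 950)])
        q_st = qvalues(p, method="storey")
        q_bh = qvalues(p, method="bh")
        assert (p > 0.5).mean() / 0.5 < 1  # pi0-hat < 1 on this vector
        assert np.all(q_st <= q_bh + 1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=200))
    def test_monotone_in_sorted_p(self, plist):
        p = np.array(plist)
        q = qvalues(p, method="bh")
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([]))


def make_fake_rda_fit(loadings):
    loadings = np.asarray(loadings, dtype=float)
    k = loadings.shape[1]
    return RDAFit(
        eigenvalues=np.linspace(1.0, 0.5, k),
        site_scores=np.zeros((4, k)),
        loadings=loadings,
        env_scores=None,
        frac_constrained=0.5,
        frac_conditioned=0.0,
        frac_residual=0.5,
        rank=k,
        n_axes=k,
        total_inertia=1.0,
    )


class TestRdadapt:
    def test_equal_loadings_degenerate_all_p_one(self):
        fit = make_fake_rda_fit(np.ones((100, 3)))
        res = rdadapt_scan(fit, n_axes=3)
        np.testing.assert_array_equal(res.d2, 0.0)
        np.testing.assert_array_equal(res.p, 1.0)

    def test_too_many_axes_rejected(self):
        fit = make_fake_rda_fit(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ValueError):
            rdadapt_scan(fit, n_axes=3)

    def test_null_flagged_fraction_bounded(self, null_chain):
        res = null_chain["rd"]
        flagged = (res.q < 0.1).mean()
        assert flagged <= 0.1


class TestPcadapt:
    def test_median_distance_gives_half_p(self, null_chain):
        res = null_chain["pc"]
        d2 = res.d2[np.isfinite(res.d2)]
        p = res.p[np.isfinite(res.p)]
        at_median = np.argmin(np.abs(d2 - np.median(d2)))
        assert abs(p[at_median] - 0.5) < 0.01

    def test_locus_order_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 120),
                         size=(40, 120)).astype(float)
        G = toy_matrix(d)
        res = pcadapt_scan(G, K=2)
        perm = rng.permutation(120)
        res_p = pcadapt_scan(G.subset_loci(perm), K=2)
        np.testing.assert_allclose(res_p.d2, res.d2[perm], atol=1e-8)

    def test_adaptive_loci_rank_high(self, default_chain):
        """Truly adaptive loci concentrate in the scan's top decile."""
        p = default_chain["pc"].p
        is_true = default_chain["is_true"]
        order = np.argsort(p)
        ranks = np.empty(len(p))
        ranks[order] = np.arange(1, len(p) + 1)
        assert np.median(ranks[is_true]) <= 0.1 * len(p)


class TestIntersection:
    def test_set_algebra(self):
        ids = np.arange(1, 7)
        fst = np.array([0.9, 0.8, 0.7, 0.1, 0.1, 0.1])   # top-3 above pct=40
        pc_q = np.array([0.5, 0.01, 0.01, 0.01, 0.5, 0.5])
        rd_q = np.array([0.5, 0.5, 0.01, 0.5, 0.01, 0.5])

        class FakeScan:
            def __init__(self, q):
                self.q = q
                self.d2 = np.zeros_like(q)
                self.p = q
                self.inflation = 1.0
                self.df = 1
                self.tested = np.ones_like(q, dtype=bool)

        cs = intersect_candidates(ids, fst, FakeScan(pc_q), FakeScan(rd_q),
                                  fdr=0.1, fst_pct=40)
        assert set(cs.table.loc[cs.three_way, "locus_id"]) == {3}
        assert cs.table["enriched"].to_numpy()[cs.table["enriched"]].size \
            == ((rd_q < 0.05)).sum()
        # nesting: enriched subset of the rda flag set
        assert not np.any(cs.table["enriched"] & ~cs.table["flag_rda"])

    def test_empty_method_set_gives_empty_intersection(self, null_chain):
        cs = null_chain["candidates"]
        counts = cs.counts()
        if min(counts["fst"], counts["pcadapt"], counts["rda"]) == 0:
            assert counts["three_way"] == 0
        assert counts["three_way"] <= min(counts["fst"], counts["pcadapt"],
                                          counts["rda"])
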