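"""Adaptive index, genomic/geographic offsets, SGV and PAI."""

import numpy as np
import pandas as pd
import pytest

from geoadapt.genio import EnvTable, RasterGrid
from geoadapt.offsets import (
    AdaptiveSpace,
    adaptive_index,
    average_future_grids,
    fit_enriched_rda,
    fixed_fraction,
    genomic_offset,
    geographic_offset,
    haversine_km,
    pai,
    sgv,
    site_adaptive_index,
)


def make_space(scores, means, sds):
    scores = pd.DataFrame(scores, index=list(means))
    k = scores.shape[1]
    return AdaptiveSpace(
        env_scores=scores,
        eigenvalues=np.linspace(1.0, 0.5, k),
        means=pd.Series(means),
        sds=pd.Series(sds),
        frac_constrained=0.5,
        axis_var_fractions=np.full(k, 1.0 / k),
    )


class TestAdaptiveIndex:
    def test_arithmetic_example(self):
        # scores (0.5, -0.2), pixel z = (1, 2) -> AI = 0.5*1 - 0.2*2 = 0.1
        space = make_space({"RDA1": [0.5, -0.2]},
                           means={"v1": 10.0, "v2": 100.0},
                           sds={"v1": 2.0, "v2": 50.0})
        grid = RasterGrid({"v1": np.array([[12.0]]), "v2": np.array([[200.0]])},
                          0.0, 0.0, 1.0)
        ai = adaptive_index(space, grid)
        np.testing.assert_allclose(ai[0, 0, 0], 0.1, atol=1e-12)

    def test_zero_at_fit_mean(self):
        space = make_space({"RDA1": [0.7, 0.3], "RDA2": [-0.2, 0.5]},
                           means={"v1": 5.0, "v2": -3.0},
                           sds={"v1": 1.0, "v2": 4.0})
        grid = RasterGrid({"v1": np.full((2, 2), 5.0),
                           "v2": np.full((2, 2), -3.0)}, 0.0, 0.0, 1.0)
        np.testing.assert_array_equal(adaptive_index(space, grid), 0.0)

    def test_missing_variable_rejected(self):
        space = make_space({"RDA1": [1.0]}, means={"v1": 0.0}, sds={"v1": 1.0})
        grid = RasterGrid({"other": np.ones((2, 2))}, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="lacks"):
            adaptive_index(space, grid)

    def test_nodata_propagates(self):
        space = make_space({"RDA1": [1.0]}, means={"v1": 0.0}, sds={"v1": 1.0})
        data = np.ones((2, 2))
        data[0, 0] = np.nan
        ai = adaptive_index(space, RasterGrid({"v1": data}, 0.0, 0.0, 1.0))
        assert np.isnan(ai[0, 0, 0]) and np.isfinite(ai[0, 1, 1])


class TestGenomicOffset:
    def test_zero_shift_identity(self):
        ai = np.random.default_rng(0).normal(size=(3, 4, 5))
        np.testing.assert_array_equal(genomic_offset(ai, ai.copy()), 0.0)

    def test_single_axis_arithmetic(self):
        cur = np.zeros((1, 1, 1))
        fut = np.full((1, 1, 1), 0.3)
        assert genomic_offset(cur, fut)[0, 0] == pytest.approx(0.3)

    def test_triangle_inequality_per_pixel(self):
        rng = np.random.default_rng(1)
        a, b, c = (rng.normal(size=(3, 6, 6)) for _ in range(3))
        direct = genomic_offset(a, c)
        via_b = genomic_offset(a, b) + genomic_offset(b, c)
        assert np.all(via_b >= direct - 1e-12)

    def test_l2_and_weights(self):
        cur = np.zeros((2, 1, 1))
        fut = np.stack([np.full((1, 1), 3.0), np.full((1, 1), 4.0)])
        assert genomic_offset(cur, fut, agg="l2")[0, 0] == pytest.approx(5.0)
        assert genomic_offset(cur, fut, weights=np.array([2.0, 1.0]))[0, 0] \
            == pytest.approx(10.0)


class TestGeographicOffset:
    def grid(self, ncols=10):
        return RasterGrid({"v": np.zeros((1, ncols))}, 0.0, 50.0, 0.1)

    def test_self_match_zero_everywhere(self):
        grid = self.grid()
        ai = np.linspace(0, 1, 10).reshape(1, 1, 10)
        res = geographic_offset(ai, ai.copy(), grid, tolerance=0.01)
        np.testing.assert_array_equal(res.offset_km, 0.0)
        assert not res.no_match.any()

    def test_uniform_shift_on_linear_gradient_matches_brute_force(self):
        """1 x 10 transect, AI = column index, future shifted by +2.5 units."""
        grid = self.grid()
        cur = np.arange(10.0).reshape(1, 1, 10)
        fut = cur + 2.5
        tol = 0.6
        res = geographic_offset(cur, fut, grid, tolerance=tol)
        lat, lon = grid.latlon_arrays()
        for j in range(10):
            match = [k for k in range(10) if abs(cur[0, 0, k] - fut[0, 0, j]) <= tol]
            if not match:
                assert res.no_match[0, j] and np.isnan(res.offset_km[0, j])
            else:
                expect = min(haversine_km(lat[0], lon[j], lat[0], lon[k])
                             for k in match)
                np.testing.assert_allclose(res.offset_km[0, j], expect,
                                           atol=1e-9)
        # trailing (eastern) edge of the gradient has no analog left
        assert res.no_match[0, -1]

    def test_population_match_mode(self):
        grid = self.grid(5)
        cur = np.arange(5.0).reshape(1, 1, 5)
        fut = cur + 1.0
        sites = pd.DataFrame({"lat": [50.05], "lon": [0.05]})  # pixel 0 center
        res = geographic_offset(cur, fut, grid, tolerance=0.1,
                                match_sites=sites,
                                site_ai_current=np.array([[1.0]]))
        # only the pixel whose future AI equals the site's current AI matches
        assert np.isfinite(res.offset_km[0, 0])
        assert res.no_match[0, 2:].all()

    def test_invalid_tolerance(self):
        grid = self.grid(3)
        ai = np.zeros((1, 1, 3))
        with pytest.raises(ValueError):
            geographic_offset(ai, ai, grid, tolerance=0.0)


class TestPopulationSummaries:
    def frame(self, rows, cols=None):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        cols = cols or [f"l{j}" for j in range(rows.shape[1])]
        return pd.DataFrame(rows, columns=cols,
                            index=[f"p{i}" for i in range(rows.shape[0])])

    def test_sgv_examples(self):
        P = self.frame([[0.5, 0.5], [0.0, 1.0], [0.1, 0.5]])
        s = sgv(P, np.array(["l0", "l1"]))
        assert s["p0"] == pytest.approx(0.25)   # maximal diversity
        assert s["p1"] == pytest.approx(0.0)    # fixation
        assert s["p2"] == pytest.approx((0.09 + 0.25) / 2)
        assert (s <= 0.25 + 1e-12).all() and (s >= 0).all()

    def test_sgv_across_mode_single_value(self):
        P = self.frame([[0.2, 0.4], [0.6, 0.8]])
        s = sgv(P, np.array(["l0", "l1"]), mode="across")
        assert s.nunique() == 1

    def test_pai_examples(self):
        ident = self.frame([[0.3, 0.7], [0.3, 0.7]])
        np.testing.assert_allclose(pai(ident, np.array(["l0", "l1"])), 0.0)
        polar = self.frame([[0.0, 0.0], [1.0, 1.0]])
        np.testing.assert_allclose(pai(polar, np.array(["l0", "l1"])), 0.5)

    def test_pai_duplicate_population_recomputes_mean(self):
        """Hand-worked 3-population toy plus a duplicated population."""
        P3 = self.frame([[0.0], [0.5], [1.0]])
        np.testing.assert_allclose(pai(P3, np.array(["l0"])),
                                   [0.5, 0.0, 0.5])
        P4 = self.frame([[0.0], [0.0], [0.5], [1.0]])
        # pbar = 0.375 once the duplicate enters the mean
        np.testing.assert_allclose(pai(P4, np.array(["l0"])),
                                   [0.375, 0.375, 0.125, 0.625])

    def test_missing_locus_excluded(self):
        P = self.frame([[0.5, np.nan], [0.2, 0.4]])
        s = sgv(P, np.array(["l0", "l1"]))
        assert s["p0"] == pytest.approx(0.25)

    def test_fixed_fraction(self):
        P = self.frame([[0.0, 0.995, 0.5, 1.0]])
        assert fixed_fraction(P, np.array(["l0", "l1", "l2", "l3"]))["p0"] \
            == pytest.approx(0.75)

    def test_empty_candidate_set_rejected(self):
        P = self.frame([[0.5], [0.4]])
        with pytest.raises(ValueError):
            sgv(P, np.array([], dtype=object))


class TestEnrichedRda:
    def test_single_driver_dominates_first_axis(self):
        rng = np.random.default_rng(0)
        driver = rng.normal(size=60)
        other = rng.normal(size=60)
        env = EnvTable(pd.DataFrame({"driver": driver, "other": other}))
        Y = np.outer(driver, rng.normal(size=20)) + rng.normal(size=(60, 20)) * 0.1
        space, fit = fit_enriched_rda(Y, env, n_axes=2)
        scores1 = space.env_scores["RDA1"].abs()
        assert scores1["driver"] == scores1.max()
        assert scores1["driver"] > 0.9

    def test_permuted_variable_order_same_axes(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        Y = rng.normal(size=(40, 10))
        s1, f1 = fit_enriched_rda(Y, EnvTable(frame), n_axes=2)
        s2, f2 = fit_enriched_rda(Y, EnvTable(frame[["c", "a", "b"]]), n_axes=2)
        np.testing.assert_allclose(f1.eigenvalues, f2.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(
            s1.env_scores.loc[list("abc")].abs().to_numpy(),
            s2.env_scores.loc[list("abc")].abs().to_numpy(), atol=1e-8)

    def test_site_index_zero_at_mean(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        env = EnvTable(frame)
        Y = rng.normal(size=(30, 8))
        space, _ = fit_enriched_rda(Y, env, n_axes=2)
        at_mean = pd.DataFrame([env.means], columns=["u", "v"])
        np.testing.assert_allclose(site_adaptive_index(space, at_mean), 0.0,
                                   atol=1e-12)

    def test_too_few_snps_rejected(self):
        env = EnvTable(pd.DataFrame({"v": np.arange(10.0)}))
        with pytest.raises(ValueError, match="enriched"):
            fit_enriched_rda(np.zeros((10, 2)), env, n_axes=3)


def test_average_future_grids():
    a = RasterGrid({"v": np.zeros((2, 2))}, 0.0, 0.0, 1.0)
    b = RasterGrid({"v": np.full((2, 2), 2.0)}, 0.0, 0.0, 1.0)
    avg = average_future_grids([a, b])
    np.testing.assert_array_equal(avg.data["v"], 1.0)
    bad = RasterGrid({"v": np.zeros((2, 2))}, 0.0, 0.0, 2.0)
    with pytest.raises(ValueError):
        average_future_grids([a, bad])
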