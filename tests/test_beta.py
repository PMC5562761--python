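"""Sorensen/Whittaker turnover statistics and the Mantel permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import elevdiv as ed
from elevdiv.beta import DissimilarityMatrix, dissimilarity_matrix


class TestSorensen:
    @pytest.mark.parametrize(
        "abc, expected", [((5, 0, 0), 0.0), ((0, 3, 2), 1.0), ((2, 1, 1), 1 / 3)]
    )
    def test_examples(self, abc, expected):
        assert ed.sorensen(*abc) == pytest.approx(expected)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_symmetry_and_bounds(self, a, b, c):
        if a + b == 0 or a + c == 0:
            with pytest.raises(ValueError):
                ed.sorensen(a, b, c)
            return
        s = ed.sorensen(a, b, c)
        assert s == ed.sorensen(a, c, b)
        assert 0 <= s <= 1
        assert (s == 0) == (b == 0 and c == 0)
        assert (s == 1) == (a == 0)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            ed.sorensen(0, 0, 0)


class TestAdjacentTurnover:
    def test_full_domain_species_no_turnover(self):
        grid = ed.build_grid("g", 0, 1000, 250)
        inc = ed.build_incidence(
            grid, [ed.SpeciesRange(f"s{i}", "g", frozenset({0, 3}), "Oriental") for i in range(3)]
        )
        np.testing.assert_allclose(ed.adjacent_turnover(inc), 0.0)

    def test_single_band_species_full_turnover(self):
        grid = ed.build_grid("g", 0, 750, 250)
        inc = ed.build_incidence(
            grid, [ed.SpeciesRange(f"s{i}", "g", frozenset({i}), "Oriental") for i in range(3)]
        )
        np.testing.assert_allclose(ed.adjacent_turnover(inc), 1.0)

    def test_hand_enumeration(self):
        grid = ed.build_grid("g", 0, 750, 250)
        inc = ed.build_incidence(
            grid,
            [
                ed.SpeciesRange("s1", "g", frozenset({0, 1}), "Oriental"),
                ed.SpeciesRange("s2", "g", frozenset({1, 2}), "Oriental"),
            ],
        )
        np.testing.assert_allclose(ed.adjacent_turnover(inc), [1 / 3, 1 / 3])

    def test_empty_band_reported_missing(self):
        grid = ed.build_grid("g", 0, 750, 250)
        inc = ed.build_incidence(grid, [ed.SpeciesRange("s1", "g", frozenset({0}), "Oriental")])
        t = ed.adjacent_turnover(inc)
        assert np.isnan(t).all()  # bands 1 and 2 are empty


class TestWhittaker:
    def test_formula(self):
        assert ed.whittaker(30, 10) == pytest.approx(2.0)
        assert ed.whittaker(7, 7) == 0.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            ed.whittaker(10, 0)
        with pytest.raises(ValueError):
            ed.whittaker(5, 10)

    def test_site_table_matches_brute_force(self):
        ranges = ed.generate_ranges(ed.ScenarioConfig(seed=21))
        sites = ed.generate_sites(ranges, ed.ScenarioConfig(seed=21))
        south = sites[sites["slope"] == "south"]
        w = ed.whittaker_from_sites(south)
        s = south["species_id"].nunique()
        alpha = np.mean([g["species_id"].nunique() for _, g in south.groupby("site_id")])
        assert w == pytest.approx(s / alpha - 1)

    def test_duplicating_sites_leaves_index_unchanged(self):
        tbl = pd.DataFrame(
            {"site_id": ["a", "a", "b"], "species_id": ["x", "y", "x"]}
        )
        dup = pd.concat(
            [tbl, tbl.assign(site_id=tbl["site_id"] + "_copy")], ignore_index=True
        )
        assert ed.whittaker_from_sites(dup) == pytest.approx(ed.whittaker_from_sites(tbl))

    def test_band_level_fallback(self, toy_incidence):
        w = ed.whittaker_from_incidence(toy_incidence)
        assert w == pytest.approx(3 / np.mean([1, 2, 2]) - 1)


def _random_dissim(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        d = _random_dissim(rng, 8)
        res = ed.mantel(d, d, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_anticorrelation(self):
        rng = np.random.default_rng(1)
        d = _random_dissim(rng, 7)
        d2 = d.max() - d
        np.fill_diagonal(d2, 0.0)
        res = ed.mantel(d, d2, n_perm=99, seed=2)
        assert res.r == pytest.approx(-1.0)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(3)
        d1 = _random_dissim(rng, 9)
        noise = 0.15 * _random_dissim(rng, 9)
        d2 = d1 + noise  # strong positive association -> small, stable p
        ours = ed.mantel(d1, d2, n_perm=999, seed=4)
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(d1), DistanceMatrix(d2), permutations=999, alternative="greater"
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-12)
        assert ours.p == pytest.approx(p_ref, abs=0.02)  # permutation p, binomial error

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        d1, d2 = _random_dissim(rng, 8), _random_dissim(rng, 8)
        perm = rng.permutation(8)
        base = ed.mantel(d1, d2, n_perm=99, seed=6)
        rel = ed.mantel(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)], n_perm=99, seed=6)
        assert base.r == pytest.approx(rel.r)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(7)
        d1, d2 = _random_dissim(rng, 8), _random_dissim(rng, 8)
        assert ed.mantel(d1, d2, n_perm=299, seed=9) == ed.mantel(d1, d2, n_perm=299, seed=9)

    def test_constant_matrix_rejected(self):
        d = np.ones((5, 5)) - np.eye(5)
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="constant"):
            ed.mantel(d, _random_dissim(rng, 5), n_perm=9, seed=0)

    def test_null_p_roughly_uniform(self):
        # independent matrices: permutation p should not pile up near 0
        rng = np.random.default_rng(10)
        ps = []
        for i in range(60):
            res = ed.mantel(
                _random_dissim(rng, 8), _random_dissim(rng, 8), n_perm=99, seed=100 + i
            )
            ps.append(res.p)
        assert 0.25 < np.mean(ps) < 0.75
        assert (np.asarray(ps) <= 0.05).mean() < 0.2


class TestCrossSlope:
    def test_identical_compositions_flagged_constant(self, south_grid, north_grid):
        mk = lambda slope, grid: ed.build_incidence(
            grid,
            [ed.SpeciesRange(f"s{i}", slope, frozenset({0, grid.n_bands - 1}), "Oriental") for i in range(4)],
        )
        pairs = ed.pair_bands(south_grid, north_grid)
        cst = ed.cross_slope_turnover(mk("south", south_grid), mk("north", north_grid), pairs)
        np.testing.assert_allclose(cst.dissimilarity, 0.0)
        assert cst.standardized_slope is None

    def test_synthetic_pairs_and_slope_range(self, south_grid, north_grid):
        ranges = ed.generate_ranges(ed.ScenarioConfig(seed=33))
        inc_s = ed.build_incidence(south_grid, ranges["south"])
        inc_n = ed.build_incidence(north_grid, ranges["north"])
        pairs = ed.pair_bands(south_grid, north_grid)
        cst = ed.cross_slope_turnover(inc_s, inc_n, pairs)
        assert len(cst.dissimilarity) == 10
        finite = cst.dissimilarity[np.isfinite(cst.dissimilarity)]
        assert ((finite >= 0) & (finite <= 1)).all()
        if cst.standardized_slope is not None:
            assert -1 <= cst.standardized_slope <= 1

    def test_linear_decline_gives_minus_one(self, south_grid, north_grid):
        # construct compositions whose dissimilarity decreases with elevation:
        # at pair i, both slopes share i species and each holds (9 - i) unique
        pairs = ed.pair_bands(south_grid, north_grid)

        def build(slope, grid, idx):
            cols = {}
            for k, (i, j) in enumerate(pairs):
                band = (i, j)[idx]
                for s in range(k):
                    cols.setdefault(f"shared_{k}_{s}", set()).add(band)
                for s in range(9 - k):
                    cols.setdefault(f"{slope}_uniq_{k}_{s}", set()).add(band)
            return ed.build_incidence(
                grid,
                [ed.SpeciesRange(sp, slope, frozenset(b), "Oriental") for sp, b in cols.items()],
            )

        cst = ed.cross_slope_turnover(
            build("south", south_grid, 0), build("north", north_grid, 1), pairs
        )
        assert cst.standardized_slope == pytest.approx(-1.0, abs=1e-9)

    def test_needs_three_pairs(self, toy_incidence):
        with pytest.raises(ValueError):
            ed.cross_slope_turnover(toy_incidence, toy_incidence, [(0, 0)])


class TestTurnoverFit:
    def test_u_shape_positive_quadratic(self):
        x = np.linspace(1000, 3500, 10)
        rng = np.random.default_rng(11)
        y = 0.5 + ((x - x.mean()) / 1000) ** 2 * 0.2 + 0.01 * rng.standard_normal(10)
        fit = ed.turnover_elevation_fit(y, x)
        assert fit.order == 2
        assert fit.coefficients[2] > 0

    def test_hump_negative_quadratic(self):
        x = np.linspace(1000, 3500, 10)
        rng = np.random.default_rng(12)
        order2, neg_quad = 0, 0
        reps = 25
        for _ in range(reps):
            y = 0.8 - ((x - x.mean()) / 1000) ** 2 * 0.2 + 0.01 * rng.standard_normal(10)
            fit = ed.turnover_elevation_fit(y, x)
            order2 += fit.order == 2
            neg_quad += fit.order >= 2 and fit.coefficients[2] < 0
        assert order2 >= 0.7 * reps
        assert neg_quad == reps

    def test_nan_turnover_dropped(self):
        x = np.linspace(0, 9, 10)
        y = 0.1 * x
        y_nan = y.copy()
        y_nan[3] = np.nan
        fit = ed.turnover_elevation_fit(y_nan, x)
        assert fit.order == 1


class TestDissimilarityMatrix:
    def test_matrix_invariants(self, toy_incidence):
        dm = dissimilarity_matrix(toy_incidence)
        v = dm.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert v[0, 1] == pytest.approx(1 / 3)

    def test_rejects_asymmetry(self):
        bad = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(("a", "b"), bad)
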