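"""Dissimilarities, non-metric MDS and environmental vector fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

import aeropollen as ap
from aeropollen.errors import ConfigurationError, ValidationError
from aeropollen.ordination import (
    bray_curtis,
    dissimilarity_matrix,
    fit_env_vectors,
    nmds,
    select_top_taxa,
)


def _frame(values, sites=None, taxa=None):
    values = np.asarray(values, dtype=float)
    sites = sites or [f"s{i}" for i in range(values.shape[0])]
    taxa = taxa or [f"t{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=sites, columns=taxa)


class TestSelectTopTaxa:
    def test_k_all_is_identity(self, city_matrix):
        out = select_top_taxa(city_matrix, k=city_matrix.shape[1])
        pd.testing.assert_frame_equal(out, city_matrix)

    def test_disjoint_top1_keeps_both(self):
        m = _frame([[9, 1], [1, 9]])
        out = select_top_taxa(m, k=1)
        assert list(out.columns) == ["t0", "t1"]

    def test_city_matrix_top8_retains_every_citys_leaders(self, city_matrix):
        out = select_top_taxa(city_matrix, k=8)
        for site, row in city_matrix.iterrows():
            for taxon in row.dropna().nlargest(8).index:
                assert taxon in out.columns

    def test_values_not_renormalised(self, city_matrix):
        out = select_top_taxa(city_matrix, k=8)
        assert out.loc["Darwin", "Poaceae"] == city_matrix.loc["Darwin", "Poaceae"]

    def test_k_zero_rejected(self, city_matrix):
        with pytest.raises(ConfigurationError):
            select_top_taxa(city_matrix, k=0)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(_frame([[10, 20], [10, 20]]))
        assert d.iloc[0, 1] == 0.0

    def test_hand_worked_pair(self):
        d = bray_curtis(_frame([[60, 40], [40, 60]]))
        assert d.iloc[0, 1] == pytest.approx(0.2)

    def test_disjoint_supports_one(self):
        d = bray_curtis(_frame([[100, 0], [0, 100]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_all_zero_row_raises(self):
        with pytest.raises(ValidationError, match="s1"):
            bray_curtis(_frame([[1, 2], [0, 0]]))

    def test_matrix_invariants(self, city_matrix):
        d = dissimilarity_matrix(city_matrix).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()


def _reference_stress(D, coords):
    """Independent Kruskal stress-1: sklearn isotonic fit of configuration
    distances against dissimilarity ranks (no shared code with nmds)."""
    d = squareform(D, checks=False)
    e = pdist(coords)
    iso = IsotonicRegression().fit(np.argsort(np.argsort(d)), e)
    disp = iso.predict(np.argsort(np.argsort(d)))
    return np.sqrt(((e - disp) ** 2).sum() / (e**2).sum())


class TestNmds:
    def test_planar_distances_embed_exactly(self, rng):
        pts = rng.standard_normal((4, 2))
        D = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(D, n_restarts=20, seed=0)
        assert res.stress <= 1e-3

    def test_three_equidistant_sites(self):
        D = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        res = nmds(D, n_restarts=10, seed=0)
        sides = pdist(res.coords.to_numpy())
        assert res.stress <= 1e-6
        assert np.allclose(sides, sides[0], rtol=1e-3)

    def test_reproducible_given_seed(self, city_matrix):
        d = dissimilarity_matrix(select_top_taxa(city_matrix, 8))
        a = nmds(d, n_restarts=5, seed=11)
        b = nmds(d, n_restarts=5, seed=11)
        assert a.stress == b.stress
        pd.testing.assert_frame_equal(a.coords, b.coords)

    def test_coordinates_centred(self, city_ordination):
        assert np.allclose(city_ordination.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_stress_non_increasing_in_dims(self, rng):
        values = rng.gamma(2.0, 10.0, size=(7, 9))
        d = dissimilarity_matrix(_frame(values))
        s2 = nmds(d, n_dims=2, n_restarts=20, seed=3).stress
        s3 = nmds(d, n_dims=3, n_restarts=20, seed=3).stress
        assert s3 <= s2 + 1e-6

    def test_dims_must_be_below_n_sites(self):
        D = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        with pytest.raises(ConfigurationError):
            nmds(D, n_dims=3)

    def test_small_problem_matches_direct_optimiser(self, rng):
        """On <=5 sites the SMACOF solution matches a brute-force refined
        optimum of an independently coded stress function within 1e-2."""
        values = rng.gamma(2.0, 10.0, size=(5, 6))
        D = dissimilarity_matrix(_frame(values))
        res = nmds(D, n_restarts=40, seed=5)
        Dv = D.to_numpy()

        def objective(flat):
            return _reference_stress(Dv, flat.reshape(5, 2))

        best = np.inf
        for _ in range(40):
            x0 = rng.standard_normal(10)
            out = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10})
            best = min(best, out.fun)
        assert res.stress == pytest.approx(best, abs=1e-2)

    def test_agrees_with_sklearn_smacof(self, city_matrix):
        """Independent cross-check of the minimum stress on the city data."""
        from sklearn.manifold import smacof

        d = dissimilarity_matrix(select_top_taxa(city_matrix, 8))
        mine = nmds(d, n_restarts=30, seed=2).stress
        rng = np.random.default_rng(2)
        theirs = min(
            smacof(
                d.to_numpy(), metric=False, n_components=2,
                init=rng.standard_normal((len(d), 2)), n_init=1,
                normalized_stress=True, max_iter=500, eps=1e-8, random_state=0,
            )[1]
            for _ in range(30)
        )
        assert mine == pytest.approx(theirs, abs=5e-3)


class TestEnvFit:
    def test_perfectly_aligned_variable(self, rng):
        coords = pd.DataFrame(
            rng.standard_normal((8, 2)), columns=["axis1", "axis2"]
        )
        env = pd.DataFrame({"v": coords["axis1"]}, index=coords.index)
        fit = fit_env_vectors(coords, env, n_permutations=99, seed=0)
        assert fit.loc["v", "r2"] == pytest.approx(1.0)
        assert abs(fit.loc["v", "axis1"]) == pytest.approx(1.0, abs=1e-9)
        assert fit.loc["v", "axis2"] == pytest.approx(0.0, abs=1e-9)

    def test_independent_variable_small_r2_and_p_floor(self, rng):
        coords = pd.DataFrame(
            rng.standard_normal((30, 2)), columns=["axis1", "axis2"]
        )
        env = pd.DataFrame({"noise": rng.standard_normal(30)}, index=coords.index)
        fit = fit_env_vectors(coords, env, n_permutations=999, seed=1)
        assert fit.loc["noise", "r2"] < 0.3
        assert fit.loc["noise", "p_value"] >= 1 / 1000

    def test_r2_invariant_under_orthogonal_transform(self, city_ordination, city_env, rng):
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        reflect = np.array([[1.0, 0.0], [0.0, -1.0]])
        base = fit_env_vectors(city_ordination, city_env, n_permutations=0, seed=0)
        rotated = city_ordination.coords.to_numpy() @ rot @ reflect
        coords2 = pd.DataFrame(
            rotated, index=city_ordination.coords.index, columns=["axis1", "axis2"]
        )
        alt = fit_env_vectors(coords2, city_env, n_permutations=0, seed=0)
        assert np.allclose(base["r2"].values, alt["r2"].values, atol=1e-10)

    def test_constant_variable_rejected(self, city_ordination, city_env):
        env = city_env.copy()
        env["flat"] = 1.0
        with pytest.raises(ValidationError, match="flat"):
            fit_env_vectors(city_ordination, env, n_permutations=0, seed=0)

    def test_direction_unit_norm(self, city_ordination, city_env):
        fit = fit_env_vectors(city_ordination, city_env, n_permutations=0, seed=0)
        norms = np.hypot(fit["axis1"], fit["axis2"])
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_matches_direct_regression_r2(self, city_ordination, city_env):
        """r2 equals the squared multiple correlation from an explicit
        two-regressor least-squares fit (independent linear algebra path)."""
        X = city_ordination.coords.to_numpy()
        X = np.column_stack([np.ones(len(X)), X - X.mean(axis=0)])
        fit = fit_env_vectors(city_ordination, city_env, n_permutations=0, seed=0)
        for var in city_env.columns:
            y = city_env.reindex(city_ordination.coords.index)[var].to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert fit.loc[var, "r2"] == pytest.approx(r2, abs=1e-10)
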