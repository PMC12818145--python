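import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from plsipa import (
    DegenerateDataError,
    LatentVariable,
    ModelSpec,
    PLSPCAModel,
    SingularityError,
    fit,
    latent_scores,
    location_params,
    outer_loadings,
    path_coefficients,
    pca_block_weights,
    standardize,
    total_effects,
)
from plsipa.synthetic import GeneratorConfig, generate

from conftest import composite_loading, random_standardized_block, score_reliability


def oracle_dominant_weights(X):
    """Independent route: explicit covariance + general eigensolver."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    C = np.einsum("ni,nj->ij", Xc, Xc) / (n - 1)
    evals, evecs = scipy.linalg.eig(C)
    k = int(np.argmax(evals.real))
    v = evecs[:, k].real
    v = v / np.linalg.norm(v)
    return v, float(evals[k].real)


class TestStandardize:
    def test_symmetric_triple(self):
        out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        once = standardize(df)
        twice = standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateDataError, match="x"):
            standardize(pd.DataFrame({"x": [10.0, 10.0, 10.0]}))


class TestPcaBlockWeights:
    def test_single_indicator(self, rng):
        block = pd.DataFrame({"x": rng.standard_normal(20)})
        w, ext = pca_block_weights(standardize(block))
        assert w["x"] == 1.0
        assert ext.explained_proportion == 1.0

    def test_perfectly_correlated_pair_gets_equal_weights(self, rng):
        x = rng.standard_normal(30)
        block = standardize(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        w, ext = pca_block_weights(block)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)
        assert ext.explained_proportion == pytest.approx(1.0)

    def test_matches_independent_eigensolver(self, rng):
        X = random_standardized_block(rng, 6, 3)
        w, ext = pca_block_weights(pd.DataFrame(X, columns=list("abc")))
        v, lam = oracle_dominant_weights(X)
        assert ext.eigenvalue == pytest.approx(lam, abs=1e-10)
        sign = np.sign(v @ ext.eigenvector)
        np.testing.assert_allclose(sign * v / np.abs(v).sum(), w, atol=1e-10)

    def test_abs_sum_is_one(self, rng):
        for k in (2, 4, 8):
            X = random_standardized_block(rng, 40, k)
            w, _ = pca_block_weights(X)
            assert np.abs(w).sum() == pytest.approx(1.0, abs=1e-10)

    def test_sign_orientation_largest_component_positive(self, rng):
        X = random_standardized_block(rng, 40, 4)
        w1, _ = pca_block_weights(X)
        w2, _ = pca_block_weights(X)  # deterministic
        np.testing.assert_array_equal(w1, w2)
        assert w1[np.argmax(np.abs(w1))] > 0

    def test_all_zero_block_rejected(self):
        with pytest.raises(DegenerateDataError):
            pca_block_weights(np.zeros((10, 3)))


class TestLatentScores:
    def spec2(self):
        return ModelSpec(
            [LatentVariable("L", ("a", "b", "c")), LatentVariable("S", ("d",))],
            [("L", "S")],
        )

    def test_single_indicator_score_is_the_column(self, rng):
        spec = self.spec2()
        df = standardize(pd.DataFrame(rng.standard_normal((25, 4)), columns=list("abcd")))
        scores = latent_scores(df, spec, {"L": [0.4, 0.3, 0.3], "S": [1.0]})
        np.testing.assert_allclose(scores["S"], df["d"], atol=1e-12)

    def test_known_weights_match_direct_arithmetic(self, rng):
        spec = self.spec2()
        df = standardize(pd.DataFrame(rng.standard_normal((6, 4)), columns=list("abcd")))
        w = np.array([0.5, 0.3, 0.2])
        scores = latent_scores(df, spec, {"L": w, "S": [1.0]})
        t = df[["a", "b", "c"]].to_numpy() @ w
        expected = (t - t.mean()) / t.std(ddof=1)
        np.testing.assert_allclose(scores["L"], expected, atol=1e-12)

    def test_scores_standardized(self, district_fit):
        s = district_fit.scores
        np.testing.assert_allclose(s.mean(), 0, atol=1e-8)
        np.testing.assert_allclose(s.var(ddof=1), 1, atol=1e-8)


class TestOuterLoadings:
    def test_single_indicator_loading_is_one(self, district_fit):
        assert district_fit.loadings["y1_1"] == pytest.approx(1.0)
        assert district_fit.loadings["y2_1"] == pytest.approx(1.0)

    def test_orthogonal_indicator_loads_zero(self):
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)  # exactly orthogonal to a
        spec = ModelSpec([LatentVariable("L", ("a",)), LatentVariable("O", ("b",))], [])
        df = standardize(pd.DataFrame({"a": a, "b": b}))
        scores = latent_scores(df, spec, {"L": [1.0], "O": [1.0]})
        cross = float(np.corrcoef(df["b"], scores["L"])[0, 1])
        assert cross == pytest.approx(0.0, abs=1e-12)

    def test_recovers_population_loading(self):
        spec = ModelSpec([LatentVariable("L", ("i1", "i2", "i3"))], [])
        cfg = GeneratorConfig(
            spec=spec,
            population_paths={},
            population_loadings={"i1": 0.9, "i2": 0.9, "i3": 0.9},
            n_obs=5000,
            seed=5,
        )
        res = fit(generate(cfg), spec)
        expected = composite_loading(0.9, 3)
        for ind in spec.indicator_names:
            assert res.loadings[ind] == pytest.approx(expected, abs=0.03)

    def test_loadings_bounded_by_one(self, district_fit):
        assert (district_fit.loadings.abs() <= 1 + 1e-8).all()


class TestPathCoefficients:
    def test_child_equals_parent(self, rng):
        spec = ModelSpec(
            [LatentVariable("A", ("a",)), LatentVariable("B", ("b",))], [("A", "B")]
        )
        x = rng.standard_normal(40)
        df = standardize(pd.DataFrame({"a": x, "b": 3 * x - 2}))
        res = fit(df, spec)
        assert res.path_coefficients[("A", "B")] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_child_coefficient_zero(self):
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        spec = ModelSpec(
            [LatentVariable("A", ("a",)), LatentVariable("B", ("b",))], [("A", "B")]
        )
        res = fit(pd.DataFrame({"a": a, "b": b}), spec)
        assert res.path_coefficients[("A", "B")] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_population_path(self, two_latent_config):
        # composite scores are noisy proxies: the standardised coefficient's
        # estimand is the path attenuated by both blocks' score reliabilities
        cfg = two_latent_config(path=0.7, n=5000, seed=9)
        res = fit(generate(cfg), cfg.spec)
        estimand = 0.7 * score_reliability(0.9, 2) ** 2
        assert res.path_coefficients[("A", "B")] == pytest.approx(estimand, abs=0.05)

    def test_matches_statsmodels_ols(self, district_fit):
        """Independent refit of each structural equation."""
        import statsmodels.api as sm

        spec = district_fit.spec
        for child in spec.endogenous:
            parents = list(spec.adjacency.parents(child))
            olsres = sm.OLS(
                district_fit.scores[child], district_fit.scores[parents]
            ).fit()
            for p in parents:
                assert district_fit.path_coefficients[(p, child)] == pytest.approx(
                    olsres.params[p], abs=1e-10
                )

    def test_collinear_parents_rejected(self, rng):
        spec = ModelSpec(
            [
                LatentVariable("A", ("a",)),
                LatentVariable("B", ("b",)),
                LatentVariable("C", ("c",)),
            ],
            [("A", "C"), ("B", "C")],
        )
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.standard_normal(30)})
        with pytest.raises(SingularityError):
            fit(df, spec)


class TestTotalEffects:
    def chain_spec(self):
        return ModelSpec(
            [LatentVariable(n, (n.lower(),)) for n in ("A", "B", "C")],
            [("A", "B"), ("B", "C")],
        )

    def test_direct_only_equals_coefficient(self, two_latent_config):
        cfg = two_latent_config(n=100, seed=1)
        res = fit(generate(cfg), cfg.spec)
        assert res.total_effects[("A", "B")] == res.path_coefficients[("A", "B")]

    def test_chain_product(self):
        spec = self.chain_spec()
        te = total_effects({("A", "B"): 0.5, ("B", "C"): 0.4}, spec)
        assert te[("A", "C")] == pytest.approx(0.20)

    def test_three_route_mediation_sum(self):
        """Signed path-product arithmetic over three parallel mediation routes."""
        spec = ModelSpec(
            [LatentVariable(n, (n.lower(),)) for n in ("SE", "P", "FS", "HE", "M")],
            [("SE", "P"), ("SE", "FS"), ("SE", "HE"), ("P", "M"), ("FS", "M"), ("HE", "M")],
        )
        coeffs = {
            ("SE", "P"): 0.464,
            ("SE", "FS"): 0.720,
            ("SE", "HE"): 0.513,
            ("P", "M"): -0.185,
            ("FS", "M"): 0.178,
            ("HE", "M"): -0.011,
        }
        te = total_effects(coeffs, spec)
        expected = 0.464 * (-0.185) + 0.720 * 0.178 + 0.513 * (-0.011)
        assert te[("SE", "M")] == pytest.approx(expected, abs=1e-12)
        assert te[("SE", "M")] == pytest.approx(0.0367, abs=5e-4)

    def test_matches_path_enumeration_oracle(self, rng):
        """Random DAG coefficients vs networkx all-simple-paths enumeration."""
        import itertools

        import networkx as nx

        names = list("ABCDEF")
        spec = ModelSpec(
            [LatentVariable(n, (n.lower(),)) for n in names],
            [
                (names[i], names[j])
                for i, j in itertools.combinations(range(6), 2)
                if rng.random() < 0.6
            ],
        )
        coeffs = {p: float(rng.normal()) for p in spec.adjacency.paths}
        te = total_effects(coeffs, spec)
        g = nx.DiGraph(list(spec.adjacency.paths))
        for (s, t), val in te.items():
            expected = sum(
                np.prod([coeffs[(a, b)] for a, b in zip(path, path[1:])])
                for path in nx.all_simple_paths(g, s, t)
            )
            assert val == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_district_model_end_to_end(self, district_fit, district_config):
        assert set(district_fit.path_coefficients) == set(
            district_config.spec.adjacency.paths
        )
        assert len(district_fit.path_coefficients) == 6

    def test_single_indicator_blocks_reduce_to_columns(self, rng):
        spec = ModelSpec(
            [LatentVariable("A", ("a",)), LatentVariable("B", ("b",))], [("A", "B")]
        )
        df = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        res = fit(df, spec)
        np.testing.assert_allclose(res.scores["A"], standardize(df)["a"], atol=1e-12)
        assert res.loadings["a"] == pytest.approx(1.0)
        assert res.loadings["b"] == pytest.approx(1.0)

    def test_scores_invariant_under_affine_indicator_transforms(self, district_data, district_config):
        spec = district_config.spec
        res1 = fit(district_data, spec)
        shifted = district_data * 7.5 + 1234.0
        res2 = fit(shifted, spec)
        np.testing.assert_allclose(res1.scores, res2.scores, atol=1e-10)
        np.testing.assert_allclose(res1.loadings, res2.loadings, atol=1e-10)

    def test_single_block_score_is_first_principal_component(self, rng):
        """Equivalence with classical PCA on one block (sklearn oracle)."""
        from sklearn.decomposition import PCA

        spec = ModelSpec([LatentVariable("L", ("a", "b", "c", "d"))], [])
        df = pd.DataFrame(random_standardized_block(rng, 60, 4), columns=list("abcd"))
        res = fit(df, spec)
        pc1 = PCA(n_components=1).fit_transform(standardize(df).to_numpy())[:, 0]
        r = np.corrcoef(res.scores["L"], pc1)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_fit_is_deterministic(self, district_data, district_config):
        a = fit(district_data, district_config.spec)
        b = fit(district_data, district_config.spec)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.loadings, b.loadings)


class TestLocationParams:
    def test_single_indicator_bounded_block_reproduces_rescaled_indicator(self, rng):
        spec = ModelSpec(
            [LatentVariable("A", ("a",)), LatentVariable("B", ("b",))],
            [("A", "B")],
            scale_bounds={"a": (0, 100), "b": (0, 100)},
        )
        df = pd.DataFrame(rng.uniform(10, 90, size=(30, 2)), columns=["a", "b"])
        res = fit(df, spec)
        slope, intercept = res.location_params["A"]
        reconstructed = slope * res.scores["A"] + intercept
        np.testing.assert_allclose(reconstructed, df["a"], atol=1e-8)

    def test_intercept_is_mean_unstandardized_score(self, district_fit):
        from plsipa.ipma import (
            normalized_unstandardized_weights,
            rescale,
            unstandardized_scores,
        )

        rescaled = rescale(district_fit.data)
        nw = normalized_unstandardized_weights(district_fit.weights, district_fit.spec, rescaled)
        scores_u = unstandardized_scores(rescaled, nw, district_fit.spec)
        for lat, (_, intercept) in district_fit.location_params.items():
            assert intercept == pytest.approx(scores_u[lat].mean(), abs=1e-8)

    def test_dual_construction_agreement(self, district_fit):
        """Affine map of standardised scores == direct weighted rescaled sum."""
        from plsipa.ipma import (
            normalized_unstandardized_weights,
            rescale,
            unstandardized_scores,
        )

        rescaled = rescale(district_fit.data)
        nw = normalized_unstandardized_weights(district_fit.weights, district_fit.spec, rescaled)
        scores_u = unstandardized_scores(rescaled, nw, district_fit.spec)
        for lat, (slope, intercept) in district_fit.location_params.items():
            via_affine = slope * district_fit.scores[lat] + intercept
            np.testing.assert_allclose(via_affine, scores_u[lat], atol=1e-8)
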