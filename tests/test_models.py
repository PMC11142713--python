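"""The five occurrence models: closed-form oracles, brute-force equivalence,
parameter recovery, and determinism."""

import numpy as np
import pytest
from scipy.special import expit

from snakerisk.models import (
    envelope_fit,
    forest_fit,
    glm_binomial_fit,
    glm_gaussian_fit,
    load_model,
    maxent_like_fit,
    save_model,
)
from snakerisk.simulate import FieldSpec, gen_predictor_stack

from conftest import make_stack


def brute_force_envelope(train: np.ndarray, x: np.ndarray) -> float:
    """Independent oracle: literal percentile counting per layer."""
    score = 1.0
    for j in range(train.shape[1]):
        col = train[:, j]
        if col.min() == col.max():
            s = 1.0 if x[j] == col[0] else 0.0
        elif x[j] < col.min() or x[j] > col.max():
            s = 0.0
        else:
            p = sum(v <= x[j] for v in col) / len(col)
            s = 1.0 - abs(2.0 * p - 1.0)
        score = min(score, s)
    return score


class TestEnvelope:
    def test_example_values(self):
        m = envelope_fit(np.arange(1, 11, dtype=float).reshape(-1, 1), ["v"])
        assert m.predict([[2.0]])[0] == pytest.approx(0.4)  # p = 0.2
        assert m.predict([[0.5]])[0] == 0.0  # below training minimum
        assert m.predict([[11.0]])[0] == 0.0  # above training maximum

    def test_score_at_odd_n_median(self):
        # with p = #(<= x)/n the odd-n median scores 1 - 1/n (p = (n+1)/2n)
        m = envelope_fit(np.arange(1, 10, dtype=float).reshape(-1, 1), ["v"])
        assert m.predict([[5.0]])[0] == pytest.approx(1 - 1 / 9)

    def test_constant_layer_scores_1_at_common_value(self):
        m = envelope_fit(np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]]), ["c", "v"])
        assert m.predict([[3.0, 2.0]])[0] == pytest.approx(1 - abs(2 * 2 / 3 - 1))
        assert m.predict([[3.1, 2.0]])[0] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 200))
            train = rng.normal(size=(n, 3)).round(1)  # rounding forces ties
            m = envelope_fit(train, list("abc"))
            x = rng.normal(size=3).round(1)
            assert m.predict([x])[0] == pytest.approx(brute_force_envelope(train, x))

    def test_serialization_round_trip(self, tmp_path, rng):
        m = envelope_fit(rng.normal(size=(20, 2)), ["a", "b"])
        save_model(m, tmp_path / "m.json")
        m2 = load_model(tmp_path / "m.json")
        x = rng.normal(size=(5, 2))
        np.testing.assert_allclose(m2.predict(x), m.predict(x))


class TestBinomialGLM:
    def test_2x2_table_closed_form(self):
        # exposed: 8 presence / 2 background; unexposed: 3 / 7
        x = np.array([1] * 10 + [0] * 10, dtype=float).reshape(-1, 1)
        y = np.array([1] * 8 + [0] * 2 + [1] * 3 + [0] * 7, dtype=float)
        m = glm_binomial_fit(x, y)
        assert m.coef[0] == pytest.approx(np.log((8 / 2) / (3 / 7)), abs=1e-4)
        assert m.intercept == pytest.approx(np.log(3 / 7), abs=1e-4)

    def test_null_model_coefficients_near_zero(self, rng):
        n = 2000
        X = rng.normal(size=(n, 3))
        y = np.repeat([0.0, 1.0], n // 2)
        m = glm_binomial_fit(X, y)
        assert abs(m.intercept) < 3 * m.meta["intercept_se"]
        assert np.all(np.abs(m.coef) < 3 * m.se)

    def test_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < expit(0.5 + X @ [1.0, -2.0])).astype(float)
        m = glm_binomial_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose([m.intercept, *m.coef], ref.params, atol=1e-6)
        np.testing.assert_allclose(m.se, ref.bse[1:], atol=1e-5)

    def test_parameter_recovery_from_occurrence_process(self):
        # the central known-truth chain: data generated by the logistic
        # occurrence process, coefficients recovered within 3 SE
        spec = FieldSpec(shape=(71, 71), layer_names=("a", "b"), length_scale=2.0, seed=42)
        stack = gen_predictor_stack(spec)
        beta = {"a": 1.5, "b": -1.0}
        eta = -0.5 + 1.5 * stack["a"].values + (-1.0) * stack["b"].values
        rng = np.random.default_rng(43)
        y = (rng.random(stack.shape) < expit(eta)).astype(float).ravel()
        X = np.column_stack([stack["a"].values.ravel(), stack["b"].values.ravel()])
        m = glm_binomial_fit(X, y, layer_names=["a", "b"])
        for j, name in enumerate(["a", "b"]):
            assert abs(m.coef[j] - beta[name]) < 3 * m.se[j]

    def test_separation_warns(self):
        x = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (x[:, 0] > 0).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            m = glm_binomial_fit(x, y)
        assert m.meta["separation_flag"]

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError):
            glm_binomial_fit(rng.normal(size=(10, 1)), np.ones(10))


class TestGaussianGLM:
    def test_exact_fit_on_noiseless_linear_counts(self, rng):
        x = rng.normal(size=(50, 1))
        y = 4.0 + 2.5 * x[:, 0]
        m = glm_gaussian_fit(x, y)
        assert m.meta["rss"] == pytest.approx(0.0, abs=1e-18)
        assert m.intercept == pytest.approx(4.0) and m.coef[0] == pytest.approx(2.5)

    def test_slope_recovery_with_noise(self, rng):
        x = rng.normal(size=(1000, 1))
        y = 2.0 * x[:, 0] + rng.normal(0, 0.1, 1000)
        m = glm_gaussian_fit(x, y)
        assert abs(m.coef[0] - 2.0) < 3 * m.se[0]

    def test_duplicate_columns_raise_rank_error(self, rng):
        x = rng.normal(size=(30, 1))
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="collinear"):
            glm_gaussian_fit(X, rng.normal(size=30), layer_names=["p", "q"])

    def test_map_prediction_min_max_normalized(self, rng):
        vals = rng.normal(size=(6, 6))
        stack = make_stack({"a": vals})
        m = glm_gaussian_fit(vals.reshape(-1, 1), 10 + 5 * vals.ravel(), layer_names=["a"])
        g = m.predict_map(stack)
        assert g.valid_values().min() == 0.0 and g.valid_values().max() == 1.0


class TestRandomForest:
    def test_separable_feature_learned(self, rng):
        x = np.concatenate([rng.normal(-2, 0.3, 100), rng.normal(2, 0.3, 100)])
        X = np.column_stack([x, rng.normal(size=200)])
        y = np.repeat([0.0, 1.0], 100)
        # mtry=2 lets every node see the separating feature; out-of-bag points
        # would otherwise be misrouted by trees whose root drew only noise
        m = forest_fit(X, y, n_trees=25, seed=0, mtry=2)
        pred = m.predict(X)
        assert np.all(pred[y == 1] >= 0.95) and np.all(pred[y == 0] <= 0.05)

    def test_same_seed_bit_identical(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + rng.normal(0, 1, 80) > 0).astype(float)
        m1 = forest_fit(X, y, n_trees=10, seed=5)
        m2 = forest_fit(X, y, n_trees=10, seed=5)
        assert m1.to_dict() == m2.to_dict()
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_single_tree_no_bootstrap_hand_traceable(self):
        # two points, one feature: split at the midpoint 0.5, perfect fit
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0])
        m = forest_fit(X, y, n_trees=1, seed=0, bootstrap=False, mtry=2)
        tree = m.trees[0]
        assert tree["feature"][0] in (0, 1) and tree["threshold"][0] == 0.5
        np.testing.assert_array_equal(m.predict(X), [0.0, 1.0])

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(float)
        m = forest_fit(X, y, n_trees=5, seed=3)
        save_model(m, tmp_path / "rf.json")
        np.testing.assert_array_equal(load_model(tmp_path / "rf.json").predict(X), m.predict(X))


class TestMaxentLike:
    @pytest.fixture
    def pb(self, rng):
        P = rng.normal(1.0, 1.0, size=(150, 2))
        B = rng.normal(0.0, 1.0, size=(200, 2))
        return P, B

    def test_zero_penalty_reduces_to_glm(self, pb):
        P, B = pb
        m = maxent_like_fit(P, B, penalty=0.0)
        X = np.concatenate([P, B])
        y = np.concatenate([np.ones(len(P)), np.zeros(len(B))])
        g = glm_binomial_fit(X, y)
        np.testing.assert_allclose([m.intercept, *m.coef], [g.intercept, *g.coef], atol=1e-6)

    def test_huge_penalty_shrinks_slopes_to_presence_fraction(self, pb):
        P, B = pb
        m = maxent_like_fit(P, B, penalty=1e6)
        assert np.all(np.abs(m.coef) < 1e-3)
        frac = len(P) / (len(P) + len(B))
        assert m.predict(np.zeros((1, 2)))[0] == pytest.approx(frac, abs=0.01)

    def test_penalty_monotonically_shrinks_slope_norm(self, pb):
        P, B = pb
        norms = [np.linalg.norm(maxent_like_fit(P, B, penalty=lam).coef)
                 for lam in (0.0, 0.1, 1.0, 10.0)]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_negative_penalty_rejected(self, pb):
        with pytest.raises(ValueError):
            maxent_like_fit(*pb, penalty=-1.0)


def test_common_map_contract(rng):
    """fit -> predict_map yields [0,1] values with nodata where any predictor
    is masked, for every model kind."""
    mask = np.zeros((12, 12), bool)
    mask[0, :3] = True
    a = np.where(mask, np.nan, rng.normal(size=(12, 12)))
    b = rng.normal(size=(12, 12))
    from snakerisk.raster import RasterGrid
    from snakerisk.stack import PredictorStack

    stack = PredictorStack({
        "a": RasterGrid(a, mask, 0.0, 12.0, 1.0),
        "b": RasterGrid(b, np.zeros((12, 12), bool), 0.0, 12.0, 1.0),
    })
    X, _ = stack.valid_matrix()
    y = (X[:, 0] + rng.normal(0, 0.5, len(X)) > 0).astype(float)
    models = [
        envelope_fit(X[y == 1], stack.names),
        glm_binomial_fit(X, y, layer_names=stack.names),
        glm_gaussian_fit(X, y, layer_names=stack.names),
        forest_fit(X, y, n_trees=5, seed=1, layer_names=stack.names),
        maxent_like_fit(X[y == 1], X[y == 0], layer_names=stack.names),
    ]
    for m in models:
        g = m.predict_map(stack)
        assert np.array_equal(g.mask, mask)
        v = g.valid_values()
        assert v.min() >= 0.0 and v.max() <= 1.0
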