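import itertools
import math

import numpy as np
import pytest

from dualniche.shapley import (ShapMatrix, ensemble_shap, exact_shapley,
                               export_decision_and_dependence, global_importance,
                               shap_matrix)


def permutation_shapley(predict, background, x):
    """Independent oracle: average marginal contribution over all |F|!
    feature orderings, with the same interventional value function."""
    x = np.asarray(x, float)
    background = np.atleast_2d(np.asarray(background, float))
    n = x.size

    def v(S):
        hybrid = background.copy()
        for i in S:
            hybrid[:, i] = x[i]
        return float(np.mean(predict(hybrid)))

    phi = np.zeros(n)
    for order in itertools.permutations(range(n)):
        S = []
        prev = v(S)
        for i in order:
            S.append(i)
            cur = v(S)
            phi[i] += cur - prev
            prev = cur
    return phi / math.factorial(n)


class TestExactShapley:
    def test_single_feature_is_full_contribution(self):
        predict = lambda X: 2 * X[:, 0] + 1
        bg = np.array([[0.0], [2.0]])
        phi, base = exact_shapley(predict, bg, np.array([3.0]))
        assert base == pytest.approx(3.0)  # mean of 1, 5
        assert phi[0] == pytest.approx(predict(np.array([[3.0]]))[0] - base)

    def test_ignored_feature_gets_exact_zero(self):
        predict = lambda X: X[:, 0] ** 2
        bg = np.random.default_rng(0).normal(size=(20, 3))
        phi, _ = exact_shapley(predict, bg, np.array([1.0, 5.0, -2.0]))
        assert phi[1] == 0.0 and phi[2] == 0.0

    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(1)
        b = np.array([1.5, -2.0, 0.7, 3.0])
        predict = lambda X: 0.5 + X @ b
        bg = rng.normal(size=(50, 4))
        x = rng.normal(size=4)
        phi, base = exact_shapley(predict, bg, x)
        assert np.allclose(phi, b * (x - bg.mean(axis=0)), atol=1e-10)
        assert base == pytest.approx(0.5 + bg.mean(axis=0) @ b)

    def test_matches_permutation_oracle_on_nonlinear_model(self):
        rng = np.random.default_rng(2)
        predict = lambda X: np.tanh(X[:, 0] * X[:, 1]) + 0.3 * X[:, 2] ** 2 \
            - 0.5 * np.abs(X[:, 3] - X[:, 4])
        bg = rng.normal(size=(12, 5))
        for _ in range(3):
            x = rng.normal(size=5)
            phi, base = exact_shapley(predict, bg, x)
            phi_perm = permutation_shapley(predict, bg, x)
            assert np.allclose(phi, phi_perm, atol=1e-10)
            assert base + phi.sum() == pytest.approx(float(predict(x[None])[0]),
                                                     abs=1e-10)

    def test_symmetry_of_interchangeable_features(self):
        predict = lambda X: X[:, 0] * X[:, 1]
        bg = np.zeros((5, 2))
        phi, _ = exact_shapley(predict, bg, np.array([2.0, 2.0]))
        assert phi[0] == pytest.approx(phi[1])

    def test_feature_bound_enforced(self):
        with pytest.raises(ValueError):
            exact_shapley(lambda X: X[:, 0], np.zeros((2, 16)), np.zeros(16))


class TestEnsembleShap:
    def _matrix(self, vals, base=0.1):
        return ShapMatrix(vals, base, [f"f{i}" for i in range(vals.shape[1])])

    def test_identical_matrices_pass_through(self):
        m = self._matrix(np.arange(6.0).reshape(2, 3))
        out = ensemble_shap([m, m, m, m])
        assert np.array_equal(out.values, m.values)
        assert out.base_value == m.base_value

    def test_averaging_is_linear(self):
        m = self._matrix(np.arange(6.0).reshape(2, 3), base=0.5)
        neg = self._matrix(-np.arange(6.0).reshape(2, 3), base=-0.5)
        out = ensemble_shap([m, neg, m, neg])
        assert np.allclose(out.values, 0.0) and out.base_value == 0.0

    def test_efficiency_against_mean_of_member_predictions(self):
        """Averaged matrix reproduces the mean of member predictions."""
        rng = np.random.default_rng(3)
        bg = rng.normal(size=(15, 3))
        X = rng.normal(size=(4, 3))
        members = [
            lambda Z: np.tanh(Z[:, 0]) + Z[:, 1],
            lambda Z: Z[:, 0] * Z[:, 2],
            lambda Z: np.abs(Z[:, 1]),
            lambda Z: Z @ np.array([1.0, -1.0, 0.5]),
        ]
        mats = [shap_matrix(f, X, bg, ["a", "b", "c"]) for f in members]
        ens = ensemble_shap(mats)
        mean_pred = np.mean([f(X) for f in members], axis=0)
        assert np.allclose(ens.predictions(), mean_pred, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        a = self._matrix(np.zeros((2, 3)))
        b = self._matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ensemble_shap([a, b])


class TestGlobalImportanceAndExports:
    def test_dummy_feature_ranks_last_with_zero(self):
        vals = np.array([[1.0, 0.0, -2.0], [0.5, 0.0, 1.0]])
        ranking = global_importance(ShapMatrix(vals, 0.0, ["a", "dummy", "c"]))
        assert ranking[-1] == ("dummy", 0.0)

    def test_scaling_doubles_score(self):
        vals = np.array([[1.0, 2.0], [3.0, -1.0]])
        r1 = dict(global_importance(ShapMatrix(vals, 0.0, ["a", "b"])))
        vals2 = vals.copy()
        vals2[:, 0] *= 2
        r2 = dict(global_importance(ShapMatrix(vals2, 0.0, ["a", "b"])))
        assert r2["a"] == pytest.approx(2 * r1["a"])

    def test_dominant_truth_driver_ranks_first(self):
        """The generator's dominant climate coefficient should top the
        Shapley importance ranking in most seeds."""
        from sklearn.ensemble import RandomForestClassifier
        from dualniche.geodata import extract_env, thin_occurrences
        from dualniche.synthland import (LandscapeConfig, generate_landscape,
                                         sample_occurrences)
        wins = 0
        for seed in range(5):
            cfg = LandscapeConfig(n_rows=40, n_cols=40, seed=seed)
            stack, truth = generate_landscape(cfg)
            pts = sample_occurrences(truth.climate_truth_host, 150, seed + 30)
            pres = thin_occurrences(pts, stack.geometry, seed)
            names = [f"clim{i}" for i in range(1, 5)]
            table, _ = extract_env(pres, stack.subset(names))
            # contrast with uniform background cells
            rng = np.random.default_rng(seed + 60)
            rows = rng.integers(0, 40, 150)
            cols = rng.integers(0, 40, 150)
            Xb = np.column_stack([stack[n].values[rows, cols] for n in names])
            X = np.vstack([table[names].to_numpy(float), Xb])
            y = np.r_[np.ones(len(table)), np.zeros(len(Xb))]
            model = RandomForestClassifier(n_estimators=100, random_state=seed).fit(X, y)
            predict = lambda Z: model.predict_proba(Z)[:, 1]
            mat = shap_matrix(predict, X[:12], Xb[:40], names)
            wins += global_importance(mat)[0][0] == "clim1"
        assert wins >= 4

    def test_decision_export_recomputed_paths(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(10, 3))
        X = rng.normal(size=(3, 3))
        predict = lambda Z: Z @ np.array([1.0, 2.0, -1.0])
        mat = shap_matrix(predict, X, bg, ["a", "b", "c"])
        decision, dependence = export_decision_and_dependence(mat, X)
        # last cumulative value equals the prediction (efficiency)
        last = decision.groupby("sample")["cumulative"].last()
        assert np.allclose(last.to_numpy(), predict(X), atol=1e-8)
        # recompute one path independently
        order = [n for n, _ in reversed(global_importance(mat))]
        cum = mat.base_value
        for name in order:
            j = mat.feature_names.index(name)
            cum += mat.values[0, j]
            row = decision[(decision["sample"] == 0) & (decision.feature == name)]
            assert row["cumulative"].iloc[0] == pytest.approx(cum)
        assert len(dependence) == 9  # 3 samples x 3 features

    def test_single_sample_single_path(self):
        mat = ShapMatrix(np.array([[0.2, -0.1]]), 0.5, ["a", "b"])
        decision, _ = export_decision_and_dependence(mat, np.array([[1.0, 2.0]]))
        assert decision["sample"].nunique() == 1
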