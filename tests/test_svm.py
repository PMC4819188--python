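"""Cross-validated decision values, Platt calibration, model round-trip."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from bitterx.svm import (
    SVMConfig,
    cv_decision_values,
    fit_platt,
    load_model,
    platt_probability,
    save_model,
    train_final_model,
    PlattParams,
)


def _blobs(n=100, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.standard_normal((n // 2, 2)) + sep / 2,
        rng.standard_normal((n // 2, 2)) - sep / 2,
    ])
    y = np.concatenate([np.ones(n // 2, dtype=int), -np.ones(n // 2, dtype=int)])
    return X, y


class TestCVDecisionValues:
    def test_separable_blobs_sign_match(self):
        X, y = _blobs()
        g = cv_decision_values(X, y, SVMConfig(C=1.0, gamma=0.5, seed=0))
        assert g.size == y.size
        assert np.all(np.sign(g) == y)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 5))
        y = np.array([1, -1] * 100)
        g = cv_decision_values(X, y, SVMConfig(C=1.0, gamma=0.2, seed=0))
        acc = (np.sign(g) == y).mean()
        assert abs(acc - 0.5) < 0.12

    def test_out_of_fold_bookkeeping(self):
        # the decision value of each sample comes from a fold that excluded
        # it: recompute fold-by-fold and compare
        X, y = _blobs(n=60, seed=2)
        cfg = SVMConfig(C=2.0, gamma=0.3, cv_folds=4, seed=7)
        g = cv_decision_values(X, y, cfg)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=7)
        from sklearn.svm import SVC

        seen = np.zeros(y.size, dtype=int)
        for tr, te in skf.split(X, y):
            clf = SVC(C=2.0, gamma=0.3).fit(X[tr], y[tr])
            np.testing.assert_allclose(g[te], clf.decision_function(X[te]))
            seen[te] += 1
        assert np.all(seen == 1)

    def test_single_class_fold_errors(self):
        X = np.random.default_rng(0).standard_normal((6, 2))
        y = np.array([1, 1, 1, 1, 1, -1])
        with pytest.raises(ValueError):
            cv_decision_values(X, y, SVMConfig(C=1, gamma=1, cv_folds=5))


class TestPlatt:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        g = rng.normal(0.0, 1.0, 5000)
        p_true = 1.0 / (1.0 + np.exp(-2.0 * g))
        y = np.where(rng.random(5000) < p_true, 1, -1)
        params = fit_platt(g, y)
        assert params.A == pytest.approx(-2.0, abs=0.15)
        assert params.B == pytest.approx(0.0, abs=0.15)

    def test_no_signal_gives_half(self):
        rng = np.random.default_rng(3)
        g = rng.normal(0, 1, 2000)
        y = np.array([1, -1] * 1000)
        params = fit_platt(g, y)
        assert abs(params.B) < 0.1
        assert platt_probability(0.0, params) == pytest.approx(0.5, abs=0.03)

    def test_separable_margin_steep_and_monotone(self):
        g = np.concatenate([np.linspace(1, 3, 50), np.linspace(-3, -1, 50)])
        y = np.concatenate([np.ones(50, dtype=int), -np.ones(50, dtype=int)])
        params = fit_platt(g, y)
        assert abs(params.A) > 1.0
        xs = np.linspace(-5, 5, 101)
        probs = platt_probability(xs, params)
        assert np.all(np.diff(probs) > 0) or np.all(np.diff(probs) < 0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_platt(np.array([1.0, 2.0]), np.array([1, 1]))

    @pytest.mark.parametrize(
        "A,B,g,expected",
        [
            (0.0, 0.0, 5.0, 0.5),
            (-2.0, 0.0, 1.0, 1.0 / (1.0 + np.exp(-2.0))),
            (-1.0, 0.0, 1e4, 1.0),
            (1.0, 0.0, 1e4, 0.0),
        ],
    )
    def test_probability_values_overflow_safe(self, A, B, g, expected):
        assert platt_probability(g, PlattParams(A=A, B=B)) == pytest.approx(
            expected, abs=1e-9
        )


class TestTrainedModel:
    def test_round_trip_bit_stable(self, tmp_path):
        X, y = _blobs(n=80, sep=3.0, seed=1)
        names = ["x1", "x2"]
        model = train_final_model(X, y, SVMConfig(C=4.0, gamma=0.5, seed=0), names)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        p1 = model.predict_probability(X)
        p2 = loaded.predict_probability(X)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert loaded.feature_names == names

    def test_probabilities_in_open_interval(self):
        X, y = _blobs(n=60, seed=4)
        model = train_final_model(X, y, SVMConfig(C=1.0, gamma=0.5, seed=0), ["a", "b"])
        p = model.predict_probability(X)
        assert np.all((p > 0) & (p < 1))

    def test_feature_count_checked(self):
        X, y = _blobs(n=40, seed=6)
        model = train_final_model(X, y, SVMConfig(C=1.0, gamma=0.5, seed=0), ["a", "b"])
        with pytest.raises(ValueError):
            model.decision_values(np.zeros((3, 5)))

    def test_decision_matches_sklearn(self):
        # the explicit support-vector expansion reproduces sklearn's own
        # decision function on the scaled inputs
        from sklearn.svm import SVC

        X, y = _blobs(n=80, sep=2.0, seed=9)
        model = train_final_model(X, y, SVMConfig(C=2.0, gamma=0.25, seed=0), ["a", "b"])
        Xs = (X - model.scale_min) / model.scale_range
        clf = SVC(C=2.0, gamma=0.25).fit(Xs, y)
        np.testing.assert_allclose(
            model.decision_values(X), clf.decision_function(Xs), atol=1e-9
        )
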