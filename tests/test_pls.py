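"""Orthogonal-scores PLSR: oracle equivalence, component selection,
jackknife intervals and the evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ricehsi import pls

from oracles import nipals_pls1_literal


def linear_problem(n=30, p=20, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:3] = [1.0, -2.0, 0.5]
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


class TestFit:
    def test_single_predictor_single_component_is_ols_line(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(25, 1))
        y = 2.0 + 3.0 * x[:, 0] + rng.normal(0, 0.2, 25)
        m = pls.fit_plsr(x, y, 1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        assert m.coef_[0] == pytest.approx(slope, abs=1e-10)
        assert m.intercept_ == pytest.approx(intercept, abs=1e-10)

    def test_full_components_equal_ols(self):
        X, y = linear_problem()
        m = pls.fit_plsr(X, y, 20)
        A = np.c_[np.ones(len(y)), X]
        fitted = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(m.predict(X), fitted, atol=1e-8)

    @pytest.mark.parametrize("shape,ncomp", [((8, 5), 3), ((30, 20), 5)])
    def test_matches_literal_nipals_transcription(self, shape, ncomp):
        rng = np.random.default_rng(2)
        X = rng.normal(size=shape)
        y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.1, shape[0])
        coef, intercept = nipals_pls1_literal(X, y, ncomp)
        m = pls.fit_plsr(X, y, ncomp)
        assert np.allclose(m.coef_, coef, atol=1e-8)
        assert m.intercept_ == pytest.approx(intercept, abs=1e-8)

    def test_matches_reference_library(self):
        # independent cross-check against sklearn's NIPALS implementation
        from sklearn.cross_decomposition import PLSRegression
        X, y = linear_problem(seed=3)
        m = pls.fit_plsr(X, y, 5)
        sk = PLSRegression(n_components=5, scale=False).fit(X, y.reshape(-1, 1))
        assert np.allclose(m.coef_, sk.coef_.ravel(), atol=1e-8)

    def test_scores_mutually_orthogonal(self):
        X, y = linear_problem(seed=4)
        m = pls.fit_plsr(X, y, 8)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_coefficient_path_consistent_with_single_fits(self):
        X, y = linear_problem(seed=5)
        coefs, intercepts = pls.coefficient_path(X, y, 6)
        for a in (1, 3, 6):
            m = pls.fit_plsr(X, y, a)
            assert np.allclose(coefs[:, a - 1], m.coef_, atol=1e-10)

    def test_invalid_inputs_rejected(self):
        X, y = linear_problem()
        with pytest.raises(ValueError):
            pls.fit_plsr(X, y, 0)
        with pytest.raises(ValueError):
            pls.fit_plsr(X, y, 21)  # > min(n-1, p)
        with pytest.raises(ValueError):
            pls.fit_plsr(X, np.ones(len(y)), 1)


class TestComponentSelection:
    def test_noiseless_single_latent_selects_one(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=20)
        X = np.outer(t, rng.normal(size=6))  # one latent direction, no noise
        y = 3.0 * t
        assert pls.select_components_loo(X, y) == 1
        assert pls.select_components_loo(X, y, max_components=1) == 1

    def test_pure_noise_yields_zero_components(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(30, 40))
            y = rng.normal(size=30)   # independent of X
            hits += pls.select_components_loo(X, y) == 0
        assert hits >= 6  # 0-component optimum in the majority of seeds

    def test_exactly_linear_fixture(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 4))
        y = X[:, 0] * 3.0
        assert pls.select_components_loo(X, y, max_components=1) == 1


class TestJackknife:
    def test_noiseless_linear_data_gives_degenerate_intervals(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, -1.0, 2.0]) + 5.0
        Xv = rng.normal(size=(5, 3))
        pred, lo, hi = pls.jackknife_predict(X, y, 3, Xv)
        assert np.max(hi - lo) < 1e-6
        assert np.allclose(pred, Xv @ np.array([1.0, -1.0, 2.0]) + 5.0, atol=1e-8)

    def test_duplicating_calibration_shrinks_intervals(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 4))
        y = X[:, 0] + rng.normal(0, 0.3, 15)
        Xv = rng.normal(size=(6, 4))
        _, lo1, hi1 = pls.jackknife_predict(X, y, 2, Xv)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        _, lo2, hi2 = pls.jackknife_predict(X2, y2, 2, Xv)
        assert (hi2 - lo2).mean() < (hi1 - lo1).mean()

    def test_coverage_near_nominal(self):
        # repeated small simulations; binomial error around 95%
        rng = np.random.default_rng(10)
        covered = total = 0
        for _ in range(200):
            X = rng.normal(size=(25, 4))
            beta = rng.normal(size=4)
            y = X @ beta + rng.normal(0, 0.5, 25)
            Xv = rng.normal(size=(4, 4))
            truth = Xv @ beta
            _, lo, hi = pls.jackknife_predict(X, y, 4, Xv)
            covered += int(((truth >= lo) & (truth <= hi)).sum())
            total += len(truth)
        assert 0.90 <= covered / total <= 0.99


class TestEvaluate:
    def test_perfect_prediction(self):
        m = pls.evaluate(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert m.rmsep == 0.0 and m.r2 == 1.0 and m.pct_rmsep == 0.0

    def test_hand_computed_case(self):
        m = pls.evaluate(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert m.rmsep == pytest.approx(1.0)
        assert m.r2 == pytest.approx(0.0)
        assert m.pct_rmsep == pytest.approx(50.0)

    def test_mean_predictor_scores_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = pls.evaluate(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_constant_truth_flagged_undefined(self):
        m = pls.evaluate(np.ones(3), np.array([1.0, 1.1, 0.9]))
        assert np.isnan(m.r2) and np.isnan(m.pct_rmsep)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.01, 1e3))
    def test_scale_behaviour(self, c):
        y = np.array([1.0, 2.0, 4.0, 7.0])
        yh = np.array([1.5, 2.5, 3.0, 6.0])
        base = pls.evaluate(y, yh)
        scaled = pls.evaluate(c * y, c * yh)
        assert scaled.r2 == pytest.approx(base.r2, rel=1e-9)
        assert scaled.pct_rmsep == pytest.approx(base.pct_rmsep, rel=1e-9)
        assert scaled.rmsep == pytest.approx(c * base.rmsep, rel=1e-9)
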