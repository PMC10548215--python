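"""Wavelength selection: covariance PCA / loading pooling and RReliefF."""

import numpy as np
import pandas as pd
import pytest

import ricehsi as rh
from ricehsi.reflectance import SpectraSet
from ricehsi.synth import make_planted_band_data
from ricehsi.wavesel import (SelectionResult, rrelieff_rank, select_wplsr,
                             select_wsvm, spectra_pca, SpectraPCAResult)

from oracles import rrelieff_literal


def spectra(values, wavelengths=None):
    values = np.asarray(values, dtype=float)
    wl = wavelengths if wavelengths is not None else np.arange(values.shape[1], dtype=float)
    meta = pd.DataFrame({"plant_id": [f"p{i}" for i in range(len(values))],
                         "week": 6})
    return SpectraSet(wl, values, meta)


class TestSpectraPCA:
    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=8)
        X = np.outer(rng.normal(size=10), direction) + 5.0
        pca = spectra_pca(spectra(X))
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        pca = spectra_pca(spectra(rng.normal(size=(12, 9))))
        L = pca.loadings
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            spectra_pca(spectra([[1.0, 2.0, 3.0]]))

    def test_a_leading_pc_separates_treatments(self, weekly_spectra,
                                               default_experiment):
        _, _, _, design = default_experiment
        means = rh.accession_mean(weekly_spectra, design)
        wk = means.select_week(6)
        pca = spectra_pca(wk)
        trt = wk.meta["treatment"].to_numpy()
        separations = []
        for j in range(3):
            s = pca.scores[:, j]
            gap = abs(s[trt == "N1"].mean() - s[trt == "N2"].mean())
            pooled = np.sqrt(0.5 * (s[trt == "N1"].var() + s[trt == "N2"].var()))
            separations.append(gap / pooled)
        assert max(separations) > 2.0


class TestSelectWsvm:
    def test_single_dominant_pc_takes_its_top_ten(self):
        rng = np.random.default_rng(3)
        direction = np.zeros(30)
        direction[[2, 5, 7, 11, 13, 17, 19, 23, 25, 29]] = rng.normal(2, 0.5, 10)
        X = np.outer(rng.normal(size=20), direction)
        X += rng.normal(0, 1e-4, size=X.shape)   # PC1 fraction ~ 1
        pca = spectra_pca(spectra(X))
        sel = select_wsvm(pca)
        assert pca.explained_variance_ratio[0] > 0.95
        top10 = set(np.argsort(-np.abs(pca.loadings[:, 0]))[:10].astype(float))
        assert set(sel.selected) == top10

    def test_union_bound(self, weekly_spectra, default_experiment):
        _, _, _, design = default_experiment
        means = rh.accession_mean(weekly_spectra, design)
        pca = spectra_pca(means.select_week(6))
        sel = select_wsvm(pca)
        assert len(sel.selected) <= 10 * sel.provenance["n_components"]

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(4)
        pca = spectra_pca(spectra(rng.normal(size=(15, 12))))
        flipped = SpectraPCAResult(
            wavelengths=pca.wavelengths, scores=-pca.scores,
            loadings=-pca.loadings,
            explained_variance_ratio=pca.explained_variance_ratio,
            mean=pca.mean)
        assert np.array_equal(select_wsvm(pca).selected,
                              select_wsvm(flipped).selected)

    def test_red_edge_wavelengths_selected(self, weekly_spectra,
                                           default_experiment):
        _, _, _, design = default_experiment
        means = rh.accession_mean(weekly_spectra, design)
        sel = select_wsvm(spectra_pca(means.select_week(6)))
        assert np.any((sel.selected >= 700) & (sel.selected <= 730))


class TestRReliefF:
    def test_constant_attribute_scores_zero(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(30, 4))
        X[:, 2] = 0.7
        y = X[:, 0] + rng.normal(0, 0.05, 30)
        res = rrelieff_rank(X, y, k_neighbors=10, m_iterations=500, seed=0)
        assert res.scores[2] == 0.0

    def test_duplicated_informative_columns_weigh_equally(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(40, 5))
        X[:, 4] = X[:, 1]
        y = X[:, 1] + rng.normal(0, 0.05, 40)
        res = rrelieff_rank(X, y, k_neighbors=10, m_iterations=800, seed=1)
        assert res.scores[1] == pytest.approx(res.scores[4], abs=1e-12)

    def test_dominant_column_ranked_first(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(60, 30))
        y = X[:, 7] + rng.normal(0, 0.05, 60)
        res = rrelieff_rank(X, y, seed=2)  # m = 100n default
        assert int(np.argmax(res.scores)) == 7

    def test_matches_literal_transcription(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(25, 8))
        y = X[:, 3] + 0.5 * X[:, 5] + rng.normal(0, 0.05, 25)
        k, sigma, m = 7, 20.0, 300
        expected = rrelieff_literal(X, y, k, sigma, m, np.random.default_rng(42))
        got = rrelieff_rank(X, y, k_neighbors=k, sigma=sigma, m_iterations=m,
                            seed=np.random.default_rng(42))
        assert np.allclose(got.scores, expected, atol=1e-9)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(9).uniform(size=(10, 3))
        with pytest.raises(ValueError):
            rrelieff_rank(X, np.ones(10), k_neighbors=3, m_iterations=10)

    def test_planted_bands_recovered_across_seeds(self):
        # m = 100 x n rule; 10 informative bands among 600
        passed = 0
        for s in range(20):
            X, y, planted = make_planted_band_data(n=70, n_bands=600, seed=s)
            res = rrelieff_rank(X, y, seed=s)
            top40 = np.argsort(-res.scores)[:40]
            passed += np.isin(planted, top40).sum() >= 8
        assert passed >= 18  # >= 90% of seeds


class TestSelectWplsr:
    def scores(self):
        return SelectionResult("rrelieff", np.array([400.0, 500.0, 600.0]),
                               np.array([0.5, 0.5, 0.1]), np.array([]))

    def test_all_and_argmax(self):
        s = self.scores()
        assert np.array_equal(select_wplsr(s, 3).selected, [400.0, 500.0, 600.0])
        assert np.array_equal(select_wplsr(s, 1).selected, [400.0])  # tie -> lower nm

    def test_result_in_wavelength_order(self):
        s = SelectionResult("rrelieff", np.array([400.0, 500.0, 600.0]),
                            np.array([0.1, 0.9, 0.5]), np.array([]))
        assert np.array_equal(select_wplsr(s, 2).selected, [500.0, 600.0])

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            select_wplsr(self.scores(), 0)
        with pytest.raises(ValueError):
            select_wplsr(self.scores(), 4)
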