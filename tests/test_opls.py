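"""OPLS-DA core: NIPALS algebra, orthogonal filtering, Q2 selection, VIP."""

import numpy as np
import pytest

from metabodx import (CohortConfig, NoSignalError, ValidationError,
                      assemble_bucket_table, apply_pareto, fit_pareto,
                      fit_opls, predict_scores, q2_internal_cv,
                      reference_to_lactate, select_n_orthogonal,
                      simulate_cohort, vip)
from metabodx.opls import OplsModel, q2_from_predictions


def _centered(rng, n, j):
    X = rng.normal(size=(n, j))
    return X - X.mean(axis=0)


def _balanced_y(n):
    return np.r_[np.ones(n // 2), -np.ones(n // 2)]


class TestFit:
    def test_weight_is_normalized_xty(self):
        rng = np.random.default_rng(0)
        X = _centered(rng, 30, 8)
        y = _balanced_y(30)
        model = fit_opls(X, y, n_ortho=0)
        expected = X.T @ y
        expected /= np.linalg.norm(expected)
        assert np.allclose(model.w, expected, atol=1e-12)
        assert np.linalg.norm(model.w) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_component_removes_structured_noise(self):
        """Structured variation orthogonal to y is absorbed by the
        orthogonal component, leaving the predictive scores of the clean
        model."""
        rng = np.random.default_rng(1)
        n, J = 40, 6
        y = _balanced_y(n)
        t_o = rng.normal(size=n)
        t_o -= t_o @ y / (y @ y) * y          # exactly orthogonal to y
        e1 = np.eye(J)[0]
        e2 = np.eye(J)[1]
        p_o = (e1 + e2) / np.sqrt(2)
        X_clean = np.outer(y, e1)
        X = X_clean + np.outer(t_o, p_o)
        clean = fit_opls(X_clean, y, n_ortho=0)
        noisy = fit_opls(X, y, n_ortho=1)
        assert np.allclose(predict_scores(noisy, X),
                           predict_scores(clean, X_clean), atol=1e-6)

    def test_separable_clusters_classified_at_zero(self):
        rng = np.random.default_rng(2)
        n = 20
        y = _balanced_y(n)
        X = rng.normal(scale=0.1, size=(n, 5))
        X[:, 0] += 2.0 * y
        X -= X.mean(axis=0)
        model = fit_opls(X, y, n_ortho=0)
        assert np.all(np.sign(model.fitted_scores) == y)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValidationError):
            fit_opls(X, np.ones(10), 0)

    def test_no_signal_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(NoSignalError):
            fit_opls(X, _balanced_y(10), 0)

    def test_zero_one_labels_accepted(self):
        rng = np.random.default_rng(3)
        X = _centered(rng, 20, 5)
        y01 = (_balanced_y(20) > 0).astype(int)
        a = fit_opls(X, y01, 0)
        b = fit_opls(X, _balanced_y(20), 0)
        assert np.allclose(a.w, b.w)


class TestPredict:
    def test_training_matrix_reproduces_fitted_scores(self):
        rng = np.random.default_rng(4)
        X = _centered(rng, 25, 10)
        y = np.r_[np.ones(5), -np.ones(20)]
        model = fit_opls(X, y, n_ortho=2)
        assert np.allclose(predict_scores(model, X), model.fitted_scores,
                           atol=1e-10)

    def test_duplicated_row_duplicated_score(self):
        rng = np.random.default_rng(5)
        X = _centered(rng, 20, 6)
        model = fit_opls(X, _balanced_y(20), 1)
        row = X[3]
        s = predict_scores(model, np.vstack([row, row]))
        assert s[0] == s[1]

    def test_zero_row_scores_zero(self):
        rng = np.random.default_rng(6)
        X = _centered(rng, 20, 6)
        model = fit_opls(X, _balanced_y(20), 2)
        assert predict_scores(model, np.zeros((1, 6)))[0] == pytest.approx(0.0,
                                                                           abs=1e-12)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        X = _centered(rng, 20, 6)
        model = fit_opls(X, _balanced_y(20), 0)
        with pytest.raises(ValidationError):
            predict_scores(model, np.zeros((2, 5)))


class TestQ2:
    def test_perfect_prediction_scores_one(self):
        y = _balanced_y(10)
        assert q2_from_predictions(y, y) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        y = np.r_[np.ones(3), -np.ones(7)]
        assert q2_from_predictions(y, np.full(10, y.mean())) == pytest.approx(0.0)

    def test_permuted_labels_mean_q2_nonpositive(self):
        q2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _centered(rng, 40, 20)
            y = rng.permutation(_balanced_y(40))
            q2s.append(q2_internal_cv(X, y, n_ortho=0, k=7, seed=seed))
        assert np.mean(q2s) <= 0.0

    def test_matches_selection_path(self):
        rng = np.random.default_rng(8)
        X = _centered(rng, 30, 12)
        y = _balanced_y(30)
        X[:, 0] += y
        _, q2s = select_n_orthogonal(X, y, max_ortho=4, k=7, seed=123)
        for c in range(5):
            assert q2_internal_cv(X, y, c, k=7, seed=123) == pytest.approx(
                q2s[c], abs=1e-12)


class TestSelection:
    def test_candidate_list_covers_zero_to_nine(self):
        rng = np.random.default_rng(9)
        X = _centered(rng, 40, 15)
        y = _balanced_y(40)
        X[:, 0] += y
        _, q2s = select_n_orthogonal(X, y, max_ortho=9, k=7, seed=0)
        assert q2s.size == 10

    def test_pure_predictive_structure_selects_none(self):
        chosen = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            y = _balanced_y(n)
            X = rng.normal(scale=0.3, size=(n, 10))
            X[:, 0] += 2.0 * y
            X -= X.mean(axis=0)
            n_o, _ = select_n_orthogonal(X, y, max_ortho=3, k=7, seed=seed)
            chosen.append(n_o)
        assert np.sum(np.asarray(chosen) == 0) > 10

    def test_orthogonal_confound_selects_at_least_one(self):
        chosen = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, J = 40, 10
            y = _balanced_y(n)
            t_o = rng.normal(size=n)
            t_o -= t_o @ y / (y @ y) * y
            p_o = np.zeros(J)
            p_o[0], p_o[1] = 1.0, 1.0
            X = rng.normal(scale=0.2, size=(n, J))
            X[:, 0] += y
            X += 5.0 * np.outer(t_o, p_o / np.linalg.norm(p_o))
            X -= X.mean(axis=0)
            n_o, _ = select_n_orthogonal(X, y, max_ortho=3, k=7, seed=seed)
            chosen.append(n_o)
        assert np.sum(np.asarray(chosen) >= 1) > 10


class TestVip:
    def _model_with_w(self, w):
        w = np.asarray(w, dtype=float)
        return OplsModel(w=w, p=w.copy(), t=np.zeros(2), b=1.0,
                         W_o=np.zeros((0, w.size)), P_o=np.zeros((0, w.size)),
                         T_o=np.zeros((0, 2)), n_ortho=0, y_mean=0.0, r2y=1.0)

    def test_single_loaded_bucket(self):
        v = vip(self._model_with_w([1.0, 0.0, 0.0, 0.0]))
        assert np.allclose(v.scores, [2.0, 0.0, 0.0, 0.0])
        assert list(v.significant) == []  # VIP 2 is not > 2

    def test_uniform_weights_give_unit_vip(self):
        J = 16
        v = vip(self._model_with_w(np.full(J, 1.0 / np.sqrt(J))))
        assert np.allclose(v.scores, 1.0)
        assert v.significant.size == 0

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(10)
        X = _centered(rng, 30, 40)
        model = fit_opls(X, _balanced_y(30), 2)
        v = vip(model)
        assert np.mean(v.scores ** 2) == pytest.approx(1.0, abs=1e-8)
        assert np.all(v.scores >= 0)


class TestInvariants:
    def test_predictive_and_orthogonal_scores_uncorrelated(self):
        rng = np.random.default_rng(11)
        X = _centered(rng, 50, 30)
        y = _balanced_y(50)
        X[:, 0] += y
        model = fit_opls(X, y, n_ortho=3)
        for t_o in model.T_o:
            if np.linalg.norm(t_o) == 0:
                continue
            corr = np.corrcoef(model.t, t_o)[0, 1]
            assert abs(corr) < 1e-6
        for w_o in model.W_o:
            assert abs(model.w @ w_o) < 1e-8

    def test_bucket_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        X = _centered(rng, 30, 12)
        y = _balanced_y(30)
        perm = rng.permutation(12)
        a = fit_opls(X, y, 2)
        b = fit_opls(X[:, perm], y, 2)
        assert np.allclose(b.w, a.w[perm], atol=1e-12)
        assert np.allclose(predict_scores(b, X[:, perm]),
                           predict_scores(a, X), atol=1e-10)

    def test_injected_effects_recovered_in_vip(self, library):
        """Synthetic cohorts (n=192, |log2FC| = 0.7): each injected
        metabolite's principal bucket reaches VIP > 2 in >= 80% of 20
        seeds."""
        from metabodx import SOLID_TUMOR_EFFECTS
        peaks = {p.name: p for p in library}
        names = [e.metabolite for e in SOLID_TUMOR_EFFECTS]
        hits = {n: 0 for n in names}
        for seed in range(20):
            cfg = CohortConfig(n_samples=192, prevalence=0.0885,
                               points_per_spectrum=4096, seed=seed)
            cohort = simulate_cohort(cfg, library)
            spectra = [reference_to_lactate(s) for s in cohort.spectra]
            table = assemble_bucket_table(spectra, cohort.labels)
            scaling = fit_pareto(table)
            X = apply_pareto(table, scaling).matrix
            model = fit_opls(X, cohort.labels, 0)
            sig = table.bucket_centers[vip(model).significant]
            for n in names:
                pp = peaks[n].principal_position
                if np.any(np.abs(sig - pp) < 0.005):
                    hits[n] += 1
        for n in names:
            assert hits[n] >= 16, f"{n}: {hits[n]}/20"
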