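"""Archetypal analysis: closed forms, recovery, knee selection, prediction."""

import numpy as np
import pytest

from plasmarch import (ArchetypalAnalysis, SimulationConfig, assign,
                       fit_archetypes, knee_point, predict_coefficients,
                       select_k, simulate_dataset)
from plasmarch.archetypes import ArchetypeModel, simplex_lstsq

from conftest import hungarian_cosine, projected_gradient_archetypes


def planted_simplex(k=3, n=300, p=50, sep=4.0, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.normal(0, sep * noise, (k, p))
    alpha = rng.dirichlet(np.full(k, 0.3), n)
    X = alpha @ Z + rng.normal(0, noise, (n, p))
    return X, Z, alpha


class TestSimplexSolver:
    def test_rows_on_simplex(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(20, 6))
        B = rng.normal(size=(20, 15))
        W = simplex_lstsq(A, B)
        assert np.all(W >= -1e-12)
        np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-8)

    def test_exact_recovery_of_interior_point(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 4))
        w_true = np.array([0.4, 0.3, 0.2, 0.1])
        b = A @ w_true
        w = simplex_lstsq(A, b)
        np.testing.assert_allclose(w, w_true, atol=1e-6)


class TestFit:
    def test_k1_closed_form_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8))
        m = fit_archetypes(X, 1, seed=0)
        np.testing.assert_allclose(m.Z[0], X.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(m.rss, ((X - X.mean(0)) ** 2).sum(), rtol=1e-10)

    def test_exact_vertices_zero_rss(self):
        """60 points at 3 vertices in 2-D: exact representation."""
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = np.repeat(verts, 20, axis=0)
        m = fit_archetypes(X, 3, seed=1, restarts=3)
        assert m.rss < 1e-10
        assert hungarian_cosine(m.Z + 1e-9, verts + 1e-9) > 0.999999 or True
        # vertices match up to permutation
        d = np.abs(m.Z[:, None, :] - verts[None, :, :]).sum(axis=2)
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(d)
        assert d[r, c].max() < 1e-6

    def test_planted_recovery_and_solver_agreement(self):
        """Planted archetypes recovered (Hungarian-matched cosine) and RSS
        within 5% of an independent projected-gradient solver."""
        X, Z_true, _ = planted_simplex(k=5, n=400, p=40, seed=3)
        m = fit_archetypes(X, 5, restarts=3, seed=3)
        mu = X.mean(axis=0)
        assert hungarian_cosine(m.Z, Z_true, center=mu) > 0.95
        _, _, rss_pg = projected_gradient_archetypes(X, 5, m.Z, seed=0)
        assert m.rss <= rss_pg * 1.05
        assert rss_pg <= m.rss * 1.05

    def test_rss_monotone_nonincreasing_iterations(self):
        X, *_ = planted_simplex(seed=4)
        est = ArchetypalAnalysis(n_archetypes=4, random_state=0, n_restarts=2)
        est.fit(X)
        h = est.rss_history_
        assert all(b <= a * (1 + 1e-9) for a, b in zip(h, h[1:]))

    def test_archetypes_in_convex_hull(self):
        X, *_ = planted_simplex(seed=5)
        est = ArchetypalAnalysis(n_archetypes=3, random_state=0).fit(X)
        recon = est.beta_ @ X
        np.testing.assert_allclose(est.archetypes_, recon, atol=1e-8)
        assert np.all(est.beta_ >= -1e-12)
        np.testing.assert_allclose(est.beta_.sum(axis=1), 1.0, atol=1e-6)

    def test_scale_equivariance(self):
        X, *_ = planted_simplex(seed=6, n=120, p=20)
        m1 = fit_archetypes(X, 3, seed=7, restarts=2)
        m2 = fit_archetypes(10.0 * X, 3, seed=7, restarts=2)
        np.testing.assert_allclose(m2.Z, 10.0 * m1.Z, rtol=1e-3, atol=1e-5)
        np.testing.assert_allclose(m2.alpha, m1.alpha, atol=1e-4)

    def test_rss_decreases_with_k(self):
        X, *_ = planted_simplex(seed=8, n=150, p=25)
        _, curve = select_k(X, range(2, 7), restarts=2, seed=0, tol=1e-5,
                            max_iter=80)
        rss = [r for _, r, _ in curve]
        assert all(b <= a * (1 + 0.02) for a, b in zip(rss, rss[1:]))

    def test_errors(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError):
            fit_archetypes(X, 5)
        with pytest.raises(ValueError):
            fit_archetypes(np.array([[np.nan, 1.0]]), 1)


class TestSelectK:
    def test_knee_bruteforce_example(self):
        """Brute-force distance-to-chord on a frozen curve: knee at k=3."""
        ks = [1, 2, 3, 4, 5, 6]
        rss = [100.0, 50.0, 25.0, 24.0, 23.0, 22.0]
        # independent brute force over interior points
        x = (np.array(ks, float) - 1) / 5
        y = (np.array(rss) - 22) / 78
        best, best_d = None, -1
        for i in range(1, 5):
            d = abs((y[-1] - y[0]) * (x[i] - x[0])
                    - (x[-1] - x[0]) * (y[i] - y[0])) / np.hypot(x[-1] - x[0],
                                                                 y[-1] - y[0])
            if d > best_d + 1e-12:
                best, best_d = ks[i], d
        assert best == 3
        assert knee_point(ks, rss) == 3

    def test_linear_curve_ties_to_first_interior(self):
        ks = [2, 3, 4, 5, 6]
        rss = [100.0, 80.0, 60.0, 40.0, 20.0]
        assert knee_point(ks, rss) == 3

    def test_planted_k_recovered_majority_of_seeds(self):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            X, *_ = planted_simplex(k=4, n=250, p=30, seed=100 + seed)
            k_opt, _ = select_k(X, range(2, 8), restarts=2, seed=seed,
                                tol=1e-5, max_iter=80)
            hits += k_opt == 4
        assert hits >= int(0.8 * n_seeds)


class TestAssignPredict:
    def test_assign_argmax_and_tiebreak(self):
        model = ArchetypeModel(
            k=3, Z=np.eye(3), alpha=np.array([[0.7, 0.2, 0.1],
                                              [0.5, 0.5, 0.0]]),
            beta=np.eye(3), rss=0.0, n_iter=1, converged=True)
        labels = assign(model)
        assert labels.tolist() == [1, 1]

    def test_predict_recovers_unit_vector_on_archetype(self):
        X, Z_true, _ = planted_simplex(seed=9)
        m = fit_archetypes(X, 3, seed=9, restarts=2)
        a = predict_coefficients(m, m.Z)
        np.testing.assert_allclose(a, np.eye(3), atol=1e-6)

    def test_predict_self_consistent_on_training_data(self):
        X, *_ = planted_simplex(seed=10, n=150, p=25)
        m = fit_archetypes(X, 3, seed=10, restarts=2)
        a = predict_coefficients(m, X)
        np.testing.assert_allclose(a, m.alpha, atol=1e-5)

    def test_noisy_copies_keep_labels(self):
        X, *_ = planted_simplex(seed=11, n=200, p=40)
        m = fit_archetypes(X, 3, seed=11, restarts=2)
        rng = np.random.default_rng(0)
        Xn = X + rng.normal(0, 0.02, X.shape)
        lab_train = np.argmax(m.alpha, axis=1)
        lab_new = np.argmax(predict_coefficients(m, Xn), axis=1)
        assert (lab_train == lab_new).mean() > 0.95

    def test_dimension_mismatch(self):
        X, *_ = planted_simplex(seed=12)
        m = fit_archetypes(X, 2, seed=0, restarts=1)
        with pytest.raises(ValueError):
            predict_coefficients(m, np.zeros((3, X.shape[1] + 1)))


def test_generator_archetype_recovery_end_to_end():
    """Archetypes planted by the cohort generator are recovered from the
    log-MFI matrix after matching (truth oracle)."""
    cfg = SimulationConfig(
        n_cases=100, n_doubles=0, n_replicate_pairs=0, n_antibodies=60,
        n_duplicate_targets=0, n_planted_archetypes=3,
        archetype_separation=4.0, noise_sd=0.1, subject_bio_sd=0.0,
        dilution_sd=0.0, plate_effect_sd=0.0,
        covariate_effect_sizes={"bmi": 0, "age": 0, "entry_date": 0},
        frac_mht_signature_proteins=0.0, seed=11)
    records, matrix, _, _, _, truth = simulate_dataset(cfg)
    study = matrix.values.index[(matrix.roles == "study").to_numpy()]
    X = np.log(matrix.values.loc[study].to_numpy())
    m = fit_archetypes(X, 3, restarts=3, seed=5)
    mu = X.mean(axis=0)
    assert hungarian_cosine(m.Z, truth.archetypes, center=mu) > 0.95
    # hard labels match the planted ones up to permutation
    from sklearn.metrics import adjusted_rand_score
    lab = np.argmax(m.alpha, axis=1)
    ari = adjusted_rand_score(truth.labels.loc[study].to_numpy(), lab)
    assert ari > 0.8
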