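"""Likelihood, objective, optimizer, and cross-validation of the regression model."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit

from pathreg.genesets import MembershipMatrix, SimilarityMatrix, jaccard_matrix, membership_matrix
from pathreg.model import (
    FitDivergenceError,
    ModelConfig,
    ResponseVector,
    beta_log_likelihood,
    clamp_pvalues,
    cross_validate,
    fit,
    fusion_penalty,
    link_forward,
    link_inverse,
    objective,
    soft_threshold,
)
from pathreg.synthetic import SyntheticConfig, generate_dataset, generate_term_database
from conftest import make_db, random_instance


class TestClampAndLink:
    def test_boundary_values_pulled_inside(self):
        y = clamp_pvalues([0.0, 0.5, 1.0], ("a", "b", "c"), epsilon=1e-6)
        np.testing.assert_allclose(y.values, [1e-6, 0.5, 1 - 1e-6])

    def test_interior_values_unchanged(self):
        raw = [0.2, 0.8]
        y = clamp_pvalues(raw, ("a", "b"))
        np.testing.assert_array_equal(y.values, raw)

    def test_out_of_range_names_gene(self):
        with pytest.raises(ValueError, match="bad_gene"):
            clamp_pvalues([0.5, 1.2], ("ok", "bad_gene"))

    def test_logistic_closed_forms(self):
        assert link_inverse(0.0) == pytest.approx(0.5)
        assert link_inverse(-1.0) == pytest.approx(1 / (1 + np.e))

    def test_mutual_inverses(self):
        x = np.array([-3.0, 0.0, 3.0])
        np.testing.assert_allclose(link_forward(link_inverse(x)), x, atol=1e-12)

    def test_forward_domain_error(self):
        with pytest.raises(ValueError):
            link_forward([0.0, 0.5])


class TestBetaLogLikelihood:
    def test_uniform_density_is_zero(self):
        # mu=0.5, phi=2 gives shapes (1,1): the uniform density, log-density 0
        y = np.array([0.1, 0.37, 0.92])
        assert beta_log_likelihood(y, np.full(3, 0.5), 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_shape_two(self):
        # shapes (2,2): density 6 y (1-y); at y=1/2 that is 3/2
        assert beta_log_likelihood(np.array([0.5]), np.array([0.5]), 4.0) == \
            pytest.approx(np.log(1.5), abs=1e-9)

    def test_additivity_over_genes(self):
        y = np.array([0.2, 0.7])
        mu = np.array([0.4, 0.6])
        total = beta_log_likelihood(y, mu, 3.0)
        parts = sum(beta_log_likelihood(y[i:i + 1], mu[i:i + 1], 3.0) for i in range(2))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_agrees_with_scipy_density(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(1, 6)
            y = rng.uniform(0.01, 0.99, n)
            mu = rng.uniform(0.05, 0.95, n)
            phi = rng.uniform(0.2, 10.0)
            ours = beta_log_likelihood(y, mu, phi)
            ref = stats.beta.logpdf(y, mu * phi, (1 - mu) * phi).sum()
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            beta_log_likelihood(np.array([0.0]), np.array([0.5]), 1.0)
        with pytest.raises(ValueError):
            beta_log_likelihood(np.array([0.5]), np.array([0.5]), -1.0)


class TestObjective:
    def test_zero_beta_reduces_to_negative_loglik(self):
        y, X = random_instance(0)
        G = SimilarityMatrix(values=np.eye(X.n_terms), term_ids=X.term_ids)
        cfg = ModelConfig(lambda_=3.0, psi=7.0)
        obj = objective(np.zeros(X.n_terms), 1.7, y, X, G, cfg)
        assert obj == pytest.approx(
            -beta_log_likelihood(y, np.full(X.n_genes, 0.5), 1.7), abs=1e-10)

    def test_fusion_double_sum_hand_value(self):
        # K=2, beta=(1,-1), g12=g21=1: ordered-pair sum = 2 * (1-(-1))^2 = 8
        g = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert fusion_penalty(np.array([1.0, -1.0]), g) == pytest.approx(8.0)

    def test_matches_bruteforce_three_term_sum(self):
        rng = np.random.default_rng(7)
        y, X = random_instance(3, n=5, k=3)
        gv = rng.uniform(0, 1, (3, 3))
        gv = (gv + gv.T) / 2
        np.fill_diagonal(gv, 1.0)
        G = SimilarityMatrix(values=gv, term_ids=X.term_ids)
        beta = rng.normal(size=3)
        phi = 2.3
        cfg = ModelConfig(lambda_=0.7, psi=1.3)
        # independent re-evaluation: scipy density + explicit loops
        mu = expit(X.values @ beta)
        nll = -stats.beta.logpdf(y.values, mu * phi, (1 - mu) * phi).sum()
        l1 = 0.7 * np.abs(beta).sum()
        fus = 1.3 * sum((beta[i] - beta[j]) ** 2 * gv[i, j]
                        for i in range(3) for j in range(3))
        assert objective(beta, phi, y, X, G, cfg) == pytest.approx(nll + l1 + fus, abs=1e-8)

    def test_fusion_shift_invariant_l1_not(self):
        rng = np.random.default_rng(11)
        beta = rng.normal(size=4)
        gv = rng.uniform(0, 1, (4, 4))
        gv = (gv + gv.T) / 2
        assert fusion_penalty(beta + 5.0, gv) == pytest.approx(fusion_penalty(beta, gv),
                                                               rel=1e-9)
        assert np.abs(beta + 5.0).sum() != pytest.approx(np.abs(beta).sum())

    def test_nonfinite_parameters_raise(self):
        y, X = random_instance(1)
        G = SimilarityMatrix(values=np.eye(X.n_terms), term_ids=X.term_ids)
        with pytest.raises(FitDivergenceError):
            objective(np.full(X.n_terms, np.nan), 1.0, y, X, G, ModelConfig())


class TestSoftThreshold:
    def test_zero_threshold_is_identity(self):
        x = np.array([-2.0, -0.1, 0.0, 0.1, 2.0])
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_shrinks_toward_zero(self):
        np.testing.assert_allclose(soft_threshold(np.array([3.0, -3.0, 0.2]), 1.0),
                                   [2.0, -2.0, 0.0])


class TestFit:
    def test_huge_lasso_shrinks_all_to_zero(self):
        y, X = random_instance(5, n=60, k=4)
        res = fit(y, X, None, ModelConfig(lambda_=1e6))
        assert np.abs(res.beta).max() < 1e-4

    def test_huge_fusion_forces_equality(self):
        y, X = random_instance(6, n=60, k=4)
        G = SimilarityMatrix(values=np.ones((4, 4)), term_ids=X.term_ids)
        res = fit(y, X, G, ModelConfig(psi=1e6))
        assert res.beta.max() - res.beta.min() < 1e-3

    def test_unpenalized_matches_independent_optimizer(self):
        rng = np.random.default_rng(2024)
        n, k = 200, 3
        x = rng.integers(0, 2, size=(n, k)).astype(float)
        x[:, 2] = (rng.uniform(size=n) < 0.4).astype(float)  # break collinearity
        beta_true = np.array([-1.2, 0.6, 0.0])
        mu = expit(x @ beta_true)
        yv = np.clip(rng.beta(mu * 2, (1 - mu) * 2), 1e-6, 1 - 1e-6)
        genes = tuple(f"g{i}" for i in range(n))
        y = ResponseVector(values=yv, gene_ids=genes)
        X = MembershipMatrix(values=x, gene_ids=genes, term_ids=("a", "b", "c"))

        def nll(params):
            b, theta = params[:k], params[k]
            m = np.clip(expit(x @ b), 1e-12, 1 - 1e-12)
            phi = np.exp(theta)
            return -stats.beta.logpdf(yv, m * phi, (1 - m) * phi).sum()

        ref = optimize.minimize(nll, np.zeros(k + 1), method="L-BFGS-B")
        res = fit(y, X, None, ModelConfig(tol=1e-9, max_epochs=5000))
        np.testing.assert_allclose(res.beta, ref.x[:k], atol=1e-2)
        assert res.phi == pytest.approx(np.exp(ref.x[k]), abs=1e-2)

    def test_objective_trace_monotone_and_finite(self):
        for lam, psi in [(0.0, 0.0), (0.5, 0.0), (0.0, 0.5), (1.0, 1.0)]:
            y, X = random_instance(8, n=50, k=3)
            gv = np.full((3, 3), 0.5)
            np.fill_diagonal(gv, 1.0)
            G = SimilarityMatrix(values=gv, term_ids=X.term_ids)
            res = fit(y, X, G, ModelConfig(lambda_=lam, psi=psi))
            trace = res.objective_trace
            assert np.isfinite(trace).all()
            assert (np.diff(trace) <= 1e-8).all()
            assert trace[-1] <= trace[0]
            assert ((res.fitted_means > 0) & (res.fitted_means < 1)).all()
            assert res.phi > 0

    def test_minibatch_trace_still_monotone(self):
        y, X = random_instance(9, n=80, k=3)
        res = fit(y, X, None, ModelConfig(batch_size=16, seed=4))
        assert (np.diff(res.objective_trace) <= 1e-8).all()

    def test_same_seed_reproducible(self):
        y, X = random_instance(10, n=50, k=3)
        cfg = ModelConfig(lambda_=0.3, batch_size=10, seed=13)
        a = fit(y, X, None, cfg)
        b = fit(y, X, None, cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        assert a.phi == b.phi

    def test_active_terms_get_larger_coefficients(self):
        # clean generative setting: activated terms should dominate in |beta|
        wins = 0
        for seed in range(10):
            db = generate_term_database(30, 500, (15, 40), n_blocks=3,
                                        within_block_overlap=0.3, seed=seed)
            S = jaccard_matrix(db)
            ds = generate_dataset(db, S, SyntheticConfig(n_active=4, rho=0.0, eta=0.0,
                                                         seed=seed))
            X = membership_matrix(db, ds.response.gene_ids)
            res = fit(ds.response, X, S, ModelConfig(lambda_=0.5, psi=0.1))
            active = np.array([t in ds.truth.active_terms for t in res.term_ids])
            if np.median(np.abs(res.beta[active])) > np.median(np.abs(res.beta[~active])):
                wins += 1
        assert wins >= 9

    def test_error_on_all_zero_membership(self):
        y, _ = random_instance(12, n=10, k=2)
        X = MembershipMatrix(values=np.zeros((10, 2)),
                             gene_ids=y.gene_ids, term_ids=("a", "b"))
        with pytest.raises(ValueError, match="nonzero"):
            fit(y, X, None)


class TestCrossValidation:
    def test_single_cell_grid_returned_verbatim(self):
        y, X = random_instance(20, n=40, k=3)
        cv = cross_validate(y, X, None, lambda_grid=[0.7], psi_grid=[0.3], n_folds=3)
        assert cv.best == (0.7, 0.3)
        assert len(cv.table) == 1

    def test_same_seed_identical_table(self):
        y, X = random_instance(21, n=40, k=3)
        kw = dict(lambda_grid=[0.0, 1.0], psi_grid=[0.0], n_folds=3, seed=5)
        a = cross_validate(y, X, None, **kw)
        b = cross_validate(y, X, None, **kw)
        assert a.best == b.best
        assert a.table.equals(b.table)

    def test_sparse_truth_prefers_positive_lambda(self):
        picks = []
        for seed in range(10):
            db = generate_term_database(20, 400, (15, 30), n_blocks=4,
                                        within_block_overlap=0.3, seed=100 + seed)
            S = jaccard_matrix(db)
            ds = generate_dataset(db, S, SyntheticConfig(n_active=2, rho=0.0, eta=0.0,
                                                         seed=100 + seed))
            X = membership_matrix(db, ds.response.gene_ids)
            cv = cross_validate(ds.response, X, S, lambda_grid=[0.0, 1.0, 5.0],
                                psi_grid=[0.0], n_folds=3, seed=seed)
            picks.append(cv.lambda_)
        assert sum(lam > 0 for lam in picks) > len(picks) / 2

    def test_fold_size_validation(self):
        y, X = random_instance(22, n=5, k=2)
        with pytest.raises(ValueError):
            cross_validate(y, X, None, lambda_grid=[0.0], psi_grid=[0.0], n_folds=6)
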