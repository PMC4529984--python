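import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridgepred.preprocess import build_grms, eigendecompose, make_projector
from ridgepred.ridge import (LambdaGrid, default_lambda_grid, hrr_from_tstats,
                             ridge_predict, rr_dual_predict, rr_primal,
                             rsr_score, squared_correlation)
from ridgepred.simulate import (build_phenotypes, draw_genotypes,
                                true_frequency_standardize)

from conftest import standardized_pair


def _direct_dual_solve(A, A21, y, lam):
    return A21 @ np.linalg.solve(A + lam * np.eye(A.shape[0]), y)


class TestLambdaGrid:
    def test_default_grid_spacing(self):
        grid = default_lambda_grid()
        assert len(grid) == 151
        assert grid.values[0] == pytest.approx(1e-6)
        assert grid.values[-1] == pytest.approx(1e9)
        # 10 points per decade
        assert np.log10(grid.values[10] / grid.values[0]) == pytest.approx(1.0)

    def test_scale_conversion_round_trip(self):
        grid = LambdaGrid([1.0, 10.0])
        back = grid.on_scale("grm", 50).on_scale("raw", 50)
        np.testing.assert_allclose(back.values, grid.values)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            LambdaGrid([0.0, 1.0])


class TestPrimal:
    def test_orthonormal_columns_closed_form(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((20, 5)))
        y = rng.standard_normal(20)
        fit = rr_primal(q, y, 0.5)
        np.testing.assert_allclose(fit.beta_hat, q.T @ y / 1.5, atol=1e-10)

    def test_huge_lambda_shrinks_to_zero(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        fit = rr_primal(X, y, 1e12)
        assert np.linalg.norm(fit.beta_hat) <= 1e-6 * np.linalg.norm(X.T @ y)

    def test_matches_normal_equation_solve(self, rng):
        X = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        fit = rr_primal(X, y, 3.0)
        expected = np.linalg.solve(X.T @ X + 3.0 * np.eye(6), X.T @ y)
        np.testing.assert_allclose(fit.beta_hat, expected, atol=1e-10)

    def test_singular_at_lambda_zero(self, rng):
        X = rng.standard_normal((5, 9))  # P > N
        with pytest.raises(np.linalg.LinAlgError, match="λ > 0"):
            rr_primal(X, rng.standard_normal(5), 0.0)

    def test_beta_norm_monotone_in_lambda(self, rng):
        X = rng.standard_normal((25, 10))
        y = rng.standard_normal(25)
        norms = [np.linalg.norm(rr_primal(X, y, lam).beta_hat)
                 for lam in np.logspace(-3, 5, 17)]
        assert (np.diff(norms) <= 1e-12).all()


class TestDualEquivalence:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9_999),
           log_lam=st.floats(min_value=-4.0, max_value=4.0))
    def test_primal_equals_dual_random_instances(self, seed, log_lam):
        rng = np.random.default_rng(seed)
        n, n2, p = rng.integers(10, 60), 8, rng.integers(3, 60)
        X, X2 = rng.standard_normal((n, p)), rng.standard_normal((n2, p))
        y = rng.standard_normal(n)
        lam = 10.0 ** log_lam
        fit = rr_primal(X, y, lam)
        grid = LambdaGrid([lam]).on_scale("grm", p)
        preds = rr_dual_predict(build_grms(X, X2), y, grid)
        np.testing.assert_allclose(preds.yhat2[:, 0], X2 @ fit.beta_hat,
                                   atol=1e-8)

    def test_primal_equals_dual_with_confounders(self, rng):
        n, n2, p = 30, 6, 50
        X, X2 = rng.standard_normal((n, p)), rng.standard_normal((n2, p))
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Z2 = np.column_stack([np.ones(n2), rng.standard_normal(n2)])
        y = rng.standard_normal(n)
        lam = 2.5
        fit = rr_primal(X, y, lam, Z=Z)
        grms = build_grms(X, X2, projector=make_projector(Z),
                          projector2=make_projector(Z2))
        preds = rr_dual_predict(grms, y, LambdaGrid([lam]).on_scale("grm", p))
        proj2 = make_projector(Z2)
        np.testing.assert_allclose(preds.yhat2[:, 0],
                                   proj2.apply(X2 @ fit.beta_hat), atol=1e-8)

    def test_multi_lambda_equals_per_lambda_solves(self, rng):
        n, n2, p = 20, 5, 40
        X, X2 = rng.standard_normal((n, p)), rng.standard_normal((n2, p))
        y = rng.standard_normal(n)
        grms = build_grms(X, X2)
        grid = LambdaGrid(np.logspace(-3, 3, 13), "grm")
        joint = rr_dual_predict(grms, y, grid)
        for j, lam in enumerate(grid.values):
            direct = _direct_dual_solve(grms.A_star, grms.A21_star, y, lam)
            np.testing.assert_allclose(joint.yhat2[:, j], direct, atol=1e-10)

    def test_blup_equivalence_at_variance_ratio(self, rng):
        """Ridge at λ = σ²_ε/σ²_β equals the mixed-model conditional mean."""
        n, p = 25, 40
        X = rng.standard_normal((n, p))
        s2_beta, s2_eps = 0.4, 1.3
        y = X @ rng.normal(0, np.sqrt(s2_beta), p) \
            + rng.normal(0, np.sqrt(s2_eps), n)
        lam = s2_eps / s2_beta
        blup = s2_beta * X.T @ np.linalg.solve(
            s2_beta * X @ X.T + s2_eps * np.eye(n), y)
        fit = rr_primal(X, y, lam)
        np.testing.assert_allclose(fit.beta_hat, blup, atol=1e-8)

    def test_primal_path_matches_dual_when_n_exceeds_p(self, rng):
        n, n2, p = 60, 9, 12
        X, X2 = rng.standard_normal((n, p)), rng.standard_normal((n2, p))
        y = rng.standard_normal(n)
        grid = LambdaGrid(np.logspace(-2, 2, 9))
        via_primal = ridge_predict(X, X2, y, grid)           # N > P branch
        grms = build_grms(X, X2)
        via_dual = rr_dual_predict(grms, y, grid.on_scale("grm", p))
        np.testing.assert_allclose(via_primal.yhat2, via_dual.yhat2, atol=1e-8)

    def test_projected_predictions_orthogonal_to_test_covariates(self, rng):
        n, n2, p = 40, 12, 80
        X, X2 = rng.standard_normal((n, p)), rng.standard_normal((n2, p))
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Z2 = np.column_stack([np.ones(n2), rng.standard_normal(n2)])
        y = rng.standard_normal(n)
        preds = ridge_predict(X, X2, y, LambdaGrid(np.logspace(-2, 4, 7)),
                              Z=Z, Z2=Z2)
        assert np.abs(Z2.T @ preds.yhat2).max() < 1e-8


class TestRsr:
    def test_single_causal_orthogonal_snps(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((30, 4)))
        X = q * np.sqrt(29.0)  # standardized columns: x_pᵀx_p = N-1
        y = X[:, 0].copy()
        beta_rsr = X.T @ y
        np.testing.assert_allclose(beta_rsr, [29.0, 0, 0, 0], atol=1e-10)
        score = rsr_score(X, X, y)
        np.testing.assert_allclose(score, X @ beta_rsr, atol=1e-10)

    def test_unstandardized_input_rejected(self, rng):
        X = rng.standard_normal((20, 5)) * np.array([1, 2, 3, 4, 5.0])
        with pytest.raises(ValueError, match="standardized"):
            rsr_score(X, X, rng.standard_normal(20))

    def test_inflated_ridge_approaches_rsr(self, rng):
        X, X2 = standardized_pair(rng, 50, 20, 200)
        y = rng.standard_normal(50)
        rr = ridge_predict(X, X2, y, LambdaGrid([1e9])).yhat2[:, 0]
        rsr = rsr_score(X, X2, y)
        assert squared_correlation(rr, rsr) >= 1 - 1e-6

    def test_vanishing_lambda_recovers_ols(self, rng):
        X, X2 = standardized_pair(rng, 50, 10, 5)
        y = rng.standard_normal(50)
        rr = ridge_predict(X, X2, y, LambdaGrid([1e-8])).yhat2[:, 0]
        ols = X2 @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(rr, ols, atol=1e-6)

    def test_training_fit_dominance_over_rsr(self, rng):
        """In-sample, ridge at tiny λ fits at least as well as the GWAS score."""
        X, _ = standardized_pair(rng, 40, 2, 25)
        y = rng.standard_normal(40)
        rr_in = ridge_predict(X, X, y, LambdaGrid([1e-6])).yhat2[:, 0]
        rsr_in = rsr_score(X, X, y)
        assert squared_correlation(rr_in, y) >= squared_correlation(rsr_in, y)


class TestHrrWeights:
    def test_constant_tstats_equal_homoskedastic_at_adjusted_lambda(self, rng):
        n, n2, p = 25, 6, 40
        X, X2 = rng.standard_normal((n, p)), rng.standard_normal((n2, p))
        y = rng.standard_normal(n)
        w = hrr_from_tstats(np.full(p, 2.0))   # Λ = I/4
        lam = 3.0
        hrr = ridge_predict(X, X2, y, LambdaGrid([lam]), weights=w).yhat2[:, 0]
        plain = ridge_predict(X, X2, y, LambdaGrid([lam / 4.0])).yhat2[:, 0]
        np.testing.assert_allclose(hrr, plain, atol=1e-8)

    def test_doubling_t_quarters_penalty(self):
        w1 = hrr_from_tstats(np.array([1.0, 2.0]))
        assert w1.lambda_p[1] == pytest.approx(w1.lambda_p[0] / 4.0)

    def test_zero_tstat_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            w = hrr_from_tstats(np.array([0.0, 1.0]))
        assert w.lambda_p[0] == pytest.approx(1e6)

    def test_informative_prior_beats_homoskedastic_usually(self):
        """t statistics ∝ true |β| should help ridge more often than not.

        Monte-Carlo regression guard: informative per-SNP penalties win in a
        clear majority of replicates on sparse architectures.
        """
        wins = 0
        n_rep = 50
        n, p, h2, fc = 500, 2000, 0.5, 0.05
        grid = LambdaGrid(np.logspace(-2, 6, 33))
        for rep in range(n_rep):
            seed = 60_000 + rep
            G, f = draw_genotypes(int(1.1 * n), p, seed)
            X = true_frequency_standardize(G, f)
            y, mask, beta = build_phenotypes(X, p, fc, h2, seed + 1)
            t = np.zeros(p)
            t[mask] = 5.0 * np.abs(beta)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # non-causal t's hit the floor
                w = hrr_from_tstats(t)
            Xtr, Xte, ytr, yte = X[:n], X[n:], y[:n], y[n:]
            r2 = lambda preds: max(squared_correlation(preds.yhat2[:, j], yte)
                                   for j in range(len(grid)))
            hrr = r2(ridge_predict(Xtr, Xte, ytr, grid, weights=w))
            plain = r2(ridge_predict(Xtr, Xte, ytr, grid))
            wins += hrr >= plain
        assert wins / n_rep >= 0.60
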