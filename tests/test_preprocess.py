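import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridgepred.io_formats import GenotypeMatrix
from ridgepred.preprocess import (EigenGRM, Projector, ShrinkWeights,
                                  build_grms, eigendecompose,
                                  frequency_weights, make_projector,
                                  standardize)
from ridgepred.ridge import rr_primal

from conftest import random_genotypes


def _gm(counts):
    counts = np.asarray(counts)
    return GenotypeMatrix(counts, [f"i{k}" for k in range(counts.shape[0])],
                          [f"s{j}" for j in range(counts.shape[1])])


class TestStandardize:
    def test_single_column_0_1_2(self):
        std = standardize(_gm([[0], [1], [2]]))
        np.testing.assert_allclose(std.X[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_names_offender(self):
        with pytest.raises(ValueError, match="s1"):
            standardize(_gm([[0, 1], [1, 1], [2, 1]]))

    def test_columns_centered_and_norm_n_minus_1(self, rng):
        gm = random_genotypes(rng, 50, 20)
        std = standardize(gm)
        np.testing.assert_allclose(std.X.sum(axis=0), 0.0, atol=1e-8 * 50)
        np.testing.assert_allclose((std.X ** 2).sum(axis=0), 49.0, atol=1e-8)

    def test_true_frequency_uses_generating_frequencies(self, rng):
        gm = random_genotypes(rng, 30, 5)
        std = standardize(gm, "true_frequency")
        f = gm.allele_freqs
        expected = (gm.counts - 2 * f) / np.sqrt(2 * f * (1 - f))
        np.testing.assert_allclose(std.X, expected)

    def test_true_frequency_requires_freqs(self):
        with pytest.raises(ValueError, match="allele_freqs"):
            standardize(_gm([[0], [1], [2]]), "true_frequency")

    def test_transform_reuses_training_scaling(self, rng):
        gm = random_genotypes(rng, 40, 8)
        train = GenotypeMatrix(gm.counts[:30], gm.sample_ids[:30], gm.snp_ids)
        test = GenotypeMatrix(gm.counts[30:], gm.sample_ids[30:], gm.snp_ids)
        std = standardize(train)
        expected = (test.counts - std.column_means) * std.scale_diag
        np.testing.assert_allclose(std.transform(test), expected)


class TestFrequencyWeights:
    def test_alpha_zero_gives_unit_weights(self):
        w = frequency_weights(np.array([0.5, 2.0, 3.0]), 0.0)
        np.testing.assert_array_equal(w.lambda_p, 1.0)

    def test_alpha_minus_two_power(self):
        w = frequency_weights(np.array([2.0]), -2.0)
        assert w.lambda_p[0] == pytest.approx(0.25)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            frequency_weights(np.array([1.0, 0.0]), -2.0)

    @pytest.mark.parametrize("lam", [0.3, 7.0])
    def test_hrr_on_raw_equals_rr_on_standardized(self, rng, lam):
        """Penalty D^-2 on centered counts reproduces plain ridge on X = GD."""
        gm = random_genotypes(rng, 30, 12)
        g_test = random_genotypes(rng, 8, 12)
        std = standardize(gm)
        G = gm.imputed() - gm.imputed().mean(axis=0)
        G2 = g_test.imputed() - gm.imputed().mean(axis=0)
        rr = rr_primal(std.X, rng.standard_normal(30), lam)
        # refit on the same outcome for both parameterizations
        y = np.asarray(std.X @ rng.standard_normal(12) + rng.standard_normal(30))
        rr = rr_primal(std.X, y, lam)
        hrr = rr_primal(G, y, lam, weights=frequency_weights(std.scale_diag, -2.0))
        np.testing.assert_allclose(G2 @ hrr.beta_hat,
                                   std.transform(g_test) @ rr.beta_hat,
                                   atol=1e-8)


class TestProjector:
    def test_intercept_only_demeans(self, rng):
        y = rng.standard_normal(25)
        proj = make_projector(np.ones((25, 1)))
        np.testing.assert_allclose(proj.apply(y), y - y.mean())

    def test_annihilates_z(self, rng):
        Z = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        proj = make_projector(Z)
        assert np.abs(proj.apply(Z)).max() < 1e-10

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        Z = np.column_stack([np.ones(30), rng.standard_normal((30, 3))])
        y = rng.standard_normal(30)
        proj = make_projector(Z)
        once = proj.apply(y)
        np.testing.assert_allclose(proj.apply(once), once, atol=1e-12)

    def test_rank_deficient_z_rejected(self):
        Z = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank deficient"):
            make_projector(Z)


class TestBuildGrms:
    def test_trace_is_n_minus_1(self, rng):
        std = standardize(random_genotypes(rng, 35, 14))
        grms = build_grms(std.X)
        assert np.trace(grms.A_star) == pytest.approx(34.0, abs=1e-8)

    def test_unit_weights_match_unweighted(self, rng):
        std = standardize(random_genotypes(rng, 20, 9))
        plain = build_grms(std.X)
        weighted = build_grms(std.X, weights=ShrinkWeights(np.ones(9)))
        np.testing.assert_allclose(weighted.A_star, plain.A_star, atol=1e-12)

    def test_projection_annihilates_covariates(self, rng):
        std = standardize(random_genotypes(rng, 30, 10))
        Z = np.column_stack([np.ones(30), rng.standard_normal(30)])
        grms = build_grms(std.X, projector=make_projector(Z))
        assert np.abs(Z.T @ grms.A_star @ Z).max() < 1e-8

    def test_projected_grm_equals_grm_of_projected_x(self, rng):
        std = standardize(random_genotypes(rng, 24, 8))
        Z = np.column_stack([np.ones(24), rng.standard_normal(24)])
        proj = make_projector(Z)
        a = build_grms(std.X, projector=proj).A_star
        xp = proj.apply(std.X)
        np.testing.assert_allclose(a, xp @ xp.T / 8, atol=1e-10)

    def test_snp_order_invariance_and_sample_permutation(self, rng):
        std = standardize(random_genotypes(rng, 18, 7))
        base = build_grms(std.X).A_star
        perm_snps = build_grms(std.X[:, rng.permutation(7)]).A_star
        np.testing.assert_allclose(perm_snps, base, atol=1e-12)
        order = rng.permutation(18)
        perm_samples = build_grms(std.X[order]).A_star
        np.testing.assert_allclose(perm_samples, base[np.ix_(order, order)],
                                   atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="SNP count"):
            build_grms(rng.standard_normal((5, 3)), rng.standard_normal((2, 4)))


class TestEigendecompose:
    def test_identity(self):
        eig = eigendecompose(np.eye(6))
        np.testing.assert_allclose(eig.theta, 1.0)
        np.testing.assert_allclose(eig.Q.T @ eig.Q, np.eye(6), atol=1e-8)

    def test_reconstruction_random_psd(self, rng):
        b = rng.standard_normal((30, 30))
        a = b @ b.T / 30
        eig = eigendecompose(a)
        np.testing.assert_allclose(eig.Q @ np.diag(eig.theta) @ eig.Q.T, a,
                                   atol=1e-8)
        assert (np.diff(eig.theta) <= 1e-12).all()

    def test_projection_removes_k_dimensions(self, rng):
        std = standardize(random_genotypes(rng, 20, 40))
        Z = np.column_stack([np.ones(20), rng.standard_normal(20)])
        grms = build_grms(std.X, projector=make_projector(Z))
        eig = eigendecompose(grms)
        assert (eig.theta[-2:] == 0).all()

    def test_asymmetric_rejected(self):
        a = np.eye(4)
        a[0, 1] = 1e-3
        with pytest.raises(ValueError, match="asymmetric"):
            eigendecompose(a)

    def test_nan_rejected(self):
        a = np.eye(3)
        a[1, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            eigendecompose(a)

    def test_indefinite_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            eigendecompose(np.diag([1.0, -0.5]))
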