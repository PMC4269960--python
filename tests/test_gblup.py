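import math

import numpy as np
import pytest

from gsblup import (
    AdjustedPhenotypes,
    AdjustMethod,
    AlignmentError,
    DegenerateGenotypesError,
    Encoding,
    GenotypeMatrix,
    fit_gblup,
    kinship_matrix,
    marker_effects,
    project_spectrum,
    restricted_log_likelihood,
    simulate_genotypes,
    simulate_phenotypes,
)
from gsblup.gblup import centered_dosages


def dense_reml_loglik(lam, K, y):
    """Independent restricted log-likelihood: forms (K + lam I) explicitly
    and evaluates the likelihood of n-1 difference contrasts (rows e_i -
    e_{i+1}, which annihilate the intercept) via dense determinants.  The
    additive constant ln|LL'| differs from other REML conventions but is
    independent of lambda."""
    n = K.shape[0]
    H = K + lam * np.eye(n)
    L = np.eye(n)[:-1] - np.eye(n)[1:]
    M = L @ H @ L.T
    z = L @ y
    quad = z @ np.linalg.solve(M, z)
    sigma_g2 = quad / (n - 1)
    _, logdet_M = np.linalg.slogdet(M)
    return -0.5 * ((n - 1) * math.log(2 * math.pi * sigma_g2) + logdet_M
                   + (n - 1))


def _adjusted(values):
    return AdjustedPhenotypes("t", values, AdjustMethod.ARITHMETIC_MEAN, ["t1"])


class TestKinship:
    def test_identical_genotypes_have_identical_rows(self):
        d = np.array([[0.0, 1, 2, 1], [0.0, 1, 2, 1], [2.0, 0, 0, 1]])
        K = kinship_matrix(GenotypeMatrix(["a", "b", "c"],
                                          [f"m{j}" for j in range(4)], d,
                                          Encoding.ZERO_1_2))
        np.testing.assert_allclose(K.K[0], K.K[1])
        assert K.K[0, 0] == pytest.approx(K.K[0, 1])

    def test_matches_direct_cross_product(self):
        d = np.array(
            [[0.0, 1, 2, 0, 1, 2],
             [1.0, 1, 0, 2, 1, 0],
             [2.0, 0, 1, 1, 0, 1],
             [0.0, 2, 2, 1, 2, 2]]
        )
        g = GenotypeMatrix(["a", "b", "c", "d"], [f"m{j}" for j in range(6)],
                           d, Encoding.ZERO_1_2)
        K = kinship_matrix(g)
        p = d.mean(axis=0) / 2
        W = d - 2 * p
        c = 2 * float((p * (1 - p)).sum())
        np.testing.assert_allclose(K.K, W @ W.T / c, atol=1e-12)
        assert K.scale_constant == pytest.approx(c)

    def test_hardy_weinberg_large_sample_limits(self):
        g = simulate_genotypes(500, 2000, maf_range=(0.1, 0.5), seed=11)
        K = kinship_matrix(g).K
        n = K.shape[0]
        off = (K.sum() - np.trace(K)) / (n * (n - 1))
        assert abs(off) < 0.02
        assert abs(np.diag(K).mean() - 1.0) < 0.05

    def test_monomorphic_markers_excluded(self):
        d = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0]])
        K = kinship_matrix(GenotypeMatrix(["a", "b", "c"], ["mono", "poly"],
                                          d, Encoding.ZERO_1_2))
        assert K.marker_ids == ["poly"]

    def test_all_monomorphic_rejected(self):
        d = np.array([[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(DegenerateGenotypesError):
            kinship_matrix(GenotypeMatrix(["a", "b"], ["m1", "m2"], d,
                                          Encoding.ZERO_1_2))


class TestRestrictedLogLikelihood:
    def test_two_individuals_closed_form(self):
        xi = np.array([0.8])
        eta = np.array([1.3])
        lam = 2.0
        sigma = eta[0] ** 2 / (xi[0] + lam)
        expected = -0.5 * (math.log(2 * math.pi * sigma)
                           + math.log(xi[0] + lam) + 1.0)
        assert restricted_log_likelihood(lam, xi, eta) == pytest.approx(expected)

    def test_invariant_to_phenotype_shift(self, small_population):
        g, _, y = small_population
        K = kinship_matrix(g)
        yv = np.array([y.values[i] for i in K.individual_ids])
        xi, eta = project_spectrum(K.K, yv)
        xi2, eta2 = project_spectrum(K.K, yv + 42.0)
        for lam in (0.1, 1.0, 10.0):
            assert restricted_log_likelihood(lam, xi, eta) == pytest.approx(
                restricted_log_likelihood(lam, xi2, eta2), abs=1e-8)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            restricted_log_likelihood(0.0, np.array([1.0]), np.array([1.0]))


class TestFitGblup:
    def test_h2_is_variance_ratio_and_invariants(self, small_population):
        g, _, y = small_population
        K = kinship_matrix(g)
        fit = fit_gblup(y, K)
        assert fit.h2 == fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2)
        assert 0.0 <= fit.h2 <= 1.0
        gebv = np.array([fit.gebvs[i] for i in fit.individual_ids])
        yv = np.array([y.values[i] for i in fit.individual_ids])
        sd = yv.std()
        assert abs(gebv.sum()) <= 1e-6 * len(yv) * sd
        resid = np.array([fit.residuals[i] for i in fit.individual_ids])
        np.testing.assert_allclose(yv, fit.mu + gebv + resid, atol=1e-10)

    def test_spectral_optimum_matches_dense_grid(self):
        """The spectral REML optimum attains the dense explicit-inverse
        restricted likelihood's grid maximum (2001 points, n <= 30)."""
        g = simulate_genotypes(25, 80, seed=21)
        pop = simulate_phenotypes(g, 10, 0.5, seed=22)
        y = _adjusted(pop.phenotypes)
        K = kinship_matrix(g)
        fit = fit_gblup(y, K)
        yv = np.array([y.values[i] for i in K.individual_ids])
        grid = np.exp(np.linspace(-20, 20, 2001))
        dense = [dense_reml_loglik(l, K.K, yv) for l in grid]
        assert dense_reml_loglik(fit.lam, K.K, yv) >= max(dense) - 1e-6

    def test_scale_equivariance(self, small_population):
        g, _, y = small_population
        K = kinship_matrix(g)
        fit = fit_gblup(y, K)
        s = 3.7
        y2 = _adjusted({k: s * v for k, v in y.values.items()})
        fit2 = fit_gblup(y2, K)
        assert fit2.lam == pytest.approx(fit.lam, rel=1e-4)
        assert fit2.h2 == pytest.approx(fit.h2, abs=1e-6)
        assert fit2.sigma_g2 == pytest.approx(s ** 2 * fit.sigma_g2, rel=1e-4)
        assert fit2.sigma_e2 == pytest.approx(s ** 2 * fit.sigma_e2, rel=1e-4)
        for i in fit.gebvs:
            assert fit2.gebvs[i] == pytest.approx(s * fit.gebvs[i], abs=1e-6)

    def test_id_mismatch_rejected(self, small_population):
        g, _, y = small_population
        K = kinship_matrix(g)
        bad = _adjusted({**y.values, "phantom": 1.0})
        with pytest.raises(AlignmentError):
            fit_gblup(bad, K)


class TestMarkerEffects:
    def test_ridge_backsolve_reproduces_gebvs(self, small_population):
        g, _, y = small_population
        K = kinship_matrix(g)
        fit = fit_gblup(y, K)
        eff = marker_effects(fit, g, K)
        W = centered_dosages(g.subset_individuals(fit.individual_ids),
                             eff.centering_frequencies)
        u = np.array([eff.effects[m] for m in eff.centering_frequencies])
        gebv = np.array([fit.gebvs[i] for i in fit.individual_ids])
        assert np.abs(W @ u - gebv).max() < 1e-8

    def test_monomorphic_marker_has_no_effect(self):
        d = np.hstack([np.ones((6, 1)),
                       simulate_genotypes(6, 20, seed=31).dosage])
        g = GenotypeMatrix([f"i{k}" for k in range(6)],
                           ["mono"] + [f"m{j}" for j in range(20)], d,
                           Encoding.ZERO_1_2)
        pop = simulate_phenotypes(g, 5, 0.5, seed=32)
        K = kinship_matrix(g)
        fit = fit_gblup(_adjusted(pop.phenotypes), K)
        eff = marker_effects(fit, g, K)
        assert "mono" not in eff.effects

    def test_duplicated_marker_columns_share_one_effect(self):
        base = simulate_genotypes(30, 40, seed=33)
        d = np.hstack([base.dosage, base.dosage[:, :1]])
        g = GenotypeMatrix(base.individual_ids,
                           base.marker_ids + ["m0001_copy"], d,
                           Encoding.ZERO_1_2)
        pop = simulate_phenotypes(g, 10, 0.5, seed=34)
        K = kinship_matrix(g)
        fit = fit_gblup(_adjusted(pop.phenotypes), K)
        eff = marker_effects(fit, g, K)
        assert eff.effects["m0001_copy"] == pytest.approx(
            eff.effects["m0001"], abs=1e-10)
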