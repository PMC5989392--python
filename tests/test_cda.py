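import numpy as np
import pytest

from cdascan import DOMINANT, GENOTYPIC, PhenotypeVector
from cdascan.cda import (CdaParameters, Penalizers, bayes_predict,
                         conditional_site_prob, cross_validate, fit_cda,
                         hamiltonian, kfold_indices, make_ygrid,
                         optimize_penalizers, penalized_gradient,
                         predict_phenotypes, pseudo_loglikelihood)


def _random_params(m, L, rng, scale=0.4):
    p = CdaParameters.zeros(m, L)
    p.h[:, :, 1:] = rng.normal(0, scale, size=(2, m, L - 1))
    for i in range(m):
        for j in range(i + 1, m):
            blk = rng.normal(0, scale, size=(2, L - 1, L - 1))
            p.J[:, i, j, 1:, 1:] = blk
            p.J[:, j, i, 1:, 1:] = np.swapaxes(blk, 1, 2)
    return p


class TestHamiltonian:
    def test_zero_parameters_give_zero(self):
        p = CdaParameters.zeros(3, 2)
        assert hamiltonian([1, 0, 1], 2.3, p) == 0.0

    def test_hand_computed_value(self):
        # H = h0_1(1) + y*(h1_1(1) + J1_12(1,1)) = 0.5 + 1*(1.0 + 0.2)
        p = CdaParameters.zeros(2, 2)
        p.h[0, 0, 1] = 0.5
        p.h[1, 0, 1] = 1.0
        p.J[1, 0, 1, 1, 1] = 0.2
        p.J[1, 1, 0, 1, 1] = 0.2
        assert hamiltonian([1, 1], 1.0, p) == pytest.approx(1.7)

    def test_reference_genotype_has_zero_energy(self, rng):
        p = _random_params(4, 3, rng)
        assert hamiltonian([0, 0, 0, 0], 1.7, p) == 0.0


class TestSiteConditionals:
    @pytest.mark.parametrize("L,expected", [(2, 0.5), (3, 1 / 3)])
    def test_uniform_at_zero_parameters(self, L, expected):
        p = CdaParameters.zeros(3, L)
        for a in range(L):
            assert conditional_site_prob(1, a, [0, 0, 0], 0.4, p) == \
                pytest.approx(expected)

    def test_hand_computed_logistic(self):
        p = CdaParameters.zeros(1, 2)
        p.h[0, 0, 1] = np.log(2.0)
        assert conditional_site_prob(0, 1, [0], 0.9, p) == pytest.approx(2 / 3)

    def test_normalizes_over_levels(self, rng):
        p = _random_params(4, 3, rng)
        tot = sum(conditional_site_prob(2, a, [1, 2, 0, 1], -0.7, p)
                  for a in range(3))
        assert tot == pytest.approx(1.0, abs=1e-12)


class TestPseudoLikelihood:
    def test_uniform_model_value(self, rng):
        n, m = 17, 4
        G = rng.integers(0, 3, size=(n, m))
        y = rng.normal(size=n)
        p = CdaParameters.zeros(m, 3)
        ll = pseudo_loglikelihood(G, y, p, Penalizers(1.0, 1.0), GENOTYPIC)
        assert ll == pytest.approx(n * m * np.log(1 / 3))

    def test_penalty_decreases_objective(self, rng):
        n, m = 25, 3
        G = rng.integers(0, 2, size=(n, m))
        y = rng.normal(size=n)
        p = _random_params(m, 2, rng)
        weak = pseudo_loglikelihood(G, y, p, Penalizers(1e-8, 1e-8), DOMINANT)
        strong = pseudo_loglikelihood(G, y, p, Penalizers(5.0, 5.0), DOMINANT)
        assert strong < weak

    def test_single_site_value_from_conditional(self):
        p = CdaParameters.zeros(1, 2)
        p.h[0, 0, 1] = np.log(2.0)
        ll = pseudo_loglikelihood(np.array([[1]]), np.array([0.3]), p,
                                  Penalizers(1e-12, 1e-12), DOMINANT)
        assert ll == pytest.approx(np.log(2 / 3), abs=1e-6)

    @pytest.mark.parametrize("encoding", [DOMINANT, GENOTYPIC])
    def test_gradient_matches_finite_differences(self, encoding, rng):
        L = encoding.n_levels
        n, m = 30, 4
        G = rng.integers(0, L, size=(n, m))
        y = rng.normal(size=n)
        p = _random_params(m, L, rng)
        pen = Penalizers(0.7, 0.3)
        grad = penalized_gradient(G, y, p, pen, encoding)
        eps = 1e-5
        for _ in range(8):
            l, i = rng.integers(0, 2), rng.integers(0, m)
            a = rng.integers(1, L)
            pp, pm = p.copy(), p.copy()
            pp.h[l, i, a] += eps
            pm.h[l, i, a] -= eps
            fd = (pseudo_loglikelihood(G, y, pp, pen, encoding)
                  - pseudo_loglikelihood(G, y, pm, pen, encoding)) / (2 * eps * n)
            assert grad.h[l, i, a] == pytest.approx(fd, abs=1e-7)

    def test_infinite_lambda2_freezes_couplings(self, rng):
        n, m = 30, 4
        G = rng.integers(0, 2, size=(n, m))
        y = rng.normal(size=n)
        p = CdaParameters.zeros(m, 2)
        grad = penalized_gradient(G, y, p, Penalizers(0.5, np.inf), DOMINANT)
        assert np.all(grad.J == 0)


class TestFit:
    def test_zero_reference_preserved(self, strong_cohort):
        g, pheno, _ = strong_cohort
        fitted = fit_cda(g, pheno, Penalizers(0.1, 0.1), DOMINANT)
        fitted.validate_convention()
        assert fitted.converged

    def test_deterministic(self, strong_cohort):
        g, pheno, _ = strong_cohort
        a = fit_cda(g, pheno, Penalizers(0.5, 0.5), DOMINANT)
        b = fit_cda(g, pheno, Penalizers(0.5, 0.5), DOMINANT)
        np.testing.assert_array_equal(a.h, b.h)
        np.testing.assert_array_equal(a.J, b.J)

    def test_penalty_dominated_limit_suppresses_signal_block(self, strong_cohort):
        g, pheno, _ = strong_cohort
        fitted = fit_cda(g, pheno, Penalizers(50.0, 50.0), DOMINANT)
        assert np.max(np.abs(fitted.h[1])) < 0.05
        assert np.max(np.abs(fitted.J[1])) < 0.05


class TestBayesPredict:
    def test_no_signal_returns_marginal_mean(self, rng):
        p = CdaParameters.zeros(3, 2)
        p.h[0, :, 1] = rng.normal(size=3)  # phenotype-independent only
        grid = make_ygrid(0.7, 2.0)
        assert bayes_predict([1, 0, 1], p, (0.7, 2.0), grid) == \
            pytest.approx(0.7, abs=1e-9)

    def test_matches_fine_quadrature_oracle(self, rng):
        p = _random_params(1, 2, rng, scale=0.8)
        mu, s2 = 0.2, 1.3
        ys = np.linspace(mu - 6 * np.sqrt(s2), mu + 6 * np.sqrt(s2), 20001)
        # independent oracle: direct trapezoidal integration of Eq-style
        # posterior for the m=1 model
        v = p.h[0, 0, 1] + ys * p.h[1, 0, 1]
        log_pa = v - np.logaddexp(0, v)  # Pr(a=1|y)
        logw = log_pa - 0.5 * (ys - mu) ** 2 / s2
        w = np.exp(logw - logw.max())
        oracle = np.trapezoid(ys * w, ys) / np.trapezoid(w, ys)
        grid = make_ygrid(mu, s2, span=6.0, n_points=20001)
        got = bayes_predict([1], p, (mu, s2), grid)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_grid_refinement_stable(self, rng):
        p = _random_params(3, 2, rng)
        mu, s2 = 0.0, 1.0
        a = [1, 0, 1]
        y1 = bayes_predict(a, p, (mu, s2), make_ygrid(mu, s2, n_points=101))
        y2 = bayes_predict(a, p, (mu, s2), make_ygrid(mu, s2, n_points=201))
        assert abs(y1 - y2) < 1e-4

    def test_invariant_to_constant_energy_shift(self, rng):
        # adding the same constant to every level of a site's field cancels
        p = _random_params(3, 2, rng)
        shifted = p.copy()
        shifted.h[0, 1, :] += 3.7
        grid = make_ygrid(0.0, 1.0)
        G = rng.integers(0, 2, size=(6, 3))
        np.testing.assert_allclose(
            predict_phenotypes(G, p, (0.0, 1.0), grid),
            predict_phenotypes(G, shifted, (0.0, 1.0), grid), atol=1e-10)


class TestCrossValidation:
    def test_fold_sizes_and_coverage(self):
        folds = kfold_indices(100, 5, seed=3)
        assert [len(f) for f in folds] == [20] * 5
        assert sorted(np.concatenate(folds)) == list(range(100))

    def test_null_score_near_zero(self, null_cohort, rng):
        g, pheno, _ = null_cohort
        yperm = PhenotypeVector(rng.permutation(pheno.y))
        res = cross_validate(g, yperm, Penalizers(1.0, 1.0), DOMINANT, seed=5)
        assert abs(res.R) < 3 / np.sqrt(pheno.n)

    def test_signal_beats_heavy_penalty(self, strong_cohort):
        g, pheno, _ = strong_cohort
        mild = cross_validate(g, pheno, Penalizers(0.1, 0.1), DOMINANT, seed=5)
        heavy = cross_validate(g, pheno, Penalizers(100.0, 100.0), DOMINANT,
                               seed=5)
        assert mild.R > heavy.R

    def test_deterministic_given_seed(self, strong_cohort):
        g, pheno, _ = strong_cohort
        a = cross_validate(g, pheno, Penalizers(0.5, 0.5), DOMINANT, seed=9,
                           fit_full=False)
        b = cross_validate(g, pheno, Penalizers(0.5, 0.5), DOMINANT, seed=9,
                           fit_full=False)
        assert a.R == b.R
        np.testing.assert_array_equal(a.fold_predictions, b.fold_predictions)


class TestPenalizerSearch:
    def test_single_point_grid_reduces_to_cv(self, strong_cohort):
        g, pheno, _ = strong_cohort
        single = optimize_penalizers(g, pheno, grid1=[0.5], grid2=[0.5],
                                     encoding=DOMINANT, seed=4,
                                     include_no_interaction=False)
        plain = cross_validate(g, pheno, Penalizers(0.5, 0.5), DOMINANT,
                               seed=4, fit_full=False)
        assert single.R == pytest.approx(plain.R, abs=1e-12)

    def test_interaction_dominated_data_keeps_interactions(self):
        # signal carried by the coupling slope J^(1): turning interactions
        # off (lambda2 = inf) should lose on most replicates
        from cdascan.simulate import SimSpec, sample_cohort
        finite = 0
        for rep in range(3):
            spec = SimSpec(m=6, n=300, parameter_dists={
                "h0": (0.0, 0.1), "h1": (0.0, 0.01),
                "J0": (0.0, 0.1), "J1": (0.25, 0.05)}, seed=300 + rep)
            g, pheno, _ = sample_cohort(spec)
            res = optimize_penalizers(g, pheno, grid1=np.logspace(-2, 2, 3),
                                      grid2=np.logspace(-2, 2, 3),
                                      encoding=DOMINANT, seed=rep)
            finite += np.isfinite(res.penalizers.lambda2)
        assert finite >= 2
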