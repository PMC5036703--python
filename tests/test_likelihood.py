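import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import admitsem as a
from admitsem.likelihood import (
    binomial_logit_loglik,
    bivariate_latent_logpdf,
    poisson_loglik,
)


class TestBinomialKernel:
    def test_symmetric_point_value(self):
        # Z=5, N=10 at even odds: log C(10,5) + 10 log(1/2)
        expected = math.log(math.comb(10, 5)) + 10 * math.log(0.5)
        assert binomial_logit_loglik(5, 10, 0.0) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(-1.4020, abs=1e-4)

    def test_zero_successes_closed_form(self):
        # W=0, V=10 at p=0.1: 10 log(0.9)
        lp = math.log(0.1 / 0.9)
        assert binomial_logit_loglik(0, 10, lp) == pytest.approx(10 * math.log(0.9), abs=1e-6)

    def test_saturation_limit_monotone(self):
        lps = np.array([0.0, 2.0, 5.0, 10.0, 30.0])
        vals = binomial_logit_loglik(10, 10, lps)
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(0.0, abs=1e-10)

    def test_symmetry_under_sign_flip(self):
        # W = V - W is equivalent to flipping the linear predictor's sign
        assert binomial_logit_loglik(3, 10, 1.3) == pytest.approx(
            binomial_logit_loglik(7, 10, -1.3), abs=1e-10
        )

    def test_count_above_denominator_errors(self):
        with pytest.raises(ValueError):
            binomial_logit_loglik(11, 10, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(1, 500).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))),
        st.floats(-50, 50),
    )
    def test_finite_on_data_space_closure(self, nz, lp):
        n, z = nz
        val = binomial_logit_loglik(z, n, lp)
        assert np.isfinite(val) and val <= 1e-12


class TestComponentLogliks:
    def test_quality_access_code_path_equivalence(self):
        rng = np.random.default_rng(0)
        N = rng.integers(5, 50, (4, 3))
        Z = rng.binomial(N, 0.5)
        F = rng.normal(size=4)
        eff = rng.normal(size=(4, 3)) * 0.2
        icept = rng.normal(size=3)
        load = np.array([1.0, 0.7, 1.2])
        q = a.loglik_quality(Z, N, icept, load, F, eff)
        acc = a.loglik_access(Z, N, icept, load, F, eff)
        np.testing.assert_allclose(q, acc, atol=1e-12)

    def test_poisson_values(self):
        assert poisson_loglik(0, 1.0) == pytest.approx(-1.0, abs=1e-12)
        assert poisson_loglik(3, 3.0) == pytest.approx(3 * math.log(3) - 3 - math.log(6), abs=1e-12)
        assert poisson_loglik(3, 3.0) == pytest.approx(-1.4959, abs=1e-4)

    def test_outcome_saturated_bound(self):
        rng = np.random.default_rng(1)
        Y = rng.poisson(10.0, 20) + 1
        E = rng.uniform(5, 15, 20)
        best = a.loglik_outcome(Y, E, Y / E).sum()
        for _ in range(25):
            nu = np.exp(rng.normal(0, 0.5, 20))
            assert a.loglik_outcome(Y, E, nu).sum() <= best + 1e-9

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            poisson_loglik(-1, 1.0)


class TestLinearPredictor:
    def _latents(self, I, F=None, G=None):
        lat = a.LatentState.zeros(I, 2, 2)
        if F is not None:
            lat.F = np.asarray(F, dtype=float)
        if G is not None:
            lat.G = np.asarray(G, dtype=float)
        return lat

    def _params(self, **kw):
        p = a.default_study_parameters(2, 2)
        for k, v in kw.items():
            setattr(p, k, v)
        return p

    class _Cov:
        def __init__(self, I):
            self.D = np.zeros(I)
            self.Mrate = np.zeros(I)

    def test_null_reference(self):
        p = self._params(gamma0=0.0, gamma_F=0.0, gamma_D=0.0, gamma_G=0.0, gamma_M=0.0)
        nu = a.linear_predictor_nu(p, self._latents(3), self._Cov(3), 3)
        np.testing.assert_allclose(nu, 1.0, atol=1e-14)

    def test_model1_intercept_only(self):
        # published model-1 means: gamma0=0.02 at F=0 gives nu=exp(0.02)
        p = self._params(gamma0=0.02, gamma_F=-0.25)
        nu = a.linear_predictor_nu(p, self._latents(2), self._Cov(2), 1)
        np.testing.assert_allclose(nu, math.exp(0.02), atol=1e-12)
        assert nu[0] == pytest.approx(1.0202, abs=1e-4)

    def test_model3_access_risk_ratio(self):
        # two practices one unit apart in G: risk ratio exp(0.18) ~ 1.1972
        p = self._params(gamma0=0.0, gamma_F=0.0, gamma_D=0.0, gamma_M=0.0, gamma_G=0.18)
        nu = a.linear_predictor_nu(p, self._latents(2, G=[1.0, 0.0]), self._Cov(2), 3)
        assert nu[0] / nu[1] == pytest.approx(math.exp(0.18), abs=1e-12)
        assert nu[0] / nu[1] == pytest.approx(1.1972, abs=1e-4)

    def test_model_nesting(self, tiny_table):
        std, _ = a.standardize_covariates(tiny_table)
        lat = self._latents(3, F=[0.2, -0.1, 0.4], G=[0.3, 0.0, -0.2])
        lat.u = np.array([0.05, -0.02, 0.01])
        p3 = self._params(gamma_G=0.0)
        np.testing.assert_allclose(
            a.linear_predictor_nu(p3, lat, std, 3),
            a.linear_predictor_nu(p3, lat, std, 2),
            atol=1e-14,
        )
        p2 = self._params(gamma_D=0.0, gamma_M=0.0)
        np.testing.assert_allclose(
            a.linear_predictor_nu(p2, lat, std, 2),
            a.linear_predictor_nu(p2, lat, std, 1),
            atol=1e-14,
        )

    def test_anchor_loading_identifies_scale(self):
        # rescaling (F, lambda) by (c, 1/c) leaves free columns invariant but
        # moves the anchor column, so the likelihood changes: the lambda_1=1
        # constraint removes the scale non-identifiability
        rng = np.random.default_rng(2)
        p = self._params()
        N = rng.integers(20, 60, (5, 2))
        Z = rng.binomial(N, 0.7)
        F = rng.normal(0, 0.5, 5)
        eps = np.zeros((5, 2))
        c = 1.7
        p_scaled = self._params()
        p_scaled.lam = np.array([1.0, p.lam[1] / c])
        base = a.loglik_quality(Z, N, p.delta, p.lam, F, eps).sum()
        scaled = a.loglik_quality(Z, N, p_scaled.delta, p_scaled.lam, F * c, eps).sum()
        assert abs(base - scaled) > 1e-3


class TestPriors:
    def test_sign_neutrality(self):
        cfg = a.ModelConfig(model_id=3)
        p_pos = a.default_study_parameters()
        p_neg = a.default_study_parameters()
        p_pos.gamma_F, p_neg.gamma_F = 0.37, -0.37
        assert a.log_prior(p_pos, cfg) == pytest.approx(a.log_prior(p_neg, cfg), abs=1e-12)

    def test_out_of_support_returns_neg_inf(self):
        cfg = a.ModelConfig(model_id=3)
        p = a.default_study_parameters()
        p.alpha = -0.1
        assert a.log_prior(p, cfg) == -np.inf
        p = a.default_study_parameters()
        p.rho = 1.5
        assert a.log_prior(p, cfg) == -np.inf

    def test_model1_prior_ignores_access_block(self):
        p1 = a.default_study_parameters()
        p2 = a.default_study_parameters()
        p2.beta2, p2.kappa = 3.0, np.array([1.0, 9.9, 9.9, 9.9])
        cfg = a.ModelConfig(model_id=1)
        assert a.log_prior(p1, cfg) == pytest.approx(a.log_prior(p2, cfg), abs=1e-12)


class TestPointwise:
    def test_additivity_and_shapes(self, small_sim):
        table = small_sim.table
        p = a.default_study_parameters()
        lat = small_sim.latents
        pw = a.pointwise_loglik(p, lat, table, 3)
        assert pw["outcome"].shape == (40,)
        assert pw["quality"].shape == (40, 4)
        assert pw["access"].shape == (40, 4)
        total_q = a.loglik_quality(table.Z, table.N, p.delta, p.lam, lat.F, lat.eps).sum()
        assert pw["quality"].sum() == pytest.approx(total_q, abs=1e-9)

    def test_spot_check_cells_against_scalar_recomputation(self, small_sim):
        table = small_sim.table
        p = a.default_study_parameters()
        lat = small_sim.latents
        pw = a.pointwise_loglik(p, lat, table, 3)
        rng = np.random.default_rng(3)
        for _ in range(5):
            i = int(rng.integers(table.I))
            j = int(rng.integers(table.J))
            lp = p.delta[j] + p.lam[j] * lat.F[i] + lat.eps[i, j]
            prob = 1.0 / (1.0 + math.exp(-lp))
            z, n = int(table.Z[i, j]), int(table.N[i, j])
            manual = (
                math.log(math.comb(n, z)) + z * math.log(prob) + (n - z) * math.log1p(-prob)
            )
            assert pw["quality"][i, j] == pytest.approx(manual, rel=1e-9)

    def test_likelihood_dominance_at_truth(self):
        # the generating parameters beat a perturbed copy on average
        wins = 0
        for seed in range(6):
            sim = a.simulate_practice_table(a.GeneratorConfig(I=60), seed=100 + seed)
            truth = sim.params
            pert = truth.copy()
            pert.gamma_F += 0.8
            pert.delta = pert.delta + 0.5
            ll_t = sum(v.sum() for v in a.pointwise_loglik(truth, sim.latents, sim.table, 3).values())
            ll_p = sum(v.sum() for v in a.pointwise_loglik(pert, sim.latents, sim.table, 3).values())
            wins += ll_t > ll_p
        assert wins >= 5

    def test_dimension_mismatch_errors(self, small_sim):
        p = a.default_study_parameters()
        lat = a.LatentState.zeros(10, 4, 4)
        with pytest.raises(ValueError):
            a.pointwise_loglik(p, lat, small_sim.table, 3)


def test_bivariate_logpdf_matches_scipy():
    from scipy.stats import multivariate_normal

    rng = np.random.default_rng(4)
    F, G = rng.normal(size=5), rng.normal(size=5)
    sF, sG, rho = 0.7, 1.3, -0.45
    cov = np.array([[sF**2, rho * sF * sG], [rho * sF * sG, sG**2]])
    ours = bivariate_latent_logpdf(F, G, 0.1, -0.2, sF, sG, rho, np.ones(5))
    ref = multivariate_normal([0.1, -0.2], cov).logpdf(np.c_[F, G])
    np.testing.assert_allclose(ours, ref, atol=1e-10)
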