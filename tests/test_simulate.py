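import dataclasses

import numpy as np
import pytest
from scipy import stats

import admitsem as a
from admitsem.simulate import generate_covariates, generate_indicators, generate_latents, generate_outcome


def _zeroed_structure(**over):
    """Study defaults with structural covariate paths switched off."""
    p = a.default_study_parameters()
    p.beta1 = p.beta2 = p.beta3 = p.beta4 = 0.0
    for k, v in over.items():
        setattr(p, k, v)
    return p


class TestDeterminism:
    def test_identical_seed_identical_tables(self):
        cfg = a.GeneratorConfig(I=25)
        s1 = a.simulate_practice_table(cfg, seed=5)
        s2 = a.simulate_practice_table(cfg, seed=5)
        np.testing.assert_array_equal(s1.table.Z, s2.table.Z)
        np.testing.assert_array_equal(s1.table.Y, s2.table.Y)
        np.testing.assert_array_equal(s1.latents.F, s2.latents.F)

    def test_different_seed_differs(self):
        cfg = a.GeneratorConfig(I=25)
        assert not np.array_equal(
            a.simulate_practice_table(cfg, seed=5).table.Z,
            a.simulate_practice_table(cfg, seed=6).table.Z,
        )


class TestLatents:
    def test_independent_when_rho_zero(self):
        cfg = a.GeneratorConfig(I=20_000, true_params=_zeroed_structure(rho=0.0))
        rng = np.random.default_rng(1)
        _, std = generate_covariates(cfg, rng)
        F, G, _ = generate_latents(cfg, std, rng)
        assert abs(np.corrcoef(F, G)[0, 1]) < 0.02

    def test_correlation_recovers_study_value(self):
        # rho = -0.38 at I = 50,000 should be recovered within +-0.01
        cfg = a.GeneratorConfig(I=50_000, true_params=_zeroed_structure())
        rng = np.random.default_rng(2)
        _, std = generate_covariates(cfg, rng)
        F, G, omega = generate_latents(cfg, std, rng)
        assert np.all(omega == 1.0)
        assert abs(np.corrcoef(F, G)[0, 1] - (-0.38)) < 0.01
        # moment recovery: marginal SDs match the generative scales
        p = cfg.true_params
        assert abs(F.std() - p.sigma_F) < 3 * p.sigma_F / np.sqrt(2 * cfg.I)
        assert abs(G.std() - p.sigma_G) < 3 * p.sigma_G / np.sqrt(2 * cfg.I)

    def test_student_t_has_heavier_tails(self):
        truth = _zeroed_structure()
        rng_n = np.random.default_rng(3)
        rng_t = np.random.default_rng(3)
        cfg_n = a.GeneratorConfig(I=50_000, true_params=truth, factor_family="normal")
        cfg_t = a.GeneratorConfig(I=50_000, true_params=truth, factor_family="student_t")
        _, std = generate_covariates(cfg_n, np.random.default_rng(0))
        Fn, _, _ = generate_latents(cfg_n, std, rng_n)
        Ft, _, om = generate_latents(cfg_t, std, rng_t)
        assert np.any(om != 1.0)
        assert stats.kurtosis(Ft) > stats.kurtosis(Fn) + 1.0

    def test_bad_covariance_rejected(self):
        cfg = a.GeneratorConfig(I=10)
        cfg.true_params.sigma_F = -1.0
        with pytest.raises(ValueError, match="positive definite"):
            generate_latents(cfg, {"D": np.zeros(10), "S1": np.zeros(10), "S2": np.zeros(10)}, np.random.default_rng(0))


class TestIndicators:
    def test_rate_half_at_null_parameters(self):
        p = _zeroed_structure(sigma_F=1e-8, sigma_G=1e-8)
        p.delta = np.zeros(4)
        p.sigma = np.zeros(4)
        cfg = a.GeneratorConfig(I=4000, true_params=p)
        rng = np.random.default_rng(4)
        _, std = generate_covariates(cfg, rng)
        F, G, _ = generate_latents(cfg, std, rng)
        Z, N, *_ = generate_indicators(cfg, F, G, rng)
        assert abs(Z.sum() / N.sum() - 0.5) < 0.005

    def test_overall_rate_matches_intercept(self):
        # delta_1 = logit(0.921) with a negligible factor contribution
        # reproduces the published 92.1% overall blood-pressure rate
        p = _zeroed_structure(sigma_F=1e-8, sigma_G=1e-8)
        p.sigma = np.zeros(4)
        cfg = a.GeneratorConfig(I=2000, true_params=p)
        rng = np.random.default_rng(5)
        _, std = generate_covariates(cfg, rng)
        F, G, _ = generate_latents(cfg, std, rng)
        Z, N, *_ = generate_indicators(cfg, F, G, rng)
        assert abs(Z[:, 0].sum() / N[:, 0].sum() - 0.921) < 0.005

    def test_logit_noise_overdisperses_counts(self):
        def dispersion(sigma_val, seed):
            p = _zeroed_structure(sigma_F=1e-8, sigma_G=1e-8)
            p.sigma = np.full(4, sigma_val)
            cfg = a.GeneratorConfig(I=500, true_params=p)
            rng = np.random.default_rng(seed)
            _, std = generate_covariates(cfg, rng)
            F, G, _ = generate_latents(cfg, std, rng)
            Z, N, *_ = generate_indicators(cfg, F, G, rng)
            phat = Z[:, 0].sum() / N[:, 0].sum()
            resid = (Z[:, 0] - N[:, 0] * phat) ** 2 / (N[:, 0] * phat * (1 - phat))
            return resid.mean()

        assert dispersion(0.0, 6) < 1.5
        assert dispersion(0.3, 6) > 2.0


class TestOutcome:
    def test_null_model_rate_ratio_one(self):
        p = dataclasses.replace(_zeroed_structure(), gamma0=0.0, gamma_F=0.0, gamma_D=0.0,
                                gamma_G=0.0, gamma_M=0.0, alpha=0.0)
        cfg = a.GeneratorConfig(I=4000, true_params=p)
        rng = np.random.default_rng(7)
        E = np.full(4000, 50.0)
        zeros = np.zeros(4000)
        Y, _ = generate_outcome(cfg, zeros, zeros, {"D": zeros, "Mrate": zeros}, E, rng)
        assert abs((Y / E).mean() - 1.0) < 0.01

    def test_quality_effect_scales_risk(self):
        # gamma_F = -0.25 at F = 1 gives nu = exp(-0.25) ~ 0.7788
        p = dataclasses.replace(_zeroed_structure(), gamma0=0.0, gamma_F=-0.25, gamma_D=0.0,
                                gamma_G=0.0, gamma_M=0.0, alpha=0.0)
        cfg = a.GeneratorConfig(I=4000, true_params=p)
        rng = np.random.default_rng(8)
        E = np.full(4000, 100.0)
        zeros = np.zeros(4000)
        Y, _ = generate_outcome(cfg, np.ones(4000), zeros, {"D": zeros, "Mrate": zeros}, E, rng)
        assert abs((Y / E).mean() - np.exp(-0.25)) < 0.01

    def test_log_normal_effect_inflates_variance(self):
        def spread(alpha, seed):
            p = dataclasses.replace(_zeroed_structure(), gamma0=0.0, gamma_F=0.0, gamma_D=0.0,
                                    gamma_G=0.0, gamma_M=0.0, alpha=alpha)
            cfg = a.GeneratorConfig(I=3000, true_params=p)
            rng = np.random.default_rng(seed)
            E = np.full(3000, 2000.0)
            zeros = np.zeros(3000)
            Y, _ = generate_outcome(cfg, zeros, zeros, {"D": zeros, "Mrate": zeros}, E, rng)
            return np.var(np.log(Y / E))

        assert spread(0.14, 9) > 2.0 * spread(0.0, 9)


class TestCrosswalkGeneration:
    def test_study_dimensions(self):
        xw = a.generate_crosswalk(a.GeneratorConfig(I=90), L=260, seed=10)
        assert xw.weights.shape == (260, 90)
        np.testing.assert_allclose(xw.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_single_practice_gets_all_weight(self):
        xw = a.generate_crosswalk(a.GeneratorConfig(I=2), L=3, seed=11, max_serving=1)
        assert np.all(xw.weights.max(axis=1) == 1.0)

    def test_row_sums_any_seed(self):
        for seed in (0, 1, 99):
            xw = a.generate_crosswalk(a.GeneratorConfig(I=13), L=17, seed=seed)
            np.testing.assert_allclose(xw.weights.sum(axis=1), 1.0, atol=1e-9)
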