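import math

import numpy as np
import pytest
from scipy import stats

from ebcal import simulate as sim
from ebcal.simulate import (
    ErrorSpec,
    GeneratorConfig,
    MixtureSpec,
    WithinPersonSpec,
    approximate_sigma_y_truth,
    assemble_dataset,
    bias_mee,
    bias_mes,
    simulate_covariates,
    simulate_errors,
    simulate_latents,
)


class TestCovariates:
    def test_marginals_at_n300(self):
        cov = simulate_covariates(300, seed=0)
        # binomial 3.5 sigma bound: 0.5 +/- 3.5 * 0.5 / sqrt(300)
        assert 0.38 <= cov.gender.mean() <= 0.62
        assert cov.age.min() >= 20 and cov.age.max() <= 40

    def test_bmi_clt_bound(self):
        cov = simulate_covariates(100_000, seed=1)
        assert abs(cov.bmi.mean() - 27) < 0.06  # 3.5 * 5 / sqrt(1e5)
        assert abs(cov.bmi.std() - 5) < 0.1

    def test_single_row(self):
        cov = simulate_covariates(1, seed=2)
        assert cov.n == 1
        assert 20 <= cov.age[0] <= 40
        assert cov.gender[0] in (0.0, 1.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            simulate_covariates(0, seed=0)


class TestLatents:
    def test_pooled_correlation_matches_target(self):
        spec = MixtureSpec.calibrated(counts=(40_000,) * 5)
        lat = simulate_latents(spec, seed=3)
        assert np.corrcoef(lat.x_ee, lat.x_ei)[0, 1] == pytest.approx(0.4376, abs=0.01)

    def test_population_corr_is_exact(self):
        assert MixtureSpec.calibrated().population_corr() == pytest.approx(
            0.4376, abs=1e-12
        )

    def test_balance_identity_exact(self):
        lat = simulate_latents(MixtureSpec.calibrated(), seed=4)
        np.testing.assert_array_equal(lat.x_ei - lat.x_ee - lat.x_es, 0.0)

    def test_component_counts(self):
        spec = MixtureSpec.calibrated(counts=(10, 20, 30, 40, 50))
        assert simulate_latents(spec, seed=5).n == 150

    def test_high_df_limit_recovers_scale_matrix(self):
        # single component, df -> inf: sample covariance -> scale * df/(df-2)
        scale = np.array([[90000.0, 10000.0], [10000.0, 90000.0]])
        spec = MixtureSpec(
            locations=np.array([[2500.0, 2500.0]]),
            scale=scale,
            df=1e6,
            counts=(200_000,),
        )
        lat = simulate_latents(spec, seed=6)
        cov = np.cov(np.column_stack([lat.x_ee, lat.x_ei]).T)
        np.testing.assert_allclose(cov, scale, rtol=0.02)

    def test_rejects_non_pd_scale(self):
        with pytest.raises(ValueError, match="positive definite"):
            MixtureSpec(
                locations=np.zeros((1, 2)),
                scale=np.array([[1.0, 2.0], [2.0, 1.0]]),
                counts=(10,),
            )


class TestBiasFunctions:
    def test_mee_at_inflection(self):
        # 2 * 2200 - 4000 / 2
        assert bias_mee(2200.0) == pytest.approx(2400.0)

    def test_mee_lower_asymptote(self):
        assert bias_mee(-1e6) == pytest.approx(-2e6, rel=1e-9)

    def test_mee_table_consistency(self):
        # observed device mean for a male, BMI 28.6, age 20.5 with true EE 2199.25
        z_effect = 300.0 + 14.0 * 28.6 - 7.0 * 20.5
        assert bias_mee(2199.25) + z_effect == pytest.approx(2956, abs=2)

    def test_mes_at_inflection(self):
        # 1000 / 2 + 2000
        assert bias_mes(2000.0) == pytest.approx(2500.0)

    def test_mes_is_identity_far_below(self):
        assert bias_mes(0.0) == pytest.approx(0.0, abs=1e-30)

    def test_mes_upper_asymptote(self):
        assert bias_mes(1e6) == pytest.approx(1e6 + 1000.0)

    @pytest.mark.parametrize("fn", [bias_mee, bias_mes])
    def test_nondecreasing_on_grid(self, fn):
        x = np.linspace(-5000, 6000, 50_001)
        assert np.all(np.diff(fn(x)) >= -1e-9)


class TestErrorFamilies:
    N = 1_000_000

    @pytest.mark.parametrize("family", sim.ERROR_FAMILIES)
    @pytest.mark.parametrize("sd", [250.0, 72.86])
    def test_moment_matching(self, family, sd):
        draws = simulate_errors(ErrorSpec(family, sd), self.N, seed=7)
        assert abs(draws.mean()) < 4 * sd / math.sqrt(self.N)
        assert abs(draws.std(ddof=1) - sd) < 4 * sd / math.sqrt(2 * self.N)

    def test_skew_normal_skewness_matches_closed_form(self):
        spec = ErrorSpec("skewed", 250.0, skew_shape=4.0)
        draws = simulate_errors(spec, self.N, seed=8)
        delta = 4.0 / math.sqrt(17.0)
        b = delta * math.sqrt(2 / math.pi)
        expected = (4 - math.pi) / 2 * b**3 / (1 - b**2) ** 1.5
        assert stats.skew(draws) == pytest.approx(expected, abs=0.02)

    def test_bimodal_has_two_modes(self):
        # separation 1.2 gives a genuine but shallow central dip: the
        # density ratio mode/centre is ~1.09, so compare bin masses at
        # large n rather than eyeballing a histogram
        spec = ErrorSpec("bimodal", 72.86)
        draws = simulate_errors(spec, 500_000, seed=9)
        mu, sigma0 = spec._bimodal_params()
        near_zero = np.mean(np.abs(draws) < 0.15 * sigma0)
        near_mode = np.mean(np.abs(draws - mu) < 0.15 * sigma0)
        assert near_mode > 1.02 * near_zero

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ErrorSpec("cauchy", 10.0)

    def test_zero_sd_gives_zeros(self):
        np.testing.assert_array_equal(
            simulate_errors(ErrorSpec("normal", 0.0), 5, seed=0), np.zeros(5)
        )


class TestAssembleDataset:
    def test_shapes(self):
        cfg = sim.default_config(n_replicates=4, seed=10)
        d = assemble_dataset(cfg)
        for arr in (d.w_ee, d.w_es, d.y_ee, d.y_es):
            assert arr.shape == (300, 4)
            assert np.all(np.isfinite(arr))

    def test_two_replicates(self):
        cfg = sim.default_config(n_replicates=2, seed=10)
        assert assemble_dataset(cfg).w_ee.shape == (300, 2)

    def test_degenerate_noise_recovers_means_exactly(self):
        cfg = GeneratorConfig(
            sd_u_ee=0.0,
            sd_u_es=0.0,
            sd_eps_ee=0.0,
            sd_eps_es=0.0,
            within=WithinPersonSpec(sd_ee=0.0, sd_es=0.0, corr=0.0),
            seed=11,
        )
        d = assemble_dataset(cfg)
        np.testing.assert_array_equal(d.w_ee, d.latents.x_ee[:, None] * np.ones((1, 4)))
        z = d.covariates.matrix
        expected_y = bias_mee(d.latents.x_ee) + z @ np.array([300.0, 14.0, -7.0])
        np.testing.assert_allclose(d.y_ee, expected_y[:, None] * np.ones((1, 4)))

    def test_gold_standard_unbiased(self):
        cfg = sim.default_config(seed=12)
        resid = np.concatenate(
            [
                assemble_dataset(sim.default_config(seed=12 + s)).w_ee
                - assemble_dataset(sim.default_config(seed=12 + s)).latents.x_ee[:, None]
                for s in range(5)
            ]
        )
        # MC bound: 4 * 250 / sqrt(n_draws)
        assert abs(resid.mean()) < 4 * 250 / math.sqrt(resid.size)

    def test_seed_reproducibility_bitwise(self):
        cfg = sim.default_config(seed=13)
        d1, d2 = assemble_dataset(cfg), assemble_dataset(cfg)
        np.testing.assert_array_equal(d1.w_ee, d2.w_ee)
        np.testing.assert_array_equal(d1.y_es, d2.y_es)
        np.testing.assert_array_equal(d1.latents.x_ee, d2.latents.x_ee)

    def test_total_gold_standard_error_sds(self):
        cfg = sim.default_config()
        assert cfg.sigma_w_ee_total == pytest.approx(250.0)
        assert cfg.sigma_w_es_total == pytest.approx(72.86)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sum to n_subjects"):
            GeneratorConfig(n_subjects=299)


class TestSigmaYTruth:
    def test_no_propagation_when_delta_zero(self):
        cfg = GeneratorConfig(
            within=WithinPersonSpec(sd_ee=1e-9, sd_es=1e-9, corr=0.0), seed=14
        )
        sd_ee, sd_es = approximate_sigma_y_truth(cfg, n_datasets=200, seed=1)
        assert sd_ee == pytest.approx(cfg.sd_eps_ee, rel=0.01)
        assert sd_es == pytest.approx(cfg.sd_eps_es, rel=0.01)

    def test_default_config_hits_frozen_truths(self):
        sd_ee, sd_es = approximate_sigma_y_truth(
            sim.default_config(), n_datasets=300, seed=2
        )
        assert sd_ee == pytest.approx(sim.SIGMA_Y_EE_STAR, abs=2.5)
        assert sd_es == pytest.approx(sim.SIGMA_Y_ES_STAR, abs=2.5)

    def test_linear_channel_adds_variances(self):
        # dES channel is effectively linear (identity) far below the sigmoid,
        # so the residual sd is close to sqrt(sd_delta^2 + sd_eps^2)
        cfg = sim.default_config()
        _, sd_es = approximate_sigma_y_truth(cfg, n_datasets=300, seed=3)
        expected = math.sqrt(cfg.within.sd_es**2 + cfg.sd_eps_es**2)
        assert sd_es == pytest.approx(expected, rel=0.02)
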