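import numpy as np
import pytest

from ebcal import simulate as sim
from ebcal.bspline import is_monotone
from ebcal.models import LMEMSpec, MeasurementDataset, SMEMNSpec, SMEMSpec
from ebcal.samplers import ChainConfig, rjmcmc_fit
from ebcal.samplers.rjmcmc import knot_move_probs, rj_log_prior_ratio

from conftest import small_generator


class TestMoveProbabilities:
    def test_death_disabled_at_zero_knots(self):
        cfg = ChainConfig(n_iterations=10, burn_in=5)
        pb, pd, pm = knot_move_probs(0, cfg)
        assert pd == 0.0
        assert pb == pytest.approx(0.70)
        assert pb + pd + pm == pytest.approx(1.0)

    def test_birth_disabled_at_cap(self):
        cfg = ChainConfig(n_iterations=10, burn_in=5, k_max=5)
        pb, pd, pm = knot_move_probs(5, cfg)
        assert pb == 0.0
        assert pd == pytest.approx(0.70)

    def test_interior_mix(self):
        cfg = ChainConfig(n_iterations=10, burn_in=5)
        assert knot_move_probs(3, cfg) == pytest.approx((0.35, 0.35, 0.30))


class TestAcceptanceRatioAlgebra:
    @pytest.mark.parametrize("k", [0, 1, 2, 5, 10])
    def test_birth_death_antisymmetry(self, k):
        """A birth at k and the matching death at k+1 cancel exactly.

        With the likelihood term removed (it is trivially antisymmetric in
        (ssr, ssr')), the prior x proposal part of the log acceptance
        ratios must sum to zero — the detailed-balance identity of the
        dimension jump.
        """
        cfg = ChainConfig(n_iterations=10, burn_in=5)
        up = rj_log_prior_ratio("birth", k, cfg, lam=1.0)
        down = rj_log_prior_ratio("death", k + 1, cfg, lam=1.0)
        assert up + down == pytest.approx(0.0, abs=1e-12)

    def test_move_is_symmetric(self):
        cfg = ChainConfig(n_iterations=10, burn_in=5)
        assert rj_log_prior_ratio("move", 3, cfg, lam=1.0) == 0.0

    def test_poisson_prior_penalises_growth(self):
        cfg = ChainConfig(n_iterations=10, burn_in=5)
        # at large k, adding a knot is increasingly improbable a priori
        assert rj_log_prior_ratio("birth", 10, cfg, lam=1.0) < rj_log_prior_ratio(
            "birth", 1, cfg, lam=1.0
        )


def _linear_dataset(seed=0, n=100, j=4, noise=5.0):
    """Data whose device channels are exactly linear in the latent value."""
    rng = np.random.default_rng(seed)
    x_ee = rng.uniform(2000, 3000, size=n)
    x_es = rng.uniform(-300, 300, size=n)
    z = np.column_stack(
        [rng.integers(0, 2, n), rng.normal(27, 5, n), rng.uniform(20, 40, n)]
    ).astype(float)
    gamma = np.array([50.0, 2.0, -1.0])
    w_ee = x_ee[:, None] + rng.normal(0, noise, (n, j))
    w_es = x_es[:, None] + rng.normal(0, noise, (n, j))
    y_ee = 0.5 * x_ee[:, None] + 1000 + (z @ gamma)[:, None] + rng.normal(0, noise, (n, j))
    y_es = 1.2 * x_es[:, None] - 50 + (z @ gamma)[:, None] + rng.normal(0, noise, (n, j))
    return (
        MeasurementDataset(w_ee=w_ee, w_es=w_es, y_ee=y_ee, y_es=y_es, z=z),
        x_ee,
        (1000.0, 0.5),
    )


class TestSamplerBehaviour:
    def test_linear_truth_concentrates_on_few_knots(self):
        ds, x_ee, (b0, b1) = _linear_dataset(seed=1)
        config = ChainConfig(
            n_chains=1, n_iterations=1500, burn_in=500, seed=3, spline_thin=5,
            proposal_sd_ee=3.0, proposal_sd_es=3.0,
        )
        draws = rjmcmc_fit(SMEMNSpec(), ds, config)
        assert np.median(draws.stacked("k_ee")) <= 1
        # fitted spline within 1% of the generating line across the bulk
        from ebcal.bspline import evaluate_spline

        grid = np.linspace(np.quantile(x_ee, 0.05), np.quantile(x_ee, 0.95), 50)
        preds = []
        for d in draws.spline_draws("ee")[-40:]:
            preds.append(evaluate_spline(grid, d.knots, d.beta))
        mean_pred = np.mean(preds, axis=0)
        np.testing.assert_allclose(mean_pred, b0 + b1 * grid, rtol=0.01)

    def test_every_retained_draw_is_monotone(self, smemn_fit):
        for attr in ("ee", "es"):
            for d in smemn_fit.spline_draws(attr):
                assert is_monotone(d.beta, tol=1e-8)

    def test_same_seed_is_deterministic(self):
        d = sim.assemble_dataset(small_generator(seed=8))
        ds = MeasurementDataset.from_simulated(d)
        cc = ChainConfig(n_chains=1, n_iterations=300, burn_in=100, seed=21)
        r1 = rjmcmc_fit(SMEMNSpec(), ds, cc)
        r2 = rjmcmc_fit(SMEMNSpec(), ds, cc)
        for name in r1.parameter_names():
            np.testing.assert_array_equal(r1.params[name], r2.params[name])

    def test_dp_variant_runs_and_occupies_few_clusters(self):
        d = sim.assemble_dataset(small_generator(seed=9))
        ds = MeasurementDataset.from_simulated(d)
        cc = ChainConfig(n_chains=1, n_iterations=600, burn_in=200, seed=22)
        draws = rjmcmc_fit(SMEMSpec(), ds, cc)
        assert draws.params["n_clusters"].max() <= 20
        assert float(draws.posterior_mean("sigma_wee")) > 0

    def test_two_replicate_dp_warns(self, caplog):
        d = sim.assemble_dataset(small_generator(seed=10, n_replicates=2))
        ds = MeasurementDataset.from_simulated(d)
        cc = ChainConfig(n_chains=1, n_iterations=200, burn_in=100, seed=23)
        import logging

        with caplog.at_level(logging.WARNING, logger="ebcal.samplers.rjmcmc"):
            rjmcmc_fit(SMEMSpec(), ds, cc)
        assert any("unstable" in rec.message for rec in caplog.records)

    def test_latent_acceptance_in_target_band(self, smemn_fit):
        assert 0.10 <= smemn_fit.acceptance["latent"] <= 0.55

    def test_dispatch_rejects_linear_spec(self):
        d = sim.assemble_dataset(small_generator(seed=12))
        ds = MeasurementDataset.from_simulated(d)
        with pytest.raises(TypeError, match="gibbs_fit"):
            rjmcmc_fit(LMEMSpec(), ds, ChainConfig(n_iterations=10, burn_in=5))

    def test_recovery_on_default_dataset(self, smemn_fit):
        assert float(smemn_fit.posterior_mean("sigma_wee")) == pytest.approx(250, rel=0.08)
        assert float(smemn_fit.posterior_mean("sigma_wes")) == pytest.approx(72.86, rel=0.08)
        assert float(smemn_fit.posterior_mean("sigma_yee")) == pytest.approx(405.5, rel=0.08)
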