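import math

import numpy as np
import pytest
from scipy import stats

from ebcal.bspline import KnotSet, linear_coefficients
from ebcal.models import (
    Hyperparameters,
    LMEMParams,
    LMEMSpec,
    LatentState,
    MeasurementDataset,
    NaiveModelSpec,
    NaiveParams,
    SMEMNSpec,
    SplineParams,
    choose_truncation,
    log_likelihood,
    stick_break_weights,
)


def _tiny_dataset(n=1, j=1):
    shape = (n, j)
    return MeasurementDataset(
        w_ee=np.zeros(shape),
        w_es=np.zeros(shape),
        y_ee=np.zeros(shape),
        y_es=np.zeros(shape),
        z=np.zeros((n, 3)),
    )


class TestStickBreaking:
    def test_single_stick(self):
        np.testing.assert_array_equal(stick_break_weights([1.0]), [1.0])

    def test_hand_product(self):
        np.testing.assert_allclose(stick_break_weights([0.5, 1.0]), [0.5, 0.5])

    def test_random_sticks_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = np.append(rng.uniform(0.01, 0.99, size=9), 1.0)
            pi = stick_break_weights(v)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(pi >= 0)

    def test_rejects_open_stick(self):
        with pytest.raises(ValueError, match="final"):
            stick_break_weights([0.5, 0.9])


class TestTruncation:
    def test_standard_setting(self):
        # (1/2)^H < 1e-3  =>  H = 10
        assert choose_truncation(1.0, 1e-3) == 10

    def test_loose_eps(self):
        assert choose_truncation(1.0, 0.5) == 1

    def test_monotone_in_eps(self):
        hs = [choose_truncation(1.0, eps) for eps in (0.5, 0.1, 0.01, 1e-4, 1e-8)]
        assert hs == sorted(hs)
        assert hs[-1] > hs[0]

    def test_default_truncation_is_safe(self):
        assert Hyperparameters().dp_truncation >= choose_truncation(1.0, 1e-3)


class TestLogLikelihood:
    def test_naive_peak_density(self):
        ds = _tiny_dataset()
        params = NaiveParams(
            beta0_ee=0.0, beta1_ee=1.0, gamma_ee=np.zeros(3), sigma2_yee=1.0,
            beta0_es=0.0, beta1_es=1.0, gamma_es=np.zeros(3), sigma2_yes=1.0,
        )
        # two channels, each at their mean with unit sd
        expected = 2 * (-0.5 * math.log(2 * math.pi))
        assert log_likelihood(NaiveModelSpec(), ds, params) == pytest.approx(expected)

    def test_lmem_four_peaks_plus_prior(self):
        ds = _tiny_dataset()
        mu = np.zeros(2)
        sigma_x = np.eye(2)
        params = LMEMParams(
            beta0_ee=0.0, beta1_ee=1.0, gamma_ee=np.zeros(3), sigma2_yee=1.0,
            beta0_es=0.0, beta1_es=1.0, gamma_es=np.zeros(3), sigma2_yes=1.0,
            sigma2_wee=1.0, sigma2_wes=1.0, mu=mu, sigma_x=sigma_x,
        )
        latent = LatentState(x_ee=np.zeros(1), x_es=np.zeros(1))
        expected = -2.0 * math.log(2 * math.pi) + stats.multivariate_normal.logpdf(
            [0.0, 0.0], mu, sigma_x
        )
        got = log_likelihood(LMEMSpec(), ds, params, latent)
        assert got == pytest.approx(expected)

    def test_doubling_dataset_doubles_loglik(self):
        rng = np.random.default_rng(1)
        n, j = 4, 2
        y_ee, y_es = rng.normal(size=(n, j)), rng.normal(size=(n, j))
        w = rng.normal(size=(n, j))
        z = rng.normal(size=(n, 3))
        ds = MeasurementDataset(w_ee=w, w_es=w, y_ee=y_ee, y_es=y_es, z=z)
        double = MeasurementDataset(
            w_ee=np.vstack([w, w]),
            w_es=np.vstack([w, w]),
            y_ee=np.vstack([y_ee, y_ee]),
            y_es=np.vstack([y_es, y_es]),
            z=np.vstack([z, z]),
        )
        params = NaiveParams(
            beta0_ee=0.1, beta1_ee=0.9, gamma_ee=np.ones(3) * 0.2, sigma2_yee=2.0,
            beta0_es=-0.1, beta1_es=1.1, gamma_es=np.ones(3) * -0.3, sigma2_yes=1.5,
        )
        single = log_likelihood(NaiveModelSpec(), ds, params)
        assert log_likelihood(NaiveModelSpec(), double, params) == pytest.approx(
            2 * single
        )

    def test_smemn_nests_lmem_at_linear_spline(self):
        rng = np.random.default_rng(2)
        n, j = 6, 3
        ds = MeasurementDataset(
            w_ee=rng.normal(2500, 100, size=(n, j)),
            w_es=rng.normal(0, 50, size=(n, j)),
            y_ee=rng.normal(2500, 100, size=(n, j)),
            y_es=rng.normal(0, 50, size=(n, j)),
            z=rng.normal(size=(n, 3)),
        )
        latent = LatentState(
            x_ee=rng.normal(2500, 100, size=n), x_es=rng.normal(0, 50, size=n)
        )
        mu = np.array([2500.0, 0.0])
        sigma_x = np.array([[10000.0, 500.0], [500.0, 2500.0]])
        b0e, b1e, b0s, b1s = 100.0, 0.9, -20.0, 1.1
        gee, ges = np.array([5.0, 1.0, -2.0]), np.array([-3.0, 0.5, 1.0])
        lin = LMEMParams(
            beta0_ee=b0e, beta1_ee=b1e, gamma_ee=gee, sigma2_yee=400.0,
            beta0_es=b0s, beta1_es=b1s, gamma_es=ges, sigma2_yes=100.0,
            sigma2_wee=900.0, sigma2_wes=25.0, mu=mu, sigma_x=sigma_x,
        )
        k_ee = KnotSet.from_data(latent.x_ee)
        k_es = KnotSet.from_data(latent.x_es)
        spl = SplineParams(
            knots_ee=k_ee, beta_ee=linear_coefficients(k_ee, b0e, b1e), gamma_ee=gee,
            sigma2_yee=400.0,
            knots_es=k_es, beta_es=linear_coefficients(k_es, b0s, b1s), gamma_es=ges,
            sigma2_yes=100.0,
            sigma2_wee=900.0, sigma2_wes=25.0, mu=mu, sigma_x=sigma_x,
        )
        ll_lin = log_likelihood(LMEMSpec(), ds, lin, latent)
        ll_spl = log_likelihood(SMEMNSpec(), ds, spl, latent)
        assert ll_spl == pytest.approx(ll_lin, rel=1e-10)

    def test_rejects_nonpositive_variance(self):
        ds = _tiny_dataset()
        params = NaiveParams(
            beta0_ee=0.0, beta1_ee=1.0, gamma_ee=np.zeros(3), sigma2_yee=-1.0,
            beta0_es=0.0, beta1_es=1.0, gamma_es=np.zeros(3), sigma2_yes=1.0,
        )
        with pytest.raises(ValueError, match="variance"):
            log_likelihood(NaiveModelSpec(), ds, params)


class TestHyperparameterDefaults:
    def test_stated_values(self):
        h = Hyperparameters()
        assert h.m_beta0 == 0 and h.c_beta0 == 1e5
        assert h.m_beta1 == 1 and h.c_beta1 == 1e5
        assert h.m_gamma == 0 and h.c_gamma == 1e5
        assert h.a_var == h.b_var == 0.1
        np.testing.assert_array_equal(h.iw_scale, np.eye(2))
        assert h.iw_df == 3
        assert h.m_mu == (2400.0, 0.0)
        assert h.c_mu == (1e5, 1e5)
        assert h.lambda_knots == 1.0
        assert h.dp_alpha == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            Hyperparameters(a_var=0.0)
        with pytest.raises(ValueError):
            Hyperparameters(dp_truncation=0)
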