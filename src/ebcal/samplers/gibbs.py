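"""Conditionally-conjugate Gibbs samplers for the naive and linear models.

Every full conditional is available in closed form: normal updates for the
regression coefficients, inverse-gamma for variances, a bivariate normal
for each subject's latent pair, and normal / inverse-Wishart updates for
the latent mean and covariance.
"""

from __future__ import annotations

import numpy as np

from ..models import LMEMSpec, MeasurementDataset, NaiveModelSpec
from ._random import inv_gamma_rv, inv_wishart_rv, mvn_rv
from .draws import ChainConfig, PosteriorDraws

__all__ = ["gibbs_fit"]


def gibbs_fit(spec, dataset: MeasurementDataset, config: ChainConfig) -> PosteriorDraws:
    """Posterior simulation for :class:`NaiveModelSpec` or :class:`LMEMSpec`."""
    if isinstance(spec, NaiveModelSpec):
        return _fit_naive(spec, dataset, config)
    if isinstance(spec, LMEMSpec):
        return _fit_lmem(spec, dataset, config)
    raise TypeError(f"gibbs_fit does not handle {type(spec).__name__}; use rjmcmc_fit")


def _check_design(z: np.ndarray) -> None:
    if np.any(np.ptp(z, axis=0) == 0):
        raise ValueError("constant covariate column makes the update singular")


def _coef_prior(hyper):
    """Prior mean vector and precision diagonal for (beta0, beta1, gamma)."""
    m0 = np.array([hyper.m_beta0, hyper.m_beta1] + [hyper.m_gamma] * 3)
    prec = np.array(
        [1.0 / hyper.c_beta0, 1.0 / hyper.c_beta1] + [1.0 / hyper.c_gamma] * 3
    )
    return m0, prec


def _draw_coefs(rng, xtx, xty, sigma2, m0, prior_prec):
    a = xtx / sigma2 + np.diag(prior_prec)
    rhs = xty / sigma2 + prior_prec * m0
    chol = np.linalg.cholesky(a)
    mean = np.linalg.solve(a, rhs)
    eps = np.linalg.solve(chol.T, rng.standard_normal(m0.size))
    return mean + eps


# ---------------------------------------------------------------------------
# naive model
# ---------------------------------------------------------------------------


def _fit_naive(spec: NaiveModelSpec, dataset, config: ChainConfig) -> PosteriorDraws:
    hyper = spec.hyper
    _check_design(dataset.z)
    n, j = dataset.n, dataset.n_replicates
    nobs = n * j
    m0, prior_prec = _coef_prior(hyper)

    # replicate-level design [1, W_ij, Z_i]; fixed, so the cross-products
    # are computed once per attribute
    per_attr = {}
    for attr in ("ee", "es"):
        w = getattr(dataset, f"w_{attr}")
        y = getattr(dataset, f"y_{attr}")
        if w is None:
            raise ValueError("naive model requires gold-standard columns")
        d = np.column_stack(
            [np.ones(nobs), w.ravel(), np.repeat(dataset.z, j, axis=0)]
        )
        per_attr[attr] = (d, y.ravel(), d.T @ d, d.T @ y.ravel())

    draws = PosteriorDraws("naive", config)
    shape_var = hyper.a_var + 0.5 * nobs
    names = []
    for attr in ("ee", "es"):
        names += [f"beta0_{attr}", f"beta1_{attr}", f"sigma_y{attr}"]
    store = {
        name: np.empty((config.n_chains, config.n_kept)) for name in names
    }
    store["gamma_ee"] = np.empty((config.n_chains, config.n_kept, 3))
    store["gamma_es"] = np.empty((config.n_chains, config.n_kept, 3))

    for c, chain_seed in enumerate(np.random.SeedSequence(config.seed).spawn(config.n_chains)):
        rng = np.random.default_rng(chain_seed)
        sigma2 = {"ee": float(np.var(per_attr["ee"][1])), "es": float(np.var(per_attr["es"][1]))}
        kept = 0
        for it in range(config.n_iterations):
            for attr in ("ee", "es"):
                d, y, xtx, xty = per_attr[attr]
                b = _draw_coefs(rng, xtx, xty, sigma2[attr], m0, prior_prec)
                ssr = float(np.sum((y - d @ b) ** 2))
                sigma2[attr] = inv_gamma_rv(rng, shape_var, hyper.b_var + 0.5 * ssr)
                if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                    store[f"beta0_{attr}"][c, kept] = b[0]
                    store[f"beta1_{attr}"][c, kept] = b[1]
                    store[f"gamma_{attr}"][c, kept] = b[2:]
                    store[f"sigma_y{attr}"][c, kept] = np.sqrt(sigma2[attr])
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                kept += 1
    draws.params = store
    return draws


# ---------------------------------------------------------------------------
# linear measurement error model
# ---------------------------------------------------------------------------


def _fit_lmem(spec: LMEMSpec, dataset, config: ChainConfig) -> PosteriorDraws:
    hyper = spec.hyper
    _check_design(dataset.z)
    if dataset.w_ee is None or dataset.w_es is None:
        raise ValueError("LMEM requires gold-standard columns")
    n, j = dataset.n, dataset.n_replicates
    nobs = n * j
    z = dataset.z
    m0, prior_prec = _coef_prior(hyper)
    m_mu = np.asarray(hyper.m_mu, dtype=float)
    prec_mu_prior = np.diag(1.0 / np.asarray(hyper.c_mu, dtype=float))

    ym = {a: getattr(dataset, f"y_{a}").mean(axis=1) for a in ("ee", "es")}
    wm = {a: getattr(dataset, f"w_{a}").mean(axis=1) for a in ("ee", "es")}
    ssw_y = {
        a: float(np.sum((getattr(dataset, f"y_{a}") - ym[a][:, None]) ** 2))
        for a in ("ee", "es")
    }
    ssw_w = {
        a: float(np.sum((getattr(dataset, f"w_{a}") - wm[a][:, None]) ** 2))
        for a in ("ee", "es")
    }

    scalar_names = []
    for attr in ("ee", "es"):
        scalar_names += [f"beta0_{attr}", f"beta1_{attr}", f"sigma_y{attr}", f"sigma_w{attr}"]
    store = {name: np.empty((config.n_chains, config.n_kept)) for name in scalar_names}
    store["gamma_ee"] = np.empty((config.n_chains, config.n_kept, 3))
    store["gamma_es"] = np.empty((config.n_chains, config.n_kept, 3))
    store["mu"] = np.empty((config.n_chains, config.n_kept, 2))
    store["sigma_x"] = np.empty((config.n_chains, config.n_kept, 3))

    n_lat = max(1, config.n_kept // max(1, config.latent_thin))
    latents = np.empty((config.n_chains, n_lat, n, 2))

    shape_var = hyper.a_var + 0.5 * nobs

    for c, chain_seed in enumerate(np.random.SeedSequence(config.seed).spawn(config.n_chains)):
        rng = np.random.default_rng(chain_seed)
        x = np.column_stack([wm["ee"], wm["es"]])
        b = {a: np.zeros(5) for a in ("ee", "es")}
        sigma2_y = {a: float(np.var(ym[a])) for a in ("ee", "es")}
        sigma2_w = {a: max(1.0, ssw_w[a] / nobs) for a in ("ee", "es")}
        mu = x.mean(axis=0)
        sigma_x = np.cov(x.T) + 1e-6 * np.eye(2)
        kept = 0
        lat_kept = 0
        for it in range(config.n_iterations):
            # (1) regression coefficients and Y-channel variances
            for ai, attr in enumerate(("ee", "es")):
                d = np.column_stack([np.ones(n), x[:, ai], z])
                xtx = j * (d.T @ d)
                xty = j * (d.T @ ym[attr])
                b[attr] = _draw_coefs(rng, xtx, xty, sigma2_y[attr], m0, prior_prec)
                ssr = ssw_y[attr] + j * float(
                    np.sum((ym[attr] - d @ b[attr]) ** 2)
                )
                sigma2_y[attr] = inv_gamma_rv(rng, shape_var, hyper.b_var + 0.5 * ssr)
                # (2) gold-standard variances
                ssr_w = ssw_w[attr] + j * float(np.sum((wm[attr] - x[:, ai]) ** 2))
                sigma2_w[attr] = inv_gamma_rv(rng, shape_var, hyper.b_var + 0.5 * ssr_w)

            # (3) latent pairs: common 2x2 posterior precision
            prec_x = np.linalg.inv(sigma_x)
            lik_prec = np.diag(
                [
                    j * b["ee"][1] ** 2 / sigma2_y["ee"] + j / sigma2_w["ee"],
                    j * b["es"][1] ** 2 / sigma2_y["es"] + j / sigma2_w["es"],
                ]
            )
            post_prec = prec_x + lik_prec
            post_cov = np.linalg.inv(post_prec)
            resid = {
                a: ym[a] - b[a][0] - z @ b[a][2:] for a in ("ee", "es")
            }
            h = np.column_stack(
                [
                    j * b["ee"][1] * resid["ee"] / sigma2_y["ee"]
                    + j * wm["ee"] / sigma2_w["ee"],
                    j * b["es"][1] * resid["es"] / sigma2_y["es"]
                    + j * wm["es"] / sigma2_w["es"],
                ]
            ) + prec_x @ mu
            mean = h @ post_cov.T
            chol = np.linalg.cholesky(post_cov)
            x = mean + rng.standard_normal((n, 2)) @ chol.T

            # (4) latent mean and covariance
            prec_post = prec_mu_prior + n * prec_x
            rhs = prec_mu_prior @ m_mu + prec_x @ x.sum(axis=0)
            cov_mu = np.linalg.inv(prec_post)
            mu = mvn_rv(rng, cov_mu @ rhs, cov_mu)
            centered = x - mu
            sigma_x = inv_wishart_rv(
                rng, hyper.iw_df + n, hyper.iw_scale + centered.T @ centered
            )

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                for attr in ("ee", "es"):
                    store[f"beta0_{attr}"][c, kept] = b[attr][0]
                    store[f"beta1_{attr}"][c, kept] = b[attr][1]
                    store[f"gamma_{attr}"][c, kept] = b[attr][2:]
                    store[f"sigma_y{attr}"][c, kept] = np.sqrt(sigma2_y[attr])
                    store[f"sigma_w{attr}"][c, kept] = np.sqrt(sigma2_w[attr])
                store["mu"][c, kept] = mu
                store["sigma_x"][c, kept] = [
                    sigma_x[0, 0],
                    sigma_x[0, 1],
                    sigma_x[1, 1],
                ]
                if kept % config.latent_thin == 0 and lat_kept < n_lat:
                    latents[c, lat_kept] = x
                    lat_kept += 1
                kept += 1

    draws = PosteriorDraws("lmem", config)
    draws.params = store
    draws.latents = latents
    return draws
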