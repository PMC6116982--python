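"""Reversible-jump MCMC for the free-knot monotone spline models.

One sweep, per attribute (EE then dES):

1. refresh the OLS fit of spline coefficients and covariate slopes on the
   current basis/latents (coefficients carry no prior and are plug-in);
2. propose a knot birth / death / move, accepted with the dimension-matched
   ratio under a Poisson prior on the knot count and discrete-uniform knot
   positions over the current latent values — proposals whose OLS refit
   violates the non-decreasing coefficient constraint are rejected;
3. Gibbs-update the device and gold-standard error variances;
4. random-walk Metropolis update of every subject's latent pair jointly,
   with proposal sds adapted toward 20-40% acceptance during burn-in only;
5. update the latent prior: (mu, Sigma) for SMEMN, or stick-breaking
   weights, labels and per-cluster (mu_h, Sigma_h) for SMEM.

Because coefficients are deterministic given the knots (OLS plug-in, the
"not fully Bayesian" free-knot scheme), the Jacobian of the
trans-dimensional move is 1 and the acceptance ratio reduces to
likelihood x knot-count prior x proposal correction.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from ..bspline import (
    KnotSet,
    basis_matrix,
    evaluate_spline,
    is_monotone,
    monotone_projection,
)
from ..models import MeasurementDataset, SMEMNSpec, SMEMSpec, stick_break_weights
from ._random import inv_gamma_rv, inv_wishart_rv, mvn_rv
from .draws import ChainConfig, PosteriorDraws, SplineDraw

logger = logging.getLogger(__name__)

__all__ = ["rjmcmc_fit", "rj_log_prior_ratio", "knot_move_probs"]

ATTRS = ("ee", "es")


def knot_move_probs(k: int, config: ChainConfig) -> tuple[float, float, float]:
    """(birth, death, move) probabilities at the current knot count.

    Death is disabled at k = 0 with its mass reassigned to birth, and
    birth is disabled at k = k_max with its mass reassigned to death.
    """
    pb, pd, pm = config.move_probs
    if k <= 0:
        return pb + pd, 0.0, pm
    if k >= config.k_max:
        return 0.0, pb + pd, pm
    return pb, pd, pm


def rj_log_prior_ratio(kind: str, k: int, config: ChainConfig, lam: float) -> float:
    """Non-likelihood part of the log acceptance ratio for a knot move.

    ``k`` is the current knot count.  The Poisson(lam) count prior, the
    uniform position prior and the proposal densities collapse to the
    terms below; the move proposal is symmetric and contributes 0.
    """
    if kind == "move":
        return 0.0
    if kind == "birth":
        pb_fwd = knot_move_probs(k, config)[0]
        pd_rev = knot_move_probs(k + 1, config)[1]
        return math.log(lam) - math.log(k + 1) + math.log(pd_rev) - math.log(pb_fwd)
    if kind == "death":
        pd_fwd = knot_move_probs(k, config)[1]
        pb_rev = knot_move_probs(k - 1, config)[0]
        return -math.log(lam) + math.log(k) + math.log(pb_rev) - math.log(pd_fwd)
    raise ValueError(f"unknown move kind {kind!r}")


class _AttrState:
    """Spline-regression state for one attribute."""

    __slots__ = ("knots", "beta", "gamma", "sigma2_y", "ssr", "fitted")

    def __init__(self):
        self.knots = None
        self.beta = None
        self.gamma = None
        self.sigma2_y = 1.0
        self.ssr = 0.0
        self.fitted = None  # subject-level spline + covariate mean


def rjmcmc_fit(spec, dataset: MeasurementDataset, config: ChainConfig) -> PosteriorDraws:
    """Posterior simulation for :class:`SMEMNSpec` or :class:`SMEMSpec`."""
    if isinstance(spec, SMEMSpec):
        dp = True
    elif isinstance(spec, SMEMNSpec):
        dp = False
    else:
        raise TypeError(
            f"rjmcmc_fit does not handle {type(spec).__name__}; use gibbs_fit"
        )
    if dataset.w_ee is None or dataset.w_es is None:
        raise ValueError("spline measurement-error models require gold-standard columns")
    if dp and dataset.n_replicates <= 2:
        logger.warning(
            "DP latent prior is known to be unstable with only %d replicates; "
            "consider the bivariate-normal latent prior instead",
            dataset.n_replicates,
        )

    sampler = _Sampler(spec, dataset, config, dp)
    return sampler.run()


class _Sampler:
    def __init__(self, spec, dataset, config, dp):
        self.spec = spec
        self.hyper = spec.hyper
        self.data = dataset
        self.cfg = config
        self.dp = dp
        self.n = dataset.n
        self.j = dataset.n_replicates
        self.z = dataset.z
        self.ym = {a: getattr(dataset, f"y_{a}").mean(axis=1) for a in ATTRS}
        self.wm = {a: getattr(dataset, f"w_{a}").mean(axis=1) for a in ATTRS}
        self.ssw_y = {
            a: float(np.sum((getattr(dataset, f"y_{a}") - self.ym[a][:, None]) ** 2))
            for a in ATTRS
        }
        self.ssw_w = {
            a: float(np.sum((getattr(dataset, f"w_{a}") - self.wm[a][:, None]) ** 2))
            for a in ATTRS
        }

    # -- OLS machinery -----------------------------------------------------

    #: minimum squared column norm of the basis design; knot layouts whose
    #: basis functions have (almost) no latent support are unidentified and
    #: would let OLS return arbitrarily large — yet monotone — coefficients
    MIN_COLUMN_SUPPORT = 0.25

    def _ols(self, attr, x_col, knots):
        """OLS of subject-mean device readings on [basis, covariates].

        Returns (beta, gamma, ssr_full, fitted) or None when the knot
        layout is unsupported by the data or the solution violates the
        monotone-coefficient constraint.
        """
        b = basis_matrix(x_col, knots)
        if np.any(np.einsum("ij,ij->j", b, b) < self.MIN_COLUMN_SUPPORT):
            return None
        d = np.hstack([b, self.z])
        coef, *_ = np.linalg.lstsq(d, self.ym[attr], rcond=None)
        beta, gamma = coef[: knots.n_basis], coef[knots.n_basis :]
        if not is_monotone(beta, tol=1e-8):
            return None
        fitted = d @ coef
        ssr = self.ssw_y[attr] + self.j * float(np.sum((self.ym[attr] - fitted) ** 2))
        return beta, gamma, ssr, fitted

    def _refresh(self, state, attr, x_col):
        """Re-run OLS after latents moved.

        If the new unconstrained OLS violates the monotone-coefficient
        constraint, the previous coefficients — which still define a valid
        monotone spline — are kept and only the residuals are recomputed.
        At initialisation (no previous coefficients) the OLS solution is
        projected onto the monotone cone once.
        """
        res = self._ols(attr, x_col, state.knots)
        if res is None:
            b = basis_matrix(x_col, state.knots)
            if state.beta is None or state.beta.size != state.knots.n_basis:
                d = np.hstack([b, self.z])
                coef, *_ = np.linalg.lstsq(d, self.ym[attr], rcond=None)
                beta = monotone_projection(coef[: state.knots.n_basis])
                gamma = coef[state.knots.n_basis :]
                self.pava_count += 1
            else:
                beta, gamma = state.beta, state.gamma
                self.stale_count += 1
            fitted = b @ beta + self.z @ gamma
            ssr = self.ssw_y[attr] + self.j * float(
                np.sum((self.ym[attr] - fitted) ** 2)
            )
            res = (beta, gamma, ssr, fitted)
        state.beta, state.gamma, state.ssr, state.fitted = res

    # -- main loop ---------------------------------------------------------

    def run(self) -> PosteriorDraws:
        cfg = self.cfg
        draws = PosteriorDraws("smem" if self.dp else "smemn", cfg)
        scalar_names = []
        for a in ATTRS:
            scalar_names += [f"sigma_y{a}", f"sigma_w{a}", f"k_{a}"]
        store = {s: np.empty((cfg.n_chains, cfg.n_kept)) for s in scalar_names}
        store["gamma_ee"] = np.empty((cfg.n_chains, cfg.n_kept, 3))
        store["gamma_es"] = np.empty((cfg.n_chains, cfg.n_kept, 3))
        if not self.dp:
            store["mu"] = np.empty((cfg.n_chains, cfg.n_kept, 2))
            store["sigma_x"] = np.empty((cfg.n_chains, cfg.n_kept, 3))
        else:
            store["n_clusters"] = np.empty((cfg.n_chains, cfg.n_kept))
        n_lat = max(1, cfg.n_kept // max(1, cfg.latent_thin))
        latents = np.empty((cfg.n_chains, n_lat, self.n, 2))
        spline_store = {a: [] for a in ATTRS}
        accept_rates = []

        for c, chain_seed in enumerate(
            np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        ):
            rng = np.random.default_rng(chain_seed)
            chain_splines = {a: [] for a in ATTRS}
            rates = self._run_chain(
                rng, c, store, latents, chain_splines, n_lat
            )
            accept_rates.append(rates)
            for a in ATTRS:
                spline_store[a].append(chain_splines[a])

        draws.params = store
        draws.latents = latents
        draws.splines = spline_store
        draws.acceptance = {
            "latent": float(np.mean([r["latent"] for r in accept_rates])),
            "knot": float(np.mean([r["knot"] for r in accept_rates])),
        }
        if self.pava_count or self.stale_count:
            logger.info(
                "monotonicity handling: %d initial projections, %d stale refits kept",
                self.pava_count,
                self.stale_count,
            )
        return draws

    pava_count = 0
    stale_count = 0

    def _init_state(self, rng):
        x = np.column_stack([self.wm["ee"], self.wm["es"]])
        states = {}
        for ai, attr in enumerate(ATTRS):
            st = _AttrState()
            st.knots = KnotSet.from_data(x[:, ai])
            self._refresh(st, attr, x[:, ai])
            st.sigma2_y = max(st.ssr / (self.n * self.j), 1e-8)
            states[attr] = st
        sigma2_w = {a: max(self.ssw_w[a] / (self.n * self.j), 1e-8) for a in ATTRS}
        return x, states, sigma2_w

    def _run_chain(self, rng, c, store, latents, chain_splines, n_lat):
        cfg, hyper, n, j = self.cfg, self.hyper, self.n, self.j
        h_lvls = hyper.dp_truncation
        x, states, sigma2_w = self._init_state(rng)

        mu = x.mean(axis=0)
        sigma_x = np.cov(x.T) + 1e-6 * np.eye(2)
        if self.dp:
            labels = rng.integers(0, 5, size=n)
            cluster_mu = np.tile(mu, (h_lvls, 1)) + rng.normal(
                0.0, 100.0, size=(h_lvls, 2)
            )
            cluster_sigma = np.tile(sigma_x, (h_lvls, 1, 1))
            pi = np.full(h_lvls, 1.0 / h_lvls)

        prop_sd = np.array([cfg.proposal_sd_ee, cfg.proposal_sd_es])
        lat_acc = lat_tot = 0
        knot_acc = knot_tot = 0
        window_acc = window_tot = 0
        reject_window = 0
        shape_var = hyper.a_var + 0.5 * n * j
        m_mu = np.asarray(hyper.m_mu, dtype=float)
        prec_mu_prior = np.diag(1.0 / np.asarray(hyper.c_mu, dtype=float))
        kept = lat_kept = 0

        for it in range(cfg.n_iterations):
            # (1)-(2) per-attribute spline refresh + RJ knot move
            for ai, attr in enumerate(ATTRS):
                st = states[attr]
                self._refresh(st, attr, x[:, ai])
                accepted = self._knot_move(rng, st, attr, x[:, ai])
                knot_tot += 1
                knot_acc += accepted
                reject_window = 0 if accepted else reject_window + 1
                if reject_window == 500:
                    logger.warning(
                        "no accepted knot proposals in the last 500 attempts"
                    )
                # (3) variances
                st.sigma2_y = inv_gamma_rv(
                    rng, shape_var, hyper.b_var + 0.5 * st.ssr
                )
                ssr_w = self.ssw_w[attr] + j * float(
                    np.sum((self.wm[attr] - x[:, ai]) ** 2)
                )
                sigma2_w[attr] = inv_gamma_rv(
                    rng, shape_var, hyper.b_var + 0.5 * ssr_w
                )

            # (4) latent random-walk update
            if self.dp:
                prior_mu = cluster_mu[labels]
                prior_prec = np.linalg.inv(cluster_sigma)[labels]
            else:
                prior_mu = mu
                prior_prec = np.linalg.inv(sigma_x)
            acc = self._latent_update(
                rng, x, states, sigma2_w, prior_mu, prior_prec, prop_sd
            )
            lat_acc += acc
            lat_tot += n
            window_acc += acc
            window_tot += n
            if it < cfg.burn_in and (it + 1) % cfg.adapt_interval == 0:
                rate = window_acc / window_tot
                if rate < 0.20:
                    prop_sd *= 0.8
                elif rate > 0.40:
                    prop_sd *= 1.25
                window_acc = window_tot = 0

            # boundary rebuild if latents escaped the spline domain
            for ai, attr in enumerate(ATTRS):
                st = states[attr]
                col = x[:, ai]
                if col.min() < st.knots.lower or col.max() > st.knots.upper:
                    new_knots = KnotSet.from_data(col)
                    keep = (st.knots.interior > new_knots.lower) & (
                        st.knots.interior < new_knots.upper
                    )
                    st.knots = new_knots.with_interior(st.knots.interior[keep])
                    self._refresh(st, attr, col)

            # (5) latent prior
            xbar = x.mean(axis=0)
            if not self.dp:
                prec_x = np.linalg.inv(sigma_x)
                prec_post = prec_mu_prior + n * prec_x
                cov_mu = np.linalg.inv(prec_post)
                rhs = prec_mu_prior @ m_mu + prec_x @ (n * xbar)
                mu = mvn_rv(rng, cov_mu @ rhs, cov_mu)
                centered = x - mu
                sigma_x = inv_wishart_rv(
                    rng, hyper.iw_df + n, hyper.iw_scale + centered.T @ centered
                )
            else:
                labels, pi, cluster_mu, cluster_sigma = self._dp_update(
                    rng, x, labels, cluster_mu, cluster_sigma
                )

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                for ai, attr in enumerate(ATTRS):
                    st = states[attr]
                    store[f"sigma_y{attr}"][c, kept] = math.sqrt(st.sigma2_y)
                    store[f"sigma_w{attr}"][c, kept] = math.sqrt(sigma2_w[attr])
                    store[f"k_{attr}"][c, kept] = st.knots.k
                    store[f"gamma_{attr}"][c, kept] = st.gamma
                    if kept % cfg.spline_thin == 0:
                        chain_splines[attr].append(
                            SplineDraw(
                                knots=st.knots,
                                beta=st.beta.copy(),
                                gamma=st.gamma.copy(),
                                x_lo=float(x[:, ai].min()),
                                x_hi=float(x[:, ai].max()),
                            )
                        )
                if not self.dp:
                    store["mu"][c, kept] = mu
                    store["sigma_x"][c, kept] = [
                        sigma_x[0, 0],
                        sigma_x[0, 1],
                        sigma_x[1, 1],
                    ]
                else:
                    store["n_clusters"][c, kept] = np.unique(labels).size
                if kept % cfg.latent_thin == 0 and lat_kept < n_lat:
                    latents[c, lat_kept] = x
                    lat_kept += 1
                kept += 1

        return {
            "latent": lat_acc / max(lat_tot, 1),
            "knot": knot_acc / max(knot_tot, 1),
        }

    # -- reversible jump ---------------------------------------------------

    def _knot_move(self, rng, st, attr, x_col) -> bool:
        cfg = self.cfg
        k = st.knots.k
        pb, pd, pm = knot_move_probs(k, cfg)
        u = rng.random()
        kind = "birth" if u < pb else ("death" if u < pb + pd else "move")

        interior = st.knots.interior
        if kind in ("birth", "move"):
            candidates = x_col[
                (x_col > st.knots.lower)
                & (x_col < st.knots.upper)
                & ~np.isin(x_col, interior)
            ]
            if candidates.size == 0:
                return False

        if kind == "birth":
            new = np.sort(np.append(interior, rng.choice(candidates)))
        elif kind == "death":
            new = np.delete(interior, rng.integers(k))
        else:
            if k == 0:
                return False
            idx = rng.integers(k)
            new = np.sort(
                np.append(np.delete(interior, idx), rng.choice(candidates))
            )

        res = self._ols(attr, x_col, st.knots.with_interior(new))
        if res is None:
            return False
        beta, gamma, ssr, fitted = res
        log_acc = (st.ssr - ssr) / (2.0 * st.sigma2_y) + rj_log_prior_ratio(
            kind, k, cfg, self.hyper.lambda_knots
        )
        if math.log(rng.random()) < log_acc:
            st.knots = st.knots.with_interior(new)
            st.beta, st.gamma, st.ssr, st.fitted = beta, gamma, ssr, fitted
            return True
        return False

    # -- latent update -----------------------------------------------------

    def _latent_update(self, rng, x, states, sigma2_w, prior_mu, prior_prec, prop_sd):
        n, j = self.n, self.j
        prop = x + rng.standard_normal((n, 2)) * prop_sd

        in_bounds = np.ones(n, dtype=bool)
        for ai, attr in enumerate(ATTRS):
            kn = states[attr].knots
            in_bounds &= (prop[:, ai] >= kn.lower) & (prop[:, ai] <= kn.upper)

        log_ratio = np.full(n, -np.inf)
        safe = np.where(in_bounds)[0]
        if safe.size:
            lr = np.zeros(safe.size)
            for ai, attr in enumerate(ATTRS):
                st = states[attr]
                s_cur = evaluate_spline(x[safe, ai], st.knots, st.beta)
                s_prop = evaluate_spline(prop[safe, ai], st.knots, st.beta)
                resid = self.ym[attr][safe] - self.z[safe] @ st.gamma
                lr += (
                    (resid - s_cur) ** 2 - (resid - s_prop) ** 2
                ) * (j / (2.0 * st.sigma2_y))
                lr += (
                    (self.wm[attr][safe] - x[safe, ai]) ** 2
                    - (self.wm[attr][safe] - prop[safe, ai]) ** 2
                ) * (j / (2.0 * sigma2_w[attr]))
            dev_cur = x[safe] - (prior_mu[safe] if prior_mu.ndim == 2 else prior_mu)
            dev_prop = prop[safe] - (
                prior_mu[safe] if prior_mu.ndim == 2 else prior_mu
            )
            if prior_prec.ndim == 3:
                pp = prior_prec[safe]
                quad_cur = np.einsum("ni,nij,nj->n", dev_cur, pp, dev_cur)
                quad_prop = np.einsum("ni,nij,nj->n", dev_prop, pp, dev_prop)
            else:
                quad_cur = np.einsum("ni,ij,nj->n", dev_cur, prior_prec, dev_cur)
                quad_prop = np.einsum("ni,ij,nj->n", dev_prop, prior_prec, dev_prop)
            lr += 0.5 * (quad_cur - quad_prop)
            log_ratio[safe] = lr

        accept = np.log(rng.random(n)) < log_ratio
        x[accept] = prop[accept]
        return int(accept.sum())

    # -- Dirichlet process block -------------------------------------------

    def _dp_update(self, rng, x, labels, cluster_mu, cluster_sigma):
        hyper, n = self.hyper, self.n
        h_lvls = hyper.dp_truncation

        # stick weights from current label counts
        counts = np.bincount(labels, minlength=h_lvls)
        tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
        v = rng.beta(1.0 + counts[:-1], hyper.dp_alpha + tail[:-1])
        v = np.clip(v, 1e-12, 1.0 - 1e-12)
        v = np.append(v, 1.0)
        pi = stick_break_weights(v)

        # label full conditional
        logp = np.empty((n, h_lvls))
        for h in range(h_lvls):
            chol = np.linalg.cholesky(cluster_sigma[h])
            diff = np.linalg.solve(chol, (x - cluster_mu[h]).T)
            logp[:, h] = (
                math.log(max(pi[h], 1e-300))
                - np.log(np.diag(chol)).sum()
                - 0.5 * np.sum(diff**2, axis=0)
            )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        labels = (p.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)

        # per-cluster normal / inverse-Wishart updates
        m_mu = np.asarray(hyper.m_mu, dtype=float)
        prec_mu_prior = np.diag(1.0 / np.asarray(hyper.c_mu, dtype=float))
        for h in range(h_lvls):
            sel = labels == h
            n_h = int(sel.sum())
            prec_h = np.linalg.inv(cluster_sigma[h])
            prec_post = prec_mu_prior + n_h * prec_h
            cov_post = np.linalg.inv(prec_post)
            rhs = prec_mu_prior @ m_mu
            if n_h:
                rhs = rhs + prec_h @ x[sel].sum(axis=0)
            cluster_mu[h] = mvn_rv(rng, cov_post @ rhs, cov_post)
            scale = hyper.iw_scale.copy()
            if n_h:
                centered = x[sel] - cluster_mu[h]
                scale = scale + centered.T @ centered
            cluster_sigma[h] = inv_wishart_rv(rng, hyper.iw_df + n_h, scale)
        return labels, pi, cluster_mu, cluster_sigma
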