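"""Convergence diagnostics and posterior summaries."""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "gelman_rubin_max", "posterior_summary"]


def _psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor for draws shaped (n_chains, n_draws)."""
    m, n = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if n < 2:
        raise ValueError("chains must contain at least 2 draws")
    chain_means = chains.mean(axis=1)
    within = chains.var(axis=1, ddof=1).mean()
    between = n * chain_means.var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def gelman_rubin(draws, parameter: str):
    """PSRF for one retained parameter of a :class:`PosteriorDraws` object.

    Vector parameters return an array of per-component PSRFs.
    """
    arr = draws.params[parameter]
    if arr.ndim == 2:
        return _psrf(arr)
    return np.array([_psrf(arr[:, :, d]) for d in range(arr.shape[2])])


def gelman_rubin_max(draws, exclude=("k_ee", "k_es")) -> float:
    """Maximum PSRF over all retained (non-latent) parameters.

    Knot counts are integer-valued trans-dimensional indicators and are
    excluded by default.
    """
    worst = -np.inf
    for name in draws.parameter_names():
        if name in exclude:
            continue
        r = gelman_rubin(draws, name)
        worst = max(worst, float(np.max(r)))
    return worst


def posterior_summary(draws, parameter: str):
    """Pooled posterior mean, sd and (2.5, 50, 97.5)% quantiles."""
    stacked = draws.stacked(parameter)
    if stacked.size == 0:
        raise ValueError("no retained draws")
    return {
        "mean": stacked.mean(axis=0),
        "sd": stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else 0.0 * stacked.mean(axis=0),
        "q2.5": np.quantile(stacked, 0.025, axis=0),
        "median": np.quantile(stacked, 0.5, axis=0),
        "q97.5": np.quantile(stacked, 0.975, axis=0),
    }
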