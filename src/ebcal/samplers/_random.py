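"""Small sampling utilities shared by the Gibbs and RJ samplers."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["inv_gamma_rv", "inv_wishart_rv", "mvn_rv"]


def inv_gamma_rv(rng: np.random.Generator, shape: float, rate: float) -> float:
    """One inverse-gamma(shape, rate) draw (mean rate / (shape - 1))."""
    return float(rate / rng.gamma(shape))


def inv_wishart_rv(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """One inverse-Wishart(df, scale) draw via the Bartlett decomposition."""
    p = scale.shape[0]
    if df <= p - 1:
        raise ValueError("inverse-Wishart df must exceed dimension - 1")
    chol_inv_scale = np.linalg.cholesky(np.linalg.inv(scale))
    a = np.zeros((p, p))
    for i in range(p):
        a[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            a[i, j] = rng.standard_normal()
    f = chol_inv_scale @ a
    return np.linalg.inv(f @ f.T)


def mvn_rv(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """One multivariate normal draw via Cholesky."""
    chol = np.linalg.cholesky(cov)
    return mean + chol @ rng.standard_normal(mean.shape[0])
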