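"""Declarative model specifications, priors, and reference likelihoods.

Four models link device measurements Y to gold-standard measurements W,
error-free covariates Z, and (except for the naive model) latent usual
values X:

* ``NaiveModelSpec``  — Y regressed directly on W, no measurement error.
* ``LMEMSpec``        — Y linear in latent X; W unbiased for X; bivariate
  normal latent prior.
* ``SMEMNSpec``       — Y given by a monotone free-knot cubic spline of X;
  bivariate normal latent prior.
* ``SMEMSpec``        — as SMEMN but with a truncated Dirichlet-process
  (stick-breaking) mixture prior on X.

``log_likelihood`` is a straightforward (unoptimised) reference
implementation used by tests and diagnostics; the samplers carry their
own vectorised versions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bspline import KnotSet, evaluate_spline

__all__ = [
    "Hyperparameters",
    "NaiveModelSpec",
    "LMEMSpec",
    "SMEMNSpec",
    "SMEMSpec",
    "MeasurementDataset",
    "LatentState",
    "NaiveParams",
    "LMEMParams",
    "SplineParams",
    "log_likelihood",
    "stick_break_weights",
    "choose_truncation",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Prior settings shared by all models.

    Regression intercepts/slopes and covariate coefficients get diffuse
    normal priors; variances get inverse-gamma(a, b); the latent mean gets
    an independent normal prior and the latent covariance an
    inverse-Wishart prior.  Knot counts are Poisson(lambda); the DP
    concentration is alpha with stick-breaking truncated at H levels.
    """

    m_beta0: float = 0.0
    c_beta0: float = 1e5
    m_beta1: float = 1.0
    c_beta1: float = 1e5
    m_gamma: float = 0.0
    c_gamma: float = 1e5
    a_var: float = 0.1
    b_var: float = 0.1
    iw_scale: np.ndarray = field(default_factory=lambda: np.eye(2))
    iw_df: float = 3.0
    m_mu: tuple = (2400.0, 0.0)
    c_mu: tuple = (1e5, 1e5)
    lambda_knots: float = 1.0
    dp_alpha: float = 1.0
    dp_truncation: int = 20

    def __post_init__(self) -> None:
        if min(self.c_beta0, self.c_beta1, self.c_gamma) <= 0:
            raise ValueError("prior variances must be positive")
        if self.a_var <= 0 or self.b_var <= 0:
            raise ValueError("inverse-gamma shape and rate must be positive")
        if self.iw_df <= 1:  # d > p - 1 with p = 2
            raise ValueError("inverse-Wishart df must exceed dimension - 1")
        if self.dp_truncation < 1:
            raise ValueError("DP truncation level must be at least 1")


@dataclass(frozen=True)
class NaiveModelSpec:
    """Y regressed on W per attribute; gold standard treated as error free."""

    hyper: Hyperparameters = field(default_factory=Hyperparameters)


@dataclass(frozen=True)
class LMEMSpec:
    """Linear measurement-error model with bivariate-normal latent prior."""

    hyper: Hyperparameters = field(default_factory=Hyperparameters)


@dataclass(frozen=True)
class SMEMNSpec:
    """Monotone free-knot spline model, bivariate-normal latent prior."""

    hyper: Hyperparameters = field(default_factory=Hyperparameters)


@dataclass(frozen=True)
class SMEMSpec:
    """Monotone free-knot spline model, truncated DP mixture latent prior."""

    hyper: Hyperparameters = field(default_factory=Hyperparameters)


@dataclass(frozen=True)
class MeasurementDataset:
    """Balanced per-subject, per-replicate measurements.

    w_* may be None for calibration-only inputs (device readings plus
    covariates, no gold standard).
    """

    w_ee: np.ndarray | None
    w_es: np.ndarray | None
    y_ee: np.ndarray
    y_es: np.ndarray
    z: np.ndarray
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.y_ee.shape
        for name in ("w_ee", "w_es", "y_es"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.z.shape != (shape[0], 3):
            raise ValueError(f"z must be (n, 3), got {self.z.shape}")

    @property
    def n(self) -> int:
        return self.y_ee.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.y_ee.shape[1]

    @classmethod
    def from_simulated(cls, sim) -> "MeasurementDataset":
        return cls(
            w_ee=sim.w_ee,
            w_es=sim.w_es,
            y_ee=sim.y_ee,
            y_es=sim.y_es,
            z=sim.covariates.matrix,
        )


@dataclass
class LatentState:
    """Current latent usual values (and DP cluster labels, if any)."""

    x_ee: np.ndarray
    x_es: np.ndarray
    labels: np.ndarray | None = None


# --- parameter containers used by the reference likelihood -----------------


@dataclass
class NaiveParams:
    beta0_ee: float
    beta1_ee: float
    gamma_ee: np.ndarray
    sigma2_yee: float
    beta0_es: float
    beta1_es: float
    gamma_es: np.ndarray
    sigma2_yes: float


@dataclass
class LMEMParams(NaiveParams):
    sigma2_wee: float = 1.0
    sigma2_wes: float = 1.0
    mu: np.ndarray = None
    sigma_x: np.ndarray = None


@dataclass
class SplineParams:
    """Parameters of SMEMN (mu/sigma_x set) or SMEM (cluster arrays set)."""

    knots_ee: KnotSet = None
    beta_ee: np.ndarray = None
    gamma_ee: np.ndarray = None
    sigma2_yee: float = 1.0
    knots_es: KnotSet = None
    beta_es: np.ndarray = None
    gamma_es: np.ndarray = None
    sigma2_yes: float = 1.0
    sigma2_wee: float = 1.0
    sigma2_wes: float = 1.0
    mu: np.ndarray = None
    sigma_x: np.ndarray = None
    cluster_mu: np.ndarray = None  # (H, 2)
    cluster_sigma: np.ndarray = None  # (H, 2, 2)


def _normal_logpdf(x, mean, var):
    if np.any(np.asarray(var) <= 0):
        raise ValueError("non-positive variance in likelihood evaluation")
    return -0.5 * (np.log(2.0 * math.pi * var) + (x - mean) ** 2 / var)


def _mvn_logpdf(x, mean, cov):
    diff = np.atleast_2d(x - mean)
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff.T)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (2.0 * math.log(2.0 * math.pi) + logdet + np.sum(sol**2, axis=0))


def log_likelihood(spec, dataset: MeasurementDataset, params, latent=None) -> float:
    """Joint log density of all measurement channels (plus latent prior).

    For the naive model this is the Y-channel density given W.  For the
    latent-variable models it is the Y and W channels given the latents,
    plus the latent prior density — normal for LMEM/SMEMN, the assigned
    cluster's normal for SMEM.
    """
    z = dataset.z
    total = 0.0
    if isinstance(spec, NaiveModelSpec):
        for attr in ("ee", "es"):
            y = getattr(dataset, f"y_{attr}")
            w = getattr(dataset, f"w_{attr}")
            mean = (
                getattr(params, f"beta0_{attr}")
                + getattr(params, f"beta1_{attr}") * w
                + (z @ getattr(params, f"gamma_{attr}"))[:, None]
            )
            total += float(np.sum(_normal_logpdf(y, mean, getattr(params, f"sigma2_y{attr}"))))
        return total

    if latent is None:
        raise ValueError("latent state required for measurement-error models")
    x = {"ee": latent.x_ee, "es": latent.x_es}

    for attr in ("ee", "es"):
        y = getattr(dataset, f"y_{attr}")
        w = getattr(dataset, f"w_{attr}")
        if isinstance(spec, LMEMSpec):
            reg = (
                getattr(params, f"beta0_{attr}")
                + getattr(params, f"beta1_{attr}") * x[attr]
            )
        else:
            reg = evaluate_spline(
                x[attr],
                getattr(params, f"knots_{attr}"),
                getattr(params, f"beta_{attr}"),
            )
        mean = reg[:, None] + (z @ getattr(params, f"gamma_{attr}"))[:, None]
        total += float(np.sum(_normal_logpdf(y, mean, getattr(params, f"sigma2_y{attr}"))))
        total += float(
            np.sum(_normal_logpdf(w, x[attr][:, None], getattr(params, f"sigma2_w{attr}")))
        )

    xmat = np.column_stack([latent.x_ee, latent.x_es])
    if isinstance(spec, SMEMSpec):
        if latent.labels is None:
            raise ValueError("SMEM likelihood needs cluster labels")
        for h in np.unique(latent.labels):
            sel = latent.labels == h
            total += float(
                np.sum(_mvn_logpdf(xmat[sel], params.cluster_mu[h], params.cluster_sigma[h]))
            )
    else:
        total += float(np.sum(_mvn_logpdf(xmat, params.mu, params.sigma_x)))
    return total


def stick_break_weights(v, h: int | None = None) -> np.ndarray:
    """Stick-breaking weights pi_h = V_h * prod_{l<h} (1 - V_l).

    Requires the final stick fraction to be exactly 1 so the weights sum
    to 1 exactly.
    """
    v = np.asarray(v, dtype=float)
    if h is not None and v.size != h:
        raise ValueError(f"expected {h} stick fractions, got {v.size}")
    if v.size == 0 or v[-1] != 1.0:
        raise ValueError("final stick fraction must equal 1")
    if np.any(v <= 0) or np.any(v > 1):
        raise ValueError("stick fractions must lie in (0, 1]")
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    return v * remaining


def choose_truncation(alpha: float, eps: float) -> int:
    """Smallest H whose expected untruncated tail mass (alpha/(alpha+1))^H
    is at most eps."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0 < eps < 1:
        raise ValueError("eps must lie in (0, 1)")
    ratio = alpha / (alpha + 1.0)
    h = 1
    tail = ratio
    while tail > eps:
        h += 1
        tail *= ratio
    return h
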