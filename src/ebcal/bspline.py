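"""Cubic B-spline bases with a monotone-coefficient constraint.

The regression functions linking a latent usual value to its noisy device
measurement are cubic B-splines with free interior knots.  Monotone
(non-decreasing) coefficient vectors guarantee a non-decreasing spline,
which is what makes the fitted curve invertible for calibration.

Boundary knots are clamped (repeated ``degree + 1`` times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3
#: slack on successive coefficient differences, absorbs floating-point ties
MONOTONE_TOL = 1e-12

__all__ = [
    "DEGREE",
    "KnotSet",
    "basis_matrix",
    "evaluate_spline",
    "is_monotone",
    "greville_abscissae",
    "linear_coefficients",
    "monotone_projection",
]


@dataclass(frozen=True)
class KnotSet:
    """Interior knots plus clamped domain boundaries for a cubic B-spline."""

    interior: np.ndarray
    lower: float
    upper: float

    def __post_init__(self) -> None:
        interior = np.atleast_1d(np.asarray(self.interior, dtype=float))
        object.__setattr__(self, "interior", interior)
        if not self.lower < self.upper:
            raise ValueError("lower boundary must be below upper boundary")
        if interior.size:
            if np.any(np.diff(interior) < 0):
                raise ValueError("interior knots must be sorted ascending")
            if interior[0] <= self.lower or interior[-1] >= self.upper:
                raise ValueError("interior knots must lie strictly inside the boundary")

    @property
    def k(self) -> int:
        """Number of interior knots."""
        return int(self.interior.size)

    @property
    def n_basis(self) -> int:
        """Number of basis functions, k + degree + 1."""
        return self.k + DEGREE + 1

    def augmented(self) -> np.ndarray:
        """Full knot vector with boundary knots repeated degree+1 times."""
        return np.concatenate(
            [
                np.full(DEGREE + 1, self.lower),
                self.interior,
                np.full(DEGREE + 1, self.upper),
            ]
        )

    def with_interior(self, interior) -> "KnotSet":
        return KnotSet(np.asarray(interior, dtype=float), self.lower, self.upper)

    @classmethod
    def from_data(cls, x, interior=(), pad: float = 0.05) -> "KnotSet":
        """Boundary at the data range widened by ``pad`` times the range."""
        x = np.asarray(x, dtype=float)
        lo, hi = float(x.min()), float(x.max())
        width = (hi - lo) * pad
        return cls(np.asarray(interior, dtype=float), lo - width, hi + width)


def _check_domain(x: np.ndarray, knots: KnotSet) -> None:
    if x.size and (x.min() < knots.lower or x.max() > knots.upper):
        raise ValueError(
            f"x outside spline domain [{knots.lower}, {knots.upper}]; "
            "widen the boundary before evaluating"
        )


def basis_matrix(x, knots: KnotSet) -> np.ndarray:
    """Dense n x (k+4) cubic B-spline design matrix at the points ``x``.

    Rows sum to one (partition of unity).  Raises for points outside the
    clamped boundary.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(x, knots)
    return BSpline.design_matrix(x, knots.augmented(), DEGREE).toarray()


def evaluate_spline(x, knots: KnotSet, beta) -> np.ndarray:
    """Evaluate ``B(x) @ beta`` for the cubic spline defined by ``knots``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if beta.size != knots.n_basis:
        raise ValueError(
            f"coefficient vector has length {beta.size}, expected {knots.n_basis}"
        )
    _check_domain(x, knots)
    return BSpline(knots.augmented(), beta, DEGREE, extrapolate=False)(x)


def is_monotone(beta, tol: float = MONOTONE_TOL) -> bool:
    """True iff successive coefficient differences are >= -tol."""
    beta = np.asarray(beta, dtype=float)
    if beta.size < 2:
        return True
    return bool(np.all(np.diff(beta) >= -tol))


def greville_abscissae(knots: KnotSet) -> np.ndarray:
    """Greville sites: means of ``degree`` consecutive internal knot values.

    A spline with coefficients beta_j = f(xi_j) for linear f reproduces f
    exactly (linear precision), which is how linear fits are embedded in
    the spline parameterization.
    """
    t = knots.augmented()
    m = knots.n_basis
    return np.array([t[j + 1 : j + 1 + DEGREE].mean() for j in range(m)])


def linear_coefficients(knots: KnotSet, intercept: float, slope: float) -> np.ndarray:
    """Coefficients that make the spline equal ``intercept + slope * x``."""
    return intercept + slope * greville_abscissae(knots)


def monotone_projection(beta) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-decreasing vectors.

    Used only as a fall-back to re-establish a valid sampler state after a
    basis rebuild; ordinary proposals that violate monotonicity are
    rejected, not projected.
    """
    beta = np.asarray(beta, dtype=float).copy()
    n = beta.size
    weight = np.ones(n)
    # classic PAVA with merge-by-averaging
    values = list(beta)
    weights = list(weight)
    i = 0
    while i < len(values) - 1:
        if values[i] > values[i + 1] + MONOTONE_TOL:
            total = weights[i] + weights[i + 1]
            merged = (values[i] * weights[i] + values[i + 1] * weights[i + 1]) / total
            values[i : i + 2] = [merged]
            weights[i : i + 2] = [total]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.concatenate(
        [np.full(int(w), v) for v, w in zip(values, weights)]
    )
    return out
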