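"""Posterior calibration: invert the fitted monotone spline per draw.

Given a device reading y and covariates z, each retained posterior draw r
supplies a monotone regression function s^(r) and covariate slopes
gamma^(r).  The calibrated latent value solves

    s^(r)(x) = y - gamma^(r)' z

on the draw's identified latent range.  Because every retained s^(r) is
non-decreasing, the minimiser of |s(x) - y*| is found by bounded root
finding; targets outside the attainable range return the nearest boundary
and raise a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bspline import evaluate_spline

__all__ = ["CalibrationResult", "calibrate", "credible_interval", "calibrate_table"]

#: fraction of the per-draw latent range used to pad the search interval
SEARCH_PAD = 0.10
#: absolute x tolerance of the inversion, kcal/day
XTOL = 1e-6


@dataclass(frozen=True)
class CalibrationResult:
    """Posterior draws of the calibrated latent value for one reading."""

    draws: np.ndarray
    median: float
    lower: float
    upper: float
    y: float
    z: np.ndarray
    attribute: str
    boundary_fraction: float

    @property
    def flagged(self) -> bool:
        """True when any draw hit the edge of its identified range."""
        return self.boundary_fraction > 0


def _invert_draw(draw, target: float) -> tuple[float, bool]:
    """Invert one retained spline at ``target``; returns (x, hit_boundary)."""
    pad = (draw.x_hi - draw.x_lo) * SEARCH_PAD
    lo = max(draw.x_lo - pad, draw.knots.lower)
    hi = min(draw.x_hi + pad, draw.knots.upper)
    s_lo = float(evaluate_spline(lo, draw.knots, draw.beta)[0])
    s_hi = float(evaluate_spline(hi, draw.knots, draw.beta)[0])
    if target <= s_lo:
        return lo, target < s_lo - XTOL
    if target >= s_hi:
        return hi, target > s_hi + XTOL

    def f(x):
        return float(evaluate_spline(x, draw.knots, draw.beta)[0]) - target

    return brentq(f, lo, hi, xtol=XTOL), False


def calibrate(
    y: float,
    z,
    draws,
    attribute: str,
    level: float = 0.95,
    max_draws: int | None = None,
) -> CalibrationResult:
    """Map one device reading to a posterior over the latent truth.

    Parameters
    ----------
    y : float
        Device reading, kcal/day.
    z : array-like, shape (3,)
        Covariates in the order (gender, bmi, age).
    draws : PosteriorDraws
        Fit of a spline measurement-error model (SMEMN or SMEM).
    attribute : {"ee", "es"}
        Which measurement channel to invert.
    max_draws : int, optional
        Subsample of retained spline draws to use (all by default).
    """
    if attribute not in ("ee", "es"):
        raise ValueError("attribute must be 'ee' or 'es'")
    if not np.isfinite(y):
        raise ValueError("device reading must be finite")
    z = np.asarray(z, dtype=float)
    spline_draws = draws.spline_draws(attribute)
    if not spline_draws:
        raise ValueError(
            "posterior contains no spline draws; calibrate requires an "
            "SMEMN or SMEM fit"
        )
    if max_draws is not None and len(spline_draws) > max_draws:
        idx = np.linspace(0, len(spline_draws) - 1, max_draws).astype(int)
        spline_draws = [spline_draws[i] for i in idx]

    values = np.empty(len(spline_draws))
    hits = 0
    for i, d in enumerate(spline_draws):
        target = y - float(d.gamma @ z)
        values[i], hit = _invert_draw(d, target)
        hits += hit

    lower, upper = np.quantile(values, [(1 - level) / 2, (1 + level) / 2])
    return CalibrationResult(
        draws=values,
        median=float(np.median(values)),
        lower=float(lower),
        upper=float(upper),
        y=float(y),
        z=z,
        attribute=attribute,
        boundary_fraction=hits / len(spline_draws),
    )


def credible_interval(result: CalibrationResult, level: float = 0.95):
    """Empirical central credible interval of the calibrated draws."""
    if result.draws.size < 100:
        raise ValueError("need at least 100 calibrated draws for an interval")
    lo, hi = np.quantile(result.draws, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def calibrate_table(
    new_data: pd.DataFrame, draws, level: float = 0.95, max_draws: int | None = 500
) -> pd.DataFrame:
    """Calibrate a table of device readings; one output row per input row.

    ``new_data`` needs covariate columns (gender, bmi, age) and at least
    one of y_ee / y_es.  Returns per attribute the posterior median, the
    credible bounds and a boundary flag.
    """
    required = {"gender", "bmi", "age"}
    if not required <= set(new_data.columns):
        missing = sorted(required - set(new_data.columns))
        raise ValueError(f"missing covariate columns: {missing}")
    attrs = [a for a in ("ee", "es") if f"y_{a}" in new_data.columns]
    if not attrs:
        raise ValueError("no device-reading column (y_ee or y_es) found")

    rows = []
    for _, rec in new_data.iterrows():
        z = np.array([rec["gender"], rec["bmi"], rec["age"]])
        out = {"gender": rec["gender"], "bmi": rec["bmi"], "age": rec["age"]}
        for a in attrs:
            res = calibrate(rec[f"y_{a}"], z, draws, a, level=level, max_draws=max_draws)
            out[f"y_{a}"] = rec[f"y_{a}"]
            out[f"x_{a}_median"] = res.median
            out[f"x_{a}_lower"] = res.lower
            out[f"x_{a}_upper"] = res.upper
            out[f"x_{a}_boundary_flag"] = int(res.flagged)
        rows.append(out)
    return pd.DataFrame(rows)
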