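"""Normalized logistic dry-matter accumulation as a function of GDD.

Aboveground biomass observations are normalized by the maximum observed (or
user-supplied) mass ``Y_m`` and fitted with

    y = Y_o / Y_m = 1 / (1 + exp(a + b·GDD))

where ``b < 0`` for any biologically increasing curve.  Fit quality on the
normalized scale is the usual RMSE.  How well a thermal-time method orders
the growing season along GDD shows up directly in this RMSE, which is why
the fit serves as a method-comparison statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .thermal_core import ParameterError

__all__ = [
    "FitError",
    "LogisticFit",
    "logistic",
    "normalize",
    "fit_logistic",
    "rmse",
]

_LOGIT_EPS = 1e-3


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries solver diagnostics."""


def logistic(gdd, a: float, b: float):
    """Normalized logistic curve y = 1/(1 + exp(a + b·GDD))."""
    gdd = np.asarray(gdd, dtype=float)
    return 1.0 / (1.0 + np.exp(a + b * gdd))


def normalize(mass, y_max: float | None = None) -> np.ndarray:
    """Normalize masses to [0, 1] by ``y_max`` (default: observed maximum)."""
    arr = np.asarray(mass, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("dry-matter mass must be non-negative")
    if y_max is None:
        if arr.size == 0:
            raise ParameterError("cannot infer y_max from an empty series")
        y_max = float(arr.max())
    if y_max <= 0:
        raise ParameterError(f"y_max must be positive, got {y_max}")
    return arr / y_max


@dataclass
class LogisticFit:
    """Fitted coefficients of the normalized logistic dry-matter curve."""

    a: float
    b: float
    y_max: float
    rmse: float
    n: int
    method: str = ""

    def predict(self, gdd):
        return logistic(gdd, self.a, self.b)


def fit_logistic(
    gdd,
    y,
    y_max: float = 1.0,
    method_id: str = "",
) -> LogisticFit:
    """Least-squares fit of the normalized logistic curve.

    Initialisation is deterministic: ``y`` is clamped into
    ``[1e-3, 1−1e-3]``, the logit ``log((1−y)/y) = a + b·GDD`` is solved by
    ordinary least squares, and the start is refined by damped least squares
    on the original (unclamped) residuals.  Observations at y = 1 are kept;
    the clamp applies only inside the initialisation.
    """
    g = np.asarray(gdd, dtype=float)
    yo = np.asarray(y, dtype=float)
    if g.shape != yo.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {yo.shape}")
    if g.size < 3:
        raise ParameterError(f"need >= 3 observations to fit, got {g.size}")
    if not (np.any(yo < 0.5) and np.any(yo > 0.5)):
        warnings.warn(
            "observations do not span both sides of y = 0.5; "
            "logistic coefficients may be poorly identified",
            stacklevel=2,
        )

    yc = np.clip(yo, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    logit = np.log((1.0 - yc) / yc)
    b0, a0 = np.polyfit(g, logit, 1)

    def residuals(theta):
        a, b = theta
        return logistic(g, a, b) - yo

    result = least_squares(residuals, x0=[a0, b0], method="lm", xtol=1e-14, ftol=1e-14)
    if not result.success:
        raise FitError(f"logistic fit did not converge: {result.message}")
    a, b = result.x
    fitted = logistic(g, a, b)
    return LogisticFit(
        a=float(a),
        b=float(b),
        y_max=float(y_max),
        rmse=rmse(yo, fitted),
        n=int(g.size),
        method=method_id,
    )


def rmse(y_obs, y_fit) -> float:
    """Root mean square error sqrt(Σ(y_f − y_o)²/n)."""
    obs = np.asarray(y_obs, dtype=float)
    fit = np.asarray(y_fit, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {fit.shape}")
    if obs.size == 0:
        raise ValueError("rmse needs at least one observation")
    return float(np.sqrt(np.mean((fit - obs) ** 2)))
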