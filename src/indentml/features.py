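"""Power-law parameterization of load-displacement curves.

A smooth indentation curve is summarised by two numbers via
``F(delta) = p * delta**s``: the prefactor ``p`` (stiffness scale) and the
exponent ``s`` (shape).  For Hertzian contact ``s = 3/2`` exactly; finite
sample size and strain stiffening shift it.  Fitting is ordinary least
squares on ``ln F = ln p + s ln delta`` over the points with positive
depth and force — a closed-form, deterministic reduction that also acts
as a low-pass filter, which is what makes the direct inverse network
robust to measurement noise.

Depths are non-dimensionalised to ``delta/R`` before fitting by default,
so ``p`` is comparable across indenter radii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from sklearn.base import BaseEstimator, TransformerMixin

from .curves import IndentationCurve

__all__ = ["PowerLawFeatures", "fit_power_law", "eval_power_law", "PowerLawFeaturizer"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFeatures:
    """Fitted ``F = p * delta**s`` parameters plus the fit RMSE (force units)."""

    p: float
    s: float
    fit_rmse: float

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError(f"prefactor p must be positive, got {self.p}")


def _loglog_ols(log_d: NDArray, log_f: NDArray) -> tuple[float, float]:
    s, logp = np.polyfit(log_d, log_f, 1)
    return float(logp), float(s)


def fit_power_law(
    curve: IndentationCurve, *, fit_on: str = "delta_over_R"
) -> PowerLawFeatures:
    """Fit ``F = p delta^s`` to a curve by log-log least squares.

    Points with non-positive depth or force are excluded before taking
    logs (a warning is logged if more than 20% are dropped); at least
    three usable points are required.
    """
    if fit_on not in ("delta_over_R", "delta"):
        raise ValueError(f"fit_on must be 'delta_over_R' or 'delta', got {fit_on}")
    d = curve.depth_over_R if fit_on == "delta_over_R" else curve.depth
    f = curve.force
    usable = (d > 0) & (f > 0)
    n_drop = int(d.size - usable.sum())
    if usable.sum() < 3:
        raise ValueError(
            f"power-law fit needs >= 3 points with positive depth and force, "
            f"have {int(usable.sum())}"
        )
    if n_drop > 0.2 * d.size:
        logger.warning(
            "power-law fit excluded %d of %d points (non-positive depth/force)",
            n_drop, d.size,
        )
    logp, s = _loglog_ols(np.log(d[usable]), np.log(f[usable]))
    p = float(np.exp(logp))
    rmse = float(np.sqrt(np.mean((p * d[usable] ** s - f[usable]) ** 2)))
    return PowerLawFeatures(p, s, rmse)


def eval_power_law(features: PowerLawFeatures, depths) -> NDArray[np.float64]:
    """Evaluate ``p * delta**s`` (0 at zero depth)."""
    d = np.asarray(depths, dtype=float)
    if np.any(d < 0):
        raise ValueError("depths must be non-negative")
    with np.errstate(divide="ignore"):
        out = features.p * np.where(d > 0, d, 1.0) ** features.s
    return np.where(d > 0, out, 0.0)


class PowerLawFeaturizer(TransformerMixin, BaseEstimator):
    """Transform a matrix of curves into ``(log10 p, s)`` feature columns.

    Rows of ``X`` are forces on the shared non-dimensional depth grid
    (zero-depth column excluded).  Stateless: ``fit`` only validates the
    grid; all rows must be strictly positive (smooth synthetic or
    power-law-smoothed curves).
    """

    def __init__(self, grid_over_R: NDArray[np.float64] | None = None):
        self.grid_over_R = grid_over_R

    def fit(self, X, y=None):
        if self.grid_over_R is None:
            raise ValueError("grid_over_R must be set before fitting")
        g = np.asarray(self.grid_over_R, dtype=float)
        if np.any(g <= 0):
            raise ValueError("grid_over_R must be strictly positive")
        self.log_grid_ = np.log(g)
        self.n_features_in_ = g.size
        return self

    def transform(self, X) -> NDArray[np.float64]:
        if not hasattr(self, "log_grid_"):
            self.fit(X)
        F = np.asarray(X, dtype=float)
        if F.ndim != 2 or F.shape[1] != self.log_grid_.size:
            raise ValueError(
                f"X must be (n_curves, {self.log_grid_.size}), got {F.shape}"
            )
        if np.any(F <= 0):
            raise ValueError("all forces must be positive for the log-log fit")
        lx = self.log_grid_
        lF = np.log(F)
        vx = lx - lx.mean()
        s = (lF - lF.mean(axis=1, keepdims=True)) @ vx / np.dot(vx, vx)
        logp = lF.mean(axis=1) - s * lx.mean()
        return np.column_stack([logp / np.log(10.0), s])
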