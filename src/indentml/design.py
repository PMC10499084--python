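"""Non-dimensional design space and latin-hypercube sampling.

The indentation problem is non-dimensionalised by the indenter radius
``R``: a design point is the tuple ``(W/R, H/R, mu[, Jm])`` of sample
width and thickness ratios plus material parameters.  Indentation depth is
not a sampled coordinate — every design point is evaluated on a shared
depth grid ``delta/R in [0, 0.5]`` with step 0.005 (101 points, of which
the identically-zero force at zero depth is dropped from learning
targets).

The shear modulus spans four decades and is stratified uniformly in
``log10`` space; the Gent parameter ``Jm`` spans nearly four decades and
is treated the same way by default (configurable to linear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.stats import qmc

from .constitutive import MaterialParams, Model

__all__ = ["DesignSpace", "DesignPoint", "sample_design", "depth_grid"]


@dataclass(frozen=True)
class DesignSpace:
    """Bounds of the sampled parameter space (defaults are the study space)."""

    W_over_R: tuple[float, float] = (5.0, 40.0)
    H_over_R: tuple[float, float] = (5.0, 40.0)
    mu: tuple[float, float] = (1.0e2, 1.0e6)  # Pa, log10-stratified
    Jm: tuple[float, float] = (5.0e-4, 5.0)  # Gent only
    jm_scale: str = "log"  # "log" | "linear"
    max_depth_over_R: float = 0.5
    depth_step_over_R: float = 0.005

    def __post_init__(self) -> None:
        for name in ("W_over_R", "H_over_R", "mu", "Jm"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound {lo} must be < upper {hi}")
        if self.mu[0] <= 0 or self.Jm[0] <= 0:
            raise ValueError("mu and Jm bounds must be positive")
        if self.jm_scale not in ("log", "linear"):
            raise ValueError(f"jm_scale must be 'log' or 'linear', got {self.jm_scale}")

    def dims(self, model: Model) -> int:
        return 4 if Model(model) is Model.GENT else 3


@dataclass(frozen=True)
class DesignPoint:
    """One sampled configuration: geometry ratios plus material parameters."""

    W_over_R: float
    H_over_R: float
    params: MaterialParams


def sample_design(
    space: DesignSpace,
    n: int,
    model: Model | str = Model.NEO_HOOKEAN,
    seed: int = 1,
) -> list[DesignPoint]:
    """Draw ``n`` latin-hypercube design points.

    Each dimension is stratified into ``n`` equal-probability bins with
    exactly one sample per bin, after the scale transform: ``mu`` (and by
    default ``Jm``) are stratified in ``log10`` space, geometry ratios
    linearly.  Deterministic for a given ``seed``.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError(f"seed must be an integer, got {seed!r}")
    model = Model(model)
    d = space.dims(model)
    unit = qmc.LatinHypercube(d=d, seed=int(seed)).random(n)

    lo = [space.W_over_R[0], space.H_over_R[0], np.log10(space.mu[0])]
    hi = [space.W_over_R[1], space.H_over_R[1], np.log10(space.mu[1])]
    if model is Model.GENT:
        if space.jm_scale == "log":
            lo.append(np.log10(space.Jm[0]))
            hi.append(np.log10(space.Jm[1]))
        else:
            lo.append(space.Jm[0])
            hi.append(space.Jm[1])
    scaled = qmc.scale(unit, lo, hi)

    points: list[DesignPoint] = []
    for row in scaled:
        mu = float(10.0 ** row[2])
        if model is Model.GENT:
            jm = float(10.0 ** row[3]) if space.jm_scale == "log" else float(row[3])
            params = MaterialParams(Model.GENT, mu, Jm=jm)
        else:
            params = MaterialParams(Model.NEO_HOOKEAN, mu)
        points.append(DesignPoint(float(row[0]), float(row[1]), params))
    return points


def depth_grid(space: DesignSpace | None = None) -> NDArray[np.float64]:
    """Shared non-dimensional depth grid ``delta/R`` (inclusive of 0).

    Defaults give ``0, 0.005, ..., 0.5`` — 101 points.  The step must
    divide the range exactly.
    """
    space = space or DesignSpace()
    step, top = space.depth_step_over_R, space.max_depth_over_R
    n = top / step
    if abs(n - round(n)) > 1.0e-12:
        raise ValueError(
            f"depth step {step} does not evenly divide max depth {top}"
        )
    return np.linspace(0.0, top, int(round(n)) + 1)
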