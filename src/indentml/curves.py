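"""Shared containers for load-displacement data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["SampleGeometry", "IndentationCurve"]


@dataclass(frozen=True)
class SampleGeometry:
    """Indenter radius ``R`` (m) and non-dimensional sample size ratios."""

    R: float
    W_over_R: float
    H_over_R: float

    def __post_init__(self) -> None:
        if min(self.R, self.W_over_R, self.H_over_R) <= 0:
            raise ValueError("R, W/R and H/R must all be positive")


@dataclass(frozen=True)
class IndentationCurve:
    """Paired indentation depth (m) and reaction force (N) arrays.

    Depths must be strictly increasing; if the curve starts at zero depth
    the force there must be zero.  Forces are finite and non-negative.
    """

    depth: NDArray[np.float64]
    force: NDArray[np.float64]
    R: float
    geometry: SampleGeometry | None = None

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "force", force)
        if depth.ndim != 1 or depth.shape != force.shape:
            raise ValueError("depth and force must be 1-d arrays of equal length")
        if self.R <= 0:
            raise ValueError("indenter radius must be positive")
        if depth.size and np.any(np.diff(depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        if not np.all(np.isfinite(force)) or np.any(force < 0):
            raise ValueError("forces must be finite and non-negative")
        if depth.size and depth[0] == 0.0 and force[0] != 0.0:
            raise ValueError("force must vanish at zero depth")

    @property
    def depth_over_R(self) -> NDArray[np.float64]:
        return self.depth / self.R

    def __len__(self) -> int:
        return int(self.depth.size)


def as_curve(
    depth_over_R: ArrayLike, force: ArrayLike, R: float, geometry: SampleGeometry | None = None
) -> IndentationCurve:
    """Build a curve from a non-dimensional depth grid and physical forces."""
    x = np.asarray(depth_over_R, dtype=float)
    return IndentationCurve(x * R, np.asarray(force, dtype=float), R, geometry)
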