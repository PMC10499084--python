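"""Inverse material-parameter identification from indentation curves.

Two machine-learning routes and two analytic baselines:

``invert_least_squares``
    Bound-constrained least squares over ``(log10 mu[, log10 Jm])`` with
    the trained forward network as the forward model, multi-started from
    a small latin-hypercube of the parameter bounds.  Iterative but
    accurate; the forward net only ever produces smooth curves, which is
    what makes this route robust to measurement noise.
``invert_direct``
    One evaluation of the trained direct inverse network on the
    ``(W/R, H/R, log10 p, s)`` power-law features of the curve.  No
    iterations.
``invert_hertz``
    Closed-form modulus from the (modified) Hertzian contact law — the
    conventional practice the ML routes are compared against.

``evaluate_inversions`` summarises recovery quality (mean/max relative
errors on the linear parameter scale, R^2 of predicted vs true on the
log10 scale, since both parameters are log-uniformly distributed), and
``verify_by_forward_sim`` closes the loop by regenerating a curve from
identified parameters and reporting its RMSE against the measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import least_squares
from scipy.stats import qmc

from .constitutive import MaterialParams, Model
from .contact import (
    HertzVariant,
    fit_contact_modulus,
    hertz_force,
    modified_hertz_force,
    young_modulus_from_shear,
)
from .curves import IndentationCurve, SampleGeometry
from .design import DesignPoint, DesignSpace, depth_grid
from .features import fit_power_law
from .generator import SurrogateCoeffs, simulate_forces
from .nets import ForwardCurveNet, InverseParamNet

__all__ = [
    "InversionResult",
    "EvaluationSummary",
    "invert_least_squares",
    "invert_direct",
    "invert_hertz",
    "evaluate_inversions",
    "verify_by_forward_sim",
]

logger = logging.getLogger(__name__)


@dataclass
class InversionResult:
    """Identified parameters plus fit diagnostics for one curve."""

    method: str
    params: MaterialParams
    misfit_rmse: float
    n_iterations: int = 0
    converged: bool = True
    at_bound: bool = False
    young_modulus: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.misfit_rmse < 0:
            raise ValueError("misfit RMSE must be non-negative")
        if self.young_modulus == 0.0:
            self.young_modulus = young_modulus_from_shear(self.params.mu)


def _resample_to_grid(
    curve: IndentationCurve, grid: NDArray
) -> tuple[NDArray, NDArray]:
    """Interpolate measured forces onto the grid; drop depths beyond range.

    Returns (mask into grid, forces at masked grid points).  The
    zero-depth grid point is always dropped.
    """
    x = curve.depth_over_R
    usable = (grid > 0) & (grid <= x.max() + 1e-12) & (grid >= x.min() - 1e-12)
    if usable.sum() < 2:
        raise ValueError("curve depth range covers fewer than 2 grid points")
    if grid[usable][-1] < grid[-1]:
        logger.info(
            "curve shallower than the standard grid; fitting on delta/R <= %.3f",
            grid[usable][-1],
        )
    f = np.interp(grid[usable], x, curve.force)
    return usable, f


def invert_least_squares(
    model: ForwardCurveNet,
    curve: IndentationCurve,
    geom: SampleGeometry | None = None,
    n_starts: int = 5,
    seed: int = 0,
    space: DesignSpace | None = None,
    residual_scale: str = "point",
) -> InversionResult:
    """Identify ``mu`` (and ``Jm``) by least squares through the forward net.

    Minimises the mean squared force residual between the measured curve
    (interpolated onto the standard depth grid) and the network
    prediction, over ``log10 mu`` — and ``log10 Jm`` for a Gent-trained
    network — within the design bounds.  ``n_starts`` latin-hypercube
    start points; deterministic for a given ``seed``.  Ties break toward
    the lowest misfit, then the lowest ``mu``.

    ``residual_scale`` sets the residual weighting: ``"point"`` (default)
    divides each force residual by the measured force at that depth, so
    every part of a curve spanning several decades counts equally (this
    is also the homoscedastic choice under multiplicative measurement
    noise, and it keeps ``mu`` identifiable for strongly stiffening Gent
    curves whose shallow-depth response is orders of magnitude below the
    peak force); ``"max"`` divides by the curve's maximum force, i.e.
    plain absolute-force least squares.
    """
    geom = geom or curve.geometry
    if geom is None:
        raise ValueError("sample geometry required (curve.geometry or geom=)")
    space = space or (model.space if model.space is not None else DesignSpace())
    grid = depth_grid(space)
    mask, f_meas = _resample_to_grid(curve, grid)
    mask = mask[1:]  # predictions exclude the zero-depth column
    scale = f_meas.max()
    if scale <= 0:
        mu_lo = space.mu[0]
        params = (MaterialParams(Model.NEO_HOOKEAN, mu_lo)
                  if model.n_features_in_ == 3
                  else MaterialParams(Model.GENT, mu_lo, Jm=space.Jm[1]))
        return InversionResult(
            "least_squares", params, misfit_rmse=0.0, converged=False,
            at_bound=True, diagnostics={"reason": "all-zero forces"},
        )

    n_params = model.n_features_in_ - 2
    lo = [np.log10(space.mu[0])]
    hi = [np.log10(space.mu[1])]
    if n_params == 2:
        lo.append(np.log10(space.Jm[0]))
        hi.append(np.log10(space.Jm[1]))
    lo, hi = np.array(lo), np.array(hi)

    if residual_scale == "point":
        denom = np.maximum(f_meas, 1.0e-9 * scale)
    elif residual_scale == "max":
        denom = scale
    else:
        raise ValueError(f"residual_scale must be 'point' or 'max', got {residual_scale!r}")

    head = [geom.W_over_R, geom.H_over_R]

    def residuals(theta: NDArray) -> NDArray:
        row = np.array([head + list(theta)])
        pred = model.predict(row)[0][mask]
        return (pred - f_meas) / denom

    starts = qmc.scale(
        qmc.LatinHypercube(d=n_params, seed=seed).random(n_starts), lo, hi
    )
    best = None
    per_start = []
    total_nfev = 0
    any_converged = False
    for x0 in starts:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-12, diff_step=1e-5,
        )
        total_nfev += sol.nfev
        misfit = float(np.sqrt(np.mean(sol.fun**2)))
        per_start.append({"x0": x0.tolist(), "theta": sol.x.tolist(), "misfit": misfit})
        any_converged |= sol.status > 0
        key = (misfit, sol.x[0])
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    theta = np.clip(sol.x, lo, hi)
    at_bound = bool(np.any(np.isclose(theta, lo)) or np.any(np.isclose(theta, hi)))
    mu = 10.0 ** theta[0]
    if n_params == 2:
        params = MaterialParams(Model.GENT, mu, Jm=10.0 ** theta[1])
    else:
        params = MaterialParams(Model.NEO_HOOKEAN, mu)
    pred = model.predict(np.array([head + list(theta)]))[0][mask]
    return InversionResult(
        "least_squares", params,
        misfit_rmse=float(np.sqrt(np.mean((pred - f_meas) ** 2))),
        n_iterations=total_nfev, converged=any_converged, at_bound=at_bound,
        diagnostics={"starts": per_start},
    )


def invert_direct(
    model: InverseParamNet,
    curve: IndentationCurve,
    geom: SampleGeometry | None = None,
) -> InversionResult:
    """Identify parameters with one inverse-network evaluation (no iterations).

    The curve is reduced to power-law features ``(p, s)`` fitted on
    ``(delta/R, F/R^2)``; the reported misfit is the power-law fit RMSE
    in force units.
    """
    geom = geom or curve.geometry
    if geom is None:
        raise ValueError("sample geometry required (curve.geometry or geom=)")
    scaled = IndentationCurve(
        curve.depth, curve.force / curve.R**2, curve.R, curve.geometry
    )
    feats = fit_power_law(scaled)
    row = np.array([[geom.W_over_R, geom.H_over_R, np.log10(feats.p), feats.s]])
    pred = model.predict(row)[0]
    mu = 10.0 ** pred[0]
    if model.n_outputs_ == 2:
        params = MaterialParams(Model.GENT, mu, Jm=10.0 ** pred[1])
    else:
        params = MaterialParams(Model.NEO_HOOKEAN, mu)
    return InversionResult(
        "direct", params, misfit_rmse=feats.fit_rmse * curve.R**2,
        n_iterations=0,
        diagnostics={"p": feats.p, "s": feats.s},
    )


def invert_hertz(
    curve: IndentationCurve,
    geom: SampleGeometry | None = None,
    variant: HertzVariant | str = HertzVariant.HERTZ,
) -> InversionResult:
    """Closed-form (modified-)Hertzian modulus baseline."""
    geom = geom or curve.geometry
    R = geom.R if geom is not None else curve.R
    variant = HertzVariant(variant)
    mu = fit_contact_modulus(curve.depth, curve.force, R, variant)
    law = hertz_force if variant is HertzVariant.HERTZ else modified_hertz_force
    pos = curve.depth > 0
    rmse = float(np.sqrt(np.mean((law(mu, R, curve.depth[pos]) - curve.force[pos]) ** 2)))
    return InversionResult(
        variant.value, MaterialParams(Model.NEO_HOOKEAN, mu), misfit_rmse=rmse
    )


@dataclass
class EvaluationSummary:
    """Parameter-recovery quality over a set of inversions.

    ``params_true`` / ``params_pred`` keep the per-curve values so
    downstream analyses (error distributions, error-vs-parameter trends)
    need not re-run the inversions.
    """

    n: int
    mean_rel_error: dict[str, float]
    max_rel_error: dict[str, float]
    r2: dict[str, float]
    error_histogram: dict[str, tuple[list, list]]
    rmse: NDArray
    params_true: dict[str, NDArray] = field(default_factory=dict)
    params_pred: dict[str, NDArray] = field(default_factory=dict)

    def rel_errors(self, name: str = "mu") -> NDArray:
        true, pred = self.params_true[name], self.params_pred[name]
        return np.abs(pred - true) / true

    def __post_init__(self) -> None:
        for v in self.r2.values():
            if v > 1.0 + 1e-12:
                raise ValueError("R^2 cannot exceed 1")


def _r2(true_log: NDArray, pred_log: NDArray) -> float:
    ss_res = np.sum((true_log - pred_log) ** 2)
    ss_tot = np.sum((true_log - true_log.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def evaluate_inversions(
    results: list[InversionResult], truth: list[MaterialParams]
) -> EvaluationSummary:
    """Compare identified against generating parameters.

    Relative errors are on the linear parameter scale; R^2 on the log10
    scale (the parameters are log-uniform over decades).  Computed
    identically for ML and Hertz-baseline results.
    """
    if len(results) != len(truth):
        raise ValueError(f"{len(results)} results vs {len(truth)} truths")
    mu_true = np.array([t.mu for t in truth])
    mu_pred = np.array([r.params.mu for r in results])
    per_param = {"mu": (mu_true, mu_pred)}
    if all(t.model is Model.GENT for t in truth) and all(
        r.params.model is Model.GENT for r in results
    ):
        per_param["Jm"] = (
            np.array([t.Jm for t in truth]),
            np.array([r.params.Jm for r in results]),
        )
    mean_rel, max_rel, r2, hist = {}, {}, {}, {}
    for name, (true, pred) in per_param.items():
        rel = np.abs(pred - true) / true
        mean_rel[name] = float(rel.mean())
        max_rel[name] = float(rel.max())
        r2[name] = _r2(np.log10(true), np.log10(pred))
        counts, edges = np.histogram(
            rel, bins=20, range=(0.0, max(float(rel.max()) * 1.0001, 1e-12))
        )
        hist[name] = (counts.tolist(), edges.tolist())
    return EvaluationSummary(
        n=len(results),
        mean_rel_error=mean_rel,
        max_rel_error=max_rel,
        r2=r2,
        error_histogram=hist,
        rmse=np.array([r.misfit_rmse for r in results]),
        params_true={k: v[0] for k, v in per_param.items()},
        params_pred={k: v[1] for k, v in per_param.items()},
    )


def verify_by_forward_sim(
    params: MaterialParams,
    geom: SampleGeometry,
    curve: IndentationCurve,
    backend: str = "surrogate",
    coeffs: SurrogateCoeffs | None = None,
) -> float:
    """RMSE (N) between the measured curve and a fresh forward simulation
    of the identified parameters — the closing validation loop."""
    if backend != "surrogate":
        raise ValueError(f"forward verification backend {backend!r} unavailable")
    point = DesignPoint(geom.W_over_R, geom.H_over_R, params)
    pred = simulate_forces([point], curve.depth_over_R, R=geom.R, coeffs=coeffs)[0]
    return float(np.sqrt(np.mean((pred - curve.force) ** 2)))
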