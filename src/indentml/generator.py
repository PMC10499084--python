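"""Synthetic ground-truth generator for the indentation forward problem.

The generator produces smooth, monotone, power-law-like load-displacement
curves whose stiffness responds to the material parameters and to finite
sample size, mimicking the behaviour of a nonlinear finite-element
solution of a rigid sphere indenting a ``W x W x H`` block.  It is a
multiplicative corrected-Hertz model,

    F(x) = (16/3) mu R^2 x^{3/2}
           * c_depth(x) * c_thick(chi_H) * c_width(W/(R sqrt(x))) * g(x, Jm)

with ``x = delta/R`` and:

``c_depth``
    The large-depth rigid-sphere correction shared with
    :mod:`indentml.contact`.
``c_thick >= 1``
    Finite-thickness stiffening of a sample bonded to a rigid base,
    using the established bonded-incompressible polynomial in the
    contact-to-thickness ratio ``chi_H = sqrt(R delta)/H``.  Thin samples
    push back harder.
``c_width <= 1``
    Edge-compliance softening for narrow samples, an exponential decay in
    ``W / sqrt(R delta)`` calibrated so the narrowest design corner
    (``W/R = 5`` at full depth) softens forces by ~15%.
``g >= 1``
    Gent strain stiffening, ``g = 1 + k x^2 / Jm`` — the leading-order
    form of the Gent energy amplification, nonsingular over the whole
    admissible ``Jm`` range, with ``g -> 1`` as ``Jm -> inf``.

Every factor tends to 1 in the Hertzian regime (shallow depth, large wide
thick sample, ``Jm -> inf``), so the generator reduces exactly to the
Hertz law there.  Forces are exactly linear in ``mu`` (as for any
hyperelastic solid at fixed ``K/mu``).

An alternative backend writes FEBio input decks instead of evaluating the
surrogate, so a user with the finite-element solver can regenerate the
ground truth externally and harvest it back (see :mod:`indentml.febio`).
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .constitutive import MaterialParams, Model
from .contact import depth_correction
from .curves import IndentationCurve, SampleGeometry, as_curve
from .design import DesignPoint, DesignSpace, depth_grid, sample_design

__all__ = [
    "SurrogateCoeffs",
    "SyntheticDataset",
    "simulate_curve",
    "simulate_forces",
    "build_dataset",
    "DEFAULT_R",
]

#: Default indenter radius: a 25 um bead, typical of soft-tissue probes.
DEFAULT_R = 25.0e-6


@dataclass(frozen=True)
class SurrogateCoeffs:
    """Coefficients of the surrogate's correction factors (one config block).

    ``thickness`` is the bonded-incompressible finite-thickness polynomial
    ``1 + a1 chi + a2 chi^2 + a3 chi^3 + a4 chi^4``; ``width_a/width_b``
    parameterise the edge softening ``1 - a exp(-b W/sqrt(R delta))``; and
    ``gent_k`` sets the effective invariant excess ``k x^2`` driving Gent
    stiffening (0.25 at full depth).
    """

    thickness: tuple[float, ...] = (1.133, 1.283, 0.769, 0.0975)
    width_a: float = 0.6
    width_b: float = 0.2
    gent_k: float = 1.0


def _corrections(
    x: NDArray[np.float64],
    W_over_R: NDArray[np.float64] | float,
    H_over_R: NDArray[np.float64] | float,
    Jm: NDArray[np.float64] | float | None,
    coeffs: SurrogateCoeffs,
) -> NDArray[np.float64]:
    """Product of all correction factors on a broadcast grid; 1 at x=0."""
    x = np.asarray(x, dtype=float)
    sqrt_x = np.sqrt(x)
    chi = sqrt_x / np.asarray(H_over_R, dtype=float)
    c_thick = np.ones_like(chi)
    for i, a in enumerate(coeffs.thickness, start=1):
        c_thick = c_thick + a * chi**i
    with np.errstate(divide="ignore"):
        arg = np.where(sqrt_x > 0, np.asarray(W_over_R, dtype=float) / np.where(sqrt_x > 0, sqrt_x, 1.0), np.inf)
    c_width = 1.0 - coeffs.width_a * np.exp(-coeffs.width_b * arg)
    c = depth_correction(x) * c_thick * c_width
    if Jm is not None:
        c = c * (1.0 + coeffs.gent_k * x**2 / np.asarray(Jm, dtype=float))
    return c


def simulate_forces(
    points: list[DesignPoint],
    grid: NDArray[np.float64],
    R: float = DEFAULT_R,
    coeffs: SurrogateCoeffs | None = None,
) -> NDArray[np.float64]:
    """Vectorised surrogate forces (N) for many design points at once.

    Returns an ``(n_points, len(grid))`` matrix on the shared depth grid.
    """
    coeffs = coeffs or SurrogateCoeffs()
    x = np.asarray(grid, dtype=float)[None, :]
    W = np.array([p.W_over_R for p in points])[:, None]
    H = np.array([p.H_over_R for p in points])[:, None]
    mu = np.array([p.params.mu for p in points])[:, None]
    gent = [p.params.model is Model.GENT for p in points]
    if any(gent):
        if not all(gent):
            raise ValueError("cannot mix constitutive models in one batch")
        Jm = np.array([p.params.Jm for p in points])[:, None]
    else:
        Jm = None
    base = (16.0 / 3.0) * mu * R**2 * x**1.5
    return base * _corrections(x, W, H, Jm, coeffs)


def _check_in_space(point: DesignPoint, space: DesignSpace) -> None:
    checks = [
        ("W/R", point.W_over_R, space.W_over_R),
        ("H/R", point.H_over_R, space.H_over_R),
        ("mu", point.params.mu, space.mu),
    ]
    if point.params.model is Model.GENT:
        checks.append(("Jm", point.params.Jm, space.Jm))
    for name, value, (lo, hi) in checks:
        if not lo <= value <= hi:
            raise ValueError(f"{name} = {value} outside design bounds [{lo}, {hi}]")


def simulate_curve(
    point: DesignPoint,
    grid: NDArray[np.float64] | None = None,
    backend: str = "surrogate",
    *,
    space: DesignSpace | None = None,
    R: float = DEFAULT_R,
    coeffs: SurrogateCoeffs | None = None,
    deck_path=None,
):
    """Forward-simulate one design point.

    With ``backend="surrogate"`` returns an :class:`IndentationCurve`;
    with ``backend="febio_deck"`` writes a finite-element input deck to
    ``deck_path`` and returns that path (forces must then be harvested
    externally, see :func:`indentml.febio.read_harvest`).
    """
    space = space or DesignSpace()
    _check_in_space(point, space)
    grid = depth_grid(space) if grid is None else np.asarray(grid, dtype=float)
    if backend == "febio_deck":
        if deck_path is None:
            raise ValueError("backend='febio_deck' requires deck_path")
        from .febio import write_febio_deck

        return write_febio_deck(point, grid, deck_path, R=R)
    if backend != "surrogate":
        raise ValueError(f"unknown backend {backend!r}")
    forces = simulate_forces([point], grid, R=R, coeffs=coeffs)[0]
    geom = SampleGeometry(R, point.W_over_R, point.H_over_R)
    return as_curve(grid, forces, R, geom)


@dataclass
class SyntheticDataset:
    """A split of simulated curves sharing one depth grid.

    ``curves`` holds forces in N, shape ``(n, len(grid))`` including the
    zero-depth column; learning targets drop that first column.
    """

    designs: list[DesignPoint]
    grid: NDArray[np.float64]
    curves: NDArray[np.float64]
    model: Model
    split: str
    seed: int
    R: float = DEFAULT_R
    backend: str = "surrogate"
    space: DesignSpace = field(default_factory=DesignSpace)

    def __post_init__(self) -> None:
        if self.curves.shape != (len(self.designs), self.grid.size):
            raise ValueError("curve matrix shape must be (n_designs, n_grid)")

    def __len__(self) -> int:
        return len(self.designs)

    # ---- learning views -------------------------------------------------
    def design_matrix(self) -> NDArray[np.float64]:
        """(W/R, H/R, log10 mu [, log10 Jm]) rows, the forward-net inputs."""
        cols = [
            [p.W_over_R for p in self.designs],
            [p.H_over_R for p in self.designs],
            np.log10([p.params.mu for p in self.designs]),
        ]
        if self.model is Model.GENT:
            cols.append(np.log10([p.params.Jm for p in self.designs]))
        return np.column_stack(cols)

    def mu(self) -> NDArray[np.float64]:
        return np.array([p.params.mu for p in self.designs])

    def Jm(self) -> NDArray[np.float64]:
        if self.model is not Model.GENT:
            raise ValueError("Jm only defined for Gent datasets")
        return np.array([p.params.Jm for p in self.designs])

    def targets(self) -> NDArray[np.float64]:
        """Forces with the identically-zero first column dropped."""
        return self.curves[:, 1:]

    def curve(self, i: int) -> IndentationCurve:
        p = self.designs[i]
        geom = SampleGeometry(self.R, p.W_over_R, p.H_over_R)
        return as_curve(self.grid, self.curves[i], self.R, geom)

    def manifest_frame(self) -> pd.DataFrame:
        rows = {
            "W_over_R": [p.W_over_R for p in self.designs],
            "H_over_R": [p.H_over_R for p in self.designs],
            "mu": [p.params.mu for p in self.designs],
        }
        if self.model is Model.GENT:
            rows["Jm"] = [p.params.Jm for p in self.designs]
        return pd.DataFrame(rows)

    # ---- deterministic archive I/O --------------------------------------
    def save(self, path) -> None:
        """Write a deterministic ``.npz``-compatible archive with manifest.

        Identical datasets produce byte-identical files (fixed zip
        timestamps), so regeneration with the same seed is reproducible at
        the file level.
        """
        members: dict[str, bytes] = {}
        for name, arr in (("grid", self.grid), ("curves", self.curves)):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr), allow_pickle=False)
            members[name + ".npy"] = buf.getvalue()
        members["designs.csv"] = self.manifest_frame().to_csv(
            index=False, float_format="%.17g"
        ).encode()
        meta = {
            "model": self.model.value,
            "split": self.split,
            "seed": self.seed,
            "R": self.R,
            "backend": self.backend,
            "space": asdict(self.space),
        }
        members["meta.json"] = json.dumps(meta, sort_keys=True).encode()
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name in sorted(members):
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, members[name])

    @classmethod
    def load(cls, path) -> "SyntheticDataset":
        with zipfile.ZipFile(path) as zf:
            grid = np.lib.format.read_array(_io.BytesIO(zf.read("grid.npy")))
            curves = np.lib.format.read_array(_io.BytesIO(zf.read("curves.npy")))
            manifest = pd.read_csv(
                _io.BytesIO(zf.read("designs.csv")), float_precision="round_trip"
            )
            meta = json.loads(zf.read("meta.json"))
        model = Model(meta["model"])
        space_kw = dict(meta["space"])
        for key in ("W_over_R", "H_over_R", "mu", "Jm"):
            space_kw[key] = tuple(space_kw[key])
        space = DesignSpace(**space_kw)
        designs = []
        for row in manifest.itertuples(index=False):
            if model is Model.GENT:
                params = MaterialParams(model, row.mu, Jm=row.Jm)
            else:
                params = MaterialParams(model, row.mu)
            designs.append(DesignPoint(row.W_over_R, row.H_over_R, params))
        return cls(
            designs, grid, curves, model, meta["split"], meta["seed"],
            R=meta["R"], backend=meta["backend"], space=space,
        )


DEFAULT_SIZES = (10_000, 1_250, 1_250)
DEFAULT_SEEDS = (1, 2, 3)
SPLITS = ("train", "validation", "test")


def build_dataset(
    space: DesignSpace | None = None,
    model: Model | str = Model.NEO_HOOKEAN,
    sizes: tuple[int, int, int] = DEFAULT_SIZES,
    seeds: tuple[int, int, int] = DEFAULT_SEEDS,
    backend: str = "surrogate",
    R: float = DEFAULT_R,
    coeffs: SurrogateCoeffs | None = None,
) -> tuple[SyntheticDataset, SyntheticDataset, SyntheticDataset]:
    """Generate the train/validation/test splits for one material model.

    Defaults reproduce the study conditions: 10 000 / 1250 / 1250 curves
    per model on the 101-point depth grid, latin-hypercube designs with
    disjoint split seeds.
    """
    space = space or DesignSpace()
    model = Model(model)
    if any(s < 1 for s in sizes):
        raise ValueError(f"split sizes must be positive, got {sizes}")
    grid = depth_grid(space)
    if backend != "surrogate":
        raise ValueError("build_dataset only supports the surrogate backend")
    out = []
    for split, n, seed in zip(SPLITS, sizes, seeds):
        points = sample_design(space, n, model, seed=seed)
        curves = simulate_forces(points, grid, R=R, coeffs=coeffs)
        out.append(
            SyntheticDataset(points, grid, curves, model, split, seed, R=R, space=space)
        )
    return tuple(out)
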