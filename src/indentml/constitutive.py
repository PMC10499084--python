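"""Hyperelastic strain-energy densities for the indentation problem.

Two quasi-incompressible isotropic models are supported:

* **neo-Hookean** — one parameter (shear modulus ``mu``), energy linear in
  the first deviatoric invariant.  The workhorse of soft-tissue
  biomechanics because ``mu`` maps directly onto familiar stiffness
  measures (``E = 3 mu`` for an incompressible solid).
* **Gent** — two parameters (``mu``, ``Jm``).  The energy diverges as the
  invariant excess ``I1_bar - 3`` approaches the limiting value ``Jm``,
  which captures the strain stiffening seen when soft tissue is indented
  deeply.  Small ``Jm`` means strong stiffening; as ``Jm -> inf`` the model
  degenerates to neo-Hookean.

Both models use the decoupled (deviatoric + volumetric) form

    W_nH   = (mu/2) (I1_bar - 3)                  + (K/2) (ln J)^2
    W_Gent = -(mu Jm / 2) ln(1 - (I1_bar - 3)/Jm) + (K/2) (ln J)^2

with ``I1_bar`` the first invariant of the isochoric Cauchy-Green tensor,
``J`` the determinant of the deformation gradient and ``K`` the bulk
modulus.  Quasi-incompressibility is imposed by default through
``K = 1000 mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class Model(str, Enum):
    """Constitutive model tag."""

    NEO_HOOKEAN = "neo_hookean"
    GENT = "gent"


#: Default ratio of bulk to shear modulus enforcing quasi-incompressibility.
DEFAULT_K_OVER_MU = 1.0e3


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive parameters.

    Parameters
    ----------
    model:
        ``Model.NEO_HOOKEAN`` or ``Model.GENT``.
    mu:
        Shear modulus in Pa, must be positive.
    Jm:
        Gent stiffening parameter (dimensionless, positive).  Ignored for
        the neo-Hookean model.
    K:
        Bulk modulus in Pa.  Defaults to ``1000 * mu``.
    """

    model: Model
    mu: float
    Jm: float | None = None
    K: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"shear modulus must be positive, got {self.mu}")
        if self.K == 0.0:
            object.__setattr__(self, "K", DEFAULT_K_OVER_MU * self.mu)
        if self.K <= 0:
            raise ValueError(f"bulk modulus must be positive, got {self.K}")
        model = Model(self.model)
        object.__setattr__(self, "model", model)
        if model is Model.GENT:
            if self.Jm is None or self.Jm <= 0:
                raise ValueError(f"Gent model requires Jm > 0, got {self.Jm}")


@dataclass(frozen=True)
class DeformationState:
    """Pointwise deformation measures entering the strain energy.

    ``I1_bar >= 3`` (equality at the identity) and ``Jdet > 0``.
    """

    I1_bar: float
    Jdet: float = 1.0

    def __post_init__(self) -> None:
        if self.I1_bar < 3.0:
            raise ValueError(f"I1_bar must be >= 3, got {self.I1_bar}")
        if self.Jdet <= 0.0:
            raise ValueError(f"Jdet must be positive, got {self.Jdet}")


class GentLockupError(ValueError):
    """Raised when the invariant excess reaches the Gent limit ``Jm``."""


def strain_energy(params: MaterialParams, state: DeformationState) -> float:
    """Strain-energy density ``W`` in Pa at the given deformation state.

    Raises
    ------
    GentLockupError
        For the Gent model when ``I1_bar - 3 >= Jm`` (lock-up).
    """
    x = state.I1_bar - 3.0
    volumetric = 0.5 * params.K * math.log(state.Jdet) ** 2
    if params.model is Model.NEO_HOOKEAN:
        deviatoric = 0.5 * params.mu * x
    else:
        assert params.Jm is not None
        if x >= params.Jm:
            raise GentLockupError(
                f"I1_bar - 3 = {x} reaches the Gent limit Jm = {params.Jm}"
            )
        # -log1p(-x/Jm) keeps precision in the neo-Hookean limit Jm >> x.
        deviatoric = 0.5 * params.mu * params.Jm * (-math.log1p(-x / params.Jm))
    return deviatoric + volumetric


def gent_limit_check(
    mu: float,
    Jm: float,
    I1_bar: float,
    tol: float = 1.0e-6,
    *,
    eps: float = 1.0e-300,
) -> bool:
    """Whether the Gent energy matches the neo-Hookean energy within ``tol``.

    Compares the two deviatoric energies at ``(I1_bar, Jdet=1)`` in relative
    terms; states at or beyond Gent lock-up report ``False``.
    """
    nh = strain_energy(
        MaterialParams(Model.NEO_HOOKEAN, mu), DeformationState(I1_bar)
    )
    try:
        gent = strain_energy(
            MaterialParams(Model.GENT, mu, Jm=Jm), DeformationState(I1_bar)
        )
    except GentLockupError:
        return False
    return abs(gent - nh) / max(nh, eps) <= tol
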