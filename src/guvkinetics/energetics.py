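"""Pore thermodynamics and kinetics of an electrically tensed bilayer.

Thermal density fluctuations in a tensed bilayer open transient "prepores".
The free energy of a circular prepore of radius ``r`` balances the rim cost
against the tension gain:

    U(r) = 2*pi*r*Gamma - pi*(sigma_e + B)*r**2

``Gamma`` is the pore-edge (line) tension, the free energy per unit rim
length; ``sigma_e`` is the field-induced lateral tension and ``B`` a constant
electrostatic tension contribution from membrane surface charge (1.76 mN/m
for the DOPG/DOPC membranes studied here).  U has a maximum -- the
nucleation barrier -- at the critical radius ``r_c = Gamma / (sigma_e + B)``:

    U_b = pi * Gamma**2 / (sigma_e + B)

Prepores below ``r_c`` reseal; those beyond it expand irreversibly and the
vesicle ruptures.  Barrier crossing is thermally activated, so the rupture
rate constant follows an Arrhenius law

    k_r = A * exp(-U_b / (k_B * T))

with a frequency factor ``A``.  A channel-forming peptide (gramicidin A,
mole fraction ``phi``) modulates the edge tension biphasically,

    Gamma(phi) = Gamma0 + a*phi - b*phi**2

which propagates through the barrier into a non-monotonic k_r(phi).  The
coefficients ``a`` and ``b`` are free parameters of either sign; the data
decide the direction of the initial stiffening/softening.  The Helfrich
bending energy density ``E_bend = kappa/2 * (C - C0)**2`` quantifies the
curvature cost relevant to toroidal-pore formation.

All quantities are SI: Gamma in N (reported as pN at the I/O boundary),
tensions in N/m, energies in J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .electromechanics import MembraneConstants

__all__ = [
    "PoreModelParams",
    "BiphasicParams",
    "BendingParams",
    "pore_free_energy",
    "critical_radius",
    "energy_barrier",
    "rupture_rate",
    "biphasic_edge_tension",
    "biphasic_rupture_rate",
    "bending_energy",
]

#: Electrostatic tension component from membrane surface charge, N/m.
DEFAULT_B_N_PER_M = 1.76e-3


@dataclass(frozen=True)
class PoreModelParams:
    """Parameters of the prepore free-energy / Arrhenius rate model.

    Attributes
    ----------
    Gamma
        Pore-edge tension in N (typically a few pN).
    sigma_e
        Applied lateral electric tension in N/m.
    B
        Electrostatic tension component in N/m (default 1.76e-3).
    A
        Arrhenius frequency factor in 1/s.  Optional because the energetic
        quantities (barrier, critical radius) do not need it; required by
        :func:`rupture_rate`.
    """

    Gamma: float
    sigma_e: float
    B: float = DEFAULT_B_N_PER_M
    A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.Gamma < 0:
            raise ValueError(f"edge tension Gamma must be >= 0, got {self.Gamma!r}")
        if self.sigma_e < 0:
            raise ValueError(f"sigma_e must be >= 0, got {self.sigma_e!r}")
        if self.B < 0:
            raise ValueError(f"B must be >= 0, got {self.B!r}")
        if self.A is not None and not self.A > 0:
            raise ValueError(f"frequency factor A must be > 0, got {self.A!r}")

    @property
    def total_tension(self) -> float:
        """sigma_e + B, the tension that drives pore expansion (N/m)."""
        return self.sigma_e + self.B


@dataclass(frozen=True)
class BiphasicParams:
    """Quadratic model Gamma(phi) = Gamma0 + a*phi - b*phi**2.

    ``phi`` is the peptide mole fraction in [0, 1].  ``a`` and ``b`` are
    unconstrained in sign: the model only asserts a quadratic shape, and the
    fitted signs report whether low peptide content stiffens or softens the
    rim.
    """

    Gamma0: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.Gamma0 > 0:
            raise ValueError(f"Gamma0 must be strictly positive, got {self.Gamma0!r}")

    @property
    def vertex_phi(self) -> Optional[float]:
        """Mole fraction a/(2b) where Gamma(phi) is extremal, or None if b == 0."""
        if self.b == 0:
            return None
        return self.a / (2.0 * self.b)


@dataclass(frozen=True)
class BendingParams:
    """Helfrich curvature-elasticity parameters.

    kappa: bending rigidity (J); C: actual local curvature (1/m);
    C0: spontaneous curvature (1/m), e.g. induced by embedded peptide.
    """

    kappa: float
    C: float
    C0: float = 0.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"bending rigidity must be strictly positive, got {self.kappa!r}")


def pore_free_energy(r: float, params: PoreModelParams) -> float:
    """Prepore free energy U(r) = 2*pi*r*Gamma - pi*(sigma_e + B)*r**2, in J.

    The linear rim term stabilizes (resists expansion); the quadratic tension
    term destabilizes.  U crosses zero again at ``r = 2*Gamma/(sigma_e+B)``.
    """
    if r < 0:
        raise ValueError(f"pore radius must be >= 0, got {r!r}")
    return 2.0 * math.pi * r * params.Gamma - math.pi * params.total_tension * r**2


def critical_radius(params: PoreModelParams) -> float:
    """Radius r_c = Gamma / (sigma_e + B) maximizing the prepore energy, in m."""
    if params.total_tension <= 0:
        raise ZeroDivisionError(
            "total tension sigma_e + B must be strictly positive to define "
            f"a critical radius; got {params.total_tension!r}"
        )
    if not params.Gamma > 0:
        raise ValueError(f"critical radius requires Gamma > 0, got {params.Gamma!r}")
    return params.Gamma / params.total_tension


def energy_barrier(params: PoreModelParams) -> float:
    """Nucleation barrier U_b = pi*Gamma**2 / (sigma_e + B), in J.

    Equals :func:`pore_free_energy` evaluated at :func:`critical_radius`.
    """
    if params.total_tension <= 0:
        raise ZeroDivisionError(
            "total tension sigma_e + B must be strictly positive; "
            f"got {params.total_tension!r}"
        )
    return math.pi * params.Gamma**2 / params.total_tension


def rupture_rate(params: PoreModelParams, constants: MembraneConstants | None = None) -> float:
    """Arrhenius rupture rate k_r = A * exp(-U_b / k_B T), in 1/s.

    Strictly increasing in ``sigma_e`` and ``T``, strictly decreasing in
    ``Gamma``.  ``params.A`` must be set.
    """
    if constants is None:
        constants = MembraneConstants()
    if params.A is None:
        raise ValueError("rupture_rate requires the frequency factor A to be set")
    return params.A * math.exp(-energy_barrier(params) / constants.kBT)


def biphasic_edge_tension(phi: float, params: BiphasicParams) -> float:
    """Edge tension at peptide mole fraction phi: Gamma0 + a*phi - b*phi**2, in N."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"mole fraction phi must lie in [0, 1], got {phi!r}")
    return params.Gamma0 + params.a * phi - params.b * phi**2


def biphasic_rupture_rate(
    phi: float,
    bparams: BiphasicParams,
    A: float,
    sigma_e: float,
    B: float = DEFAULT_B_N_PER_M,
    constants: MembraneConstants | None = None,
) -> float:
    """Rupture rate with the biphasic edge tension: k_r(phi) = A exp(-pi Gamma(phi)^2 / ((sigma_e+B) k_B T)).

    Exactly the composition ``rupture_rate(Gamma=biphasic_edge_tension(phi))``.
    """
    gamma = biphasic_edge_tension(phi, bparams)
    if gamma < 0:
        raise ValueError(
            f"biphasic edge tension is negative ({gamma!r} N) at phi={phi!r}; "
            "the rate model requires Gamma >= 0"
        )
    return rupture_rate(PoreModelParams(Gamma=gamma, sigma_e=sigma_e, B=B, A=A), constants)


def bending_energy(params: BendingParams) -> float:
    """Helfrich bending energy density kappa/2 * (C - C0)**2, in J/m^2.

    Zero (its minimum) where the actual curvature matches the spontaneous
    one -- the condition under which highly curved structures such as
    toroidal pores become cheap.
    """
    return 0.5 * params.kappa * (params.C - params.C0) ** 2
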