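"""Electromechanics of a spherical vesicle in a uniform quasi-static field.

A giant unilamellar vesicle (GUV) in a uniform DC (or low-frequency) electric
field behaves as a thin, poorly conducting dielectric shell surrounded by
conductive aqueous media.  Solving Laplace's equation for this geometry (the
Schwan equation) gives the induced transmembrane voltage

    V_m = 1.5 * R * E * |cos(theta)|

where ``R`` is the vesicle radius, ``E`` the applied field magnitude and
``theta`` the angle between the field direction and the local bilayer normal.
``V_m`` is maximal at the two poles (``theta = 0``) and vanishes at the
equator.

The voltage stores electrostatic energy in the membrane capacitor; the
resulting Maxwell stress compresses the bilayer and appears as an in-plane
(lateral) electric tension

    sigma_e = eps_m * eps_0 * (h / (2 * h_e**2)) * V_m**2

with ``eps_m`` the relative membrane permittivity, ``h`` the membrane
thickness and ``h_e`` its dielectric (capacitive) thickness.  Combining the
two expressions at the pole gives ``sigma_e = 22.86 R^2 E^2`` mN/m with the
default constants, which is the form used to choose the field that puts a
vesicle of measured radius under a target tension.

Everything here works strictly in SI units (m, V/m, V, N/m).  Conversion to
and from laboratory units (um, V/cm, mN/m) belongs to :mod:`guvkinetics.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "BOLTZMANN_J_PER_K",
    "VACUUM_PERMITTIVITY_F_PER_M",
    "MembraneConstants",
    "FieldExposure",
    "transmembrane_voltage",
    "tension_from_voltage",
    "tension_from_field",
    "field_for_target_tension",
]

#: Boltzmann constant (exact, SI).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Vacuum permittivity rounded to three significant figures.  This rounding
#: reproduces the conventional field-tension coefficient 22.86 mN m^-1 per
#: m^2 (V/m)^2 exactly at two decimals; the CODATA value 8.8541878128e-12
#: yields 22.87 and may be substituted via :class:`MembraneConstants`.
VACUUM_PERMITTIVITY_F_PER_M = 8.85e-12


@dataclass(frozen=True)
class MembraneConstants:
    """Physical constants of the bilayer and its environment.

    Parameters
    ----------
    epsilon_m
        Relative membrane permittivity (dimensionless).  ~4.5 for a
        phospholipid bilayer.
    epsilon_0
        Vacuum permittivity in F/m.
    h
        Membrane thickness in m (~4 nm).
    h_e
        Membrane dielectric thickness in m (~2.8 nm); must not exceed ``h``.
    T
        Absolute temperature in K.  Default 298.15 K (25 degC, the
        temperature at which the rupture experiments are run).
    k_B
        Boltzmann constant in J/K.
    """

    epsilon_m: float = 4.5
    epsilon_0: float = VACUUM_PERMITTIVITY_F_PER_M
    h: float = 4e-9
    h_e: float = 2.8e-9
    T: float = 298.15
    k_B: float = BOLTZMANN_J_PER_K

    def __post_init__(self) -> None:
        for name in ("epsilon_m", "epsilon_0", "h", "h_e", "T", "k_B"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.h_e > self.h:
            raise ValueError(
                f"dielectric thickness h_e={self.h_e} exceeds membrane thickness h={self.h}"
            )

    @property
    def kBT(self) -> float:
        """Thermal energy k_B * T in J."""
        return self.k_B * self.T

    @property
    def tension_prefactor(self) -> float:
        """eps_m * eps_0 * h / (2 * h_e**2), in N/m per V^2."""
        return self.epsilon_m * self.epsilon_0 * self.h / (2.0 * self.h_e**2)

    @property
    def field_tension_coefficient(self) -> float:
        """Coefficient of R^2 E^2 in the pole tension, in N/m per m^2 (V/m)^2.

        Equals ``1.5**2 * tension_prefactor``; 22.86e-3 with the defaults.
        """
        return 2.25 * self.tension_prefactor


@dataclass(frozen=True)
class FieldExposure:
    """One field application: magnitude, orientation and observation window.

    The pulse waveform parameters (``pulse_frequency_hz``, ``pulse_on_time_s``)
    are carried as annotation only: under the quasi-static assumption the duty
    cycle does not alter the induced tension, so they never enter a
    computation.
    """

    E: float
    theta: float = 0.0
    duration: float = 60.0
    pulse_frequency_hz: Optional[float] = None
    pulse_on_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError(f"field magnitude must be >= 0, got {self.E!r}")
        if not 0.0 <= self.theta <= math.pi / 2:
            raise ValueError(f"theta must lie in [0, pi/2], got {self.theta!r}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration!r}")


def transmembrane_voltage(R: float, E: float, theta: float = 0.0) -> float:
    """Induced transmembrane voltage of a spherical shell, V_m = 1.5 R E |cos theta|.

    Parameters
    ----------
    R
        Vesicle radius in m (> 0).
    E
        Applied field magnitude in V/m (>= 0).
    theta
        Angle between field and bilayer normal in radians.  The default 0
        (pole) gives the maximal voltage, which sets the rupture threshold.

    Returns
    -------
    float
        Transmembrane voltage in V.
    """
    if not R > 0:
        raise ValueError(f"vesicle radius must be strictly positive, got {R!r}")
    if E < 0:
        raise ValueError(f"field magnitude must be >= 0, got {E!r}")
    return 1.5 * R * E * abs(math.cos(theta))


def tension_from_voltage(V_m: float, constants: MembraneConstants | None = None) -> float:
    """Lateral electric tension induced by a transmembrane voltage.

    sigma_e = eps_m * eps_0 * (h / (2 h_e^2)) * V_m^2, in N/m.
    """
    if constants is None:
        constants = MembraneConstants()
    if V_m < 0:
        raise ValueError(f"transmembrane voltage must be >= 0, got {V_m!r}")
    return constants.tension_prefactor * V_m**2


def tension_from_field(R: float, E: float, constants: MembraneConstants | None = None) -> float:
    """Pole tension from radius and field: composes the Schwan voltage with
    the capacitive tension at ``theta = 0``.

    With default constants this equals ``22.86e-3 * R**2 * E**2`` N/m.
    """
    if constants is None:
        constants = MembraneConstants()
    return tension_from_voltage(transmembrane_voltage(R, E, 0.0), constants)


def field_for_target_tension(
    R: float, sigma_target: float, constants: MembraneConstants | None = None
) -> float:
    """Field magnitude that puts a vesicle of radius ``R`` under ``sigma_target``.

    Closed-form inverse of :func:`tension_from_field`:
    ``E = sqrt(sigma / coeff) / R`` with ``coeff = 2.25 eps_m eps_0 h / (2 h_e^2)``.
    This mirrors the experimental protocol, where the field is chosen per
    vesicle from its measured radius so every vesicle experiences the same
    target tension.

    Parameters
    ----------
    R
        Vesicle radius in m (> 0).
    sigma_target
        Target lateral tension in N/m (> 0).

    Returns
    -------
    float
        Field magnitude in V/m.
    """
    if constants is None:
        constants = MembraneConstants()
    if not R > 0:
        raise ValueError(f"vesicle radius must be strictly positive, got {R!r}")
    if not sigma_target > 0:
        raise ValueError(f"target tension must be strictly positive, got {sigma_target!r}")
    return math.sqrt(sigma_target / constants.field_tension_coefficient) / R
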