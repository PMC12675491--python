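"""Water properties of the settling medium.

Sedimentation velocity depends on the medium through its mass density
``rho_sw`` (buoyancy) and its kinematic viscosity ``nu`` (laminar drag).
Both are derived here from temperature and practical salinity using
published standard-seawater correlations:

* mass density: the one-atmosphere International Equation of State of
  Seawater (EOS-80; Millero & Poisson 1981 polynomial),
* dynamic viscosity: the Sharqawy, Lienhard & Zubair (2010) correlation
  (IAPWS-consistent pure-water term plus a salinity correction), with
  ``nu = mu / rho_sw``.

All quantities are SI (kg m^-3, m^2 s^-1, m s^-2).  Users who want to fix
the medium to known values — e.g. the study-median conditions of a
measurement campaign — can bypass the correlations with
:func:`override_properties`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidityError

#: default gravitational acceleration, m s^-2
STANDARD_GRAVITY = 9.81

__all__ = [
    "MediumProperties",
    "water_properties",
    "override_properties",
    "seawater_density",
    "seawater_viscosity",
    "STANDARD_GRAVITY",
    "STUDY_MEDIAN_MEDIUM",
]


@dataclass(frozen=True)
class MediumProperties:
    """State of the water column relevant to particle settling.

    Attributes
    ----------
    rho_sw : float
        Mass density of the water, kg m^-3.
    nu : float
        Kinematic viscosity, m^2 s^-1.
    g : float
        Gravitational acceleration, m s^-2.
    temperature, salinity : float or None
        The (T, S) state the properties were derived from; ``None`` when
        the properties were supplied directly.
    """

    rho_sw: float
    nu: float
    g: float = STANDARD_GRAVITY
    temperature: float | None = None
    salinity: float | None = None

    def __post_init__(self) -> None:
        for name in ("rho_sw", "nu", "g"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidityError(f"{name} must be strictly positive, got {value!r}")


def seawater_density(temperature, salinity):
    """One-atmosphere seawater density, kg m^-3 (EOS-80).

    Millero & Poisson (1981) polynomial in temperature (deg C, ITS-68 vs
    ITS-90 differences are negligible here) and practical salinity.
    Accepts scalars or arrays.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    rho = rho_w + a * s + b * s**1.5 + c * s**2
    return rho if rho.ndim else float(rho)


def seawater_viscosity(temperature, salinity):
    """Dynamic viscosity of seawater, Pa s (Sharqawy et al. 2010).

    Pure-water term valid 0-180 deg C; salinity correction uses salinity
    expressed as a mass fraction (kg/kg), for which practical salinity in
    psu divided by 1000 is an adequate proxy at this accuracy level.
    """
    t = np.asarray(temperature, dtype=float)
    sk = np.asarray(salinity, dtype=float) / 1000.0
    mu_w = 4.2844e-5 + 1.0 / (0.157 * (t + 64.993) ** 2 - 91.296)
    a = 1.541 + 1.998e-2 * t - 9.52e-5 * t**2
    b = 7.974 - 7.561e-2 * t + 4.724e-4 * t**2
    mu = mu_w * (1.0 + a * sk + b * sk**2)
    return mu if mu.ndim else float(mu)


def water_properties(
    temperature: float, salinity: float, g: float = STANDARD_GRAVITY
) -> MediumProperties:
    """Derive the medium state from temperature and salinity.

    Parameters
    ----------
    temperature : float
        Water temperature, deg C; must be in [0, 40].
    salinity : float
        Practical salinity, psu; must be in [0, 42].
    g : float
        Gravitational acceleration, m s^-2.

    Returns
    -------
    MediumProperties
        With ``rho_sw`` from EOS-80 and ``nu = mu/rho_sw`` from the
        Sharqawy correlation.  Pure function of its inputs.
    """
    if not (0.0 <= temperature <= 40.0):
        raise ValidityError(
            f"temperature must be within [0, 40] deg C, got {temperature!r}"
        )
    if not (0.0 <= salinity <= 42.0):
        raise ValidityError(f"salinity must be within [0, 42] psu, got {salinity!r}")
    rho = seawater_density(temperature, salinity)
    mu = seawater_viscosity(temperature, salinity)
    return MediumProperties(
        rho_sw=rho, nu=mu / rho, g=g, temperature=temperature, salinity=salinity
    )


def override_properties(
    rho_sw: float, nu: float, g: float = STANDARD_GRAVITY
) -> MediumProperties:
    """Build a medium directly from known (rho_sw, nu, g).

    Use this to inject measured or published medium conditions instead of
    the correlations; temperature and salinity are left unset.
    """
    return MediumProperties(rho_sw=rho_sw, nu=nu, g=g)


#: Median medium conditions of the settling experiments this package's
#: fitted model constants derive from: nu = 1.0915e-6 m^2 s^-1,
#: rho_sw = 1009.45 kg m^-3 (brackish Baltic-type water, ~15 psu).
STUDY_MEDIAN_MEDIUM = override_properties(rho_sw=1009.45, nu=1.0915e-6)
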