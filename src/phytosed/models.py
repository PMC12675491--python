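"""Sedimentation-velocity equations and drag-coefficient models.

All models solve the steady force balance between effective weight and
drag for a particle of density rho settling in water of density rho_sw:

    omega = sqrt( (4/3) * (rho/rho_sw - 1) * g * d / C_D )

For non-spherical particles the nominal diameter d_n replaces d, and the
ellipsoid correction of Riazi & Tuerker multiplies the numerator by
S_f^(2/3).  The drag coefficient follows the two-group dimensionless form

    C_D = ( X2 * nu / (d_n^1.5 * g^0.5) + X3 )^X1

whose first term dominates in the laminar limit and whose additive
constant captures the turbulent limit.  Three empirical closures with
fitted constants are shipped as presets:

* Model A — no shape dependence; C_D = k * nu / (d_n * g).  Note this
  drag group is not dimensionless, so the constant is bound to SI units.
* Model B — shape only in the numerator; C_D = k * nu / (d_n^1.5 g^0.5).
* Model C — shape also inside C_D: the laminar coefficient grows with
  S_f and two high-power S_f terms cut the drag base down near sphere
  shapes.  The base can become non-positive for S_f above roughly 0.25
  (depending on d_n and nu): the model structure is then outside its
  domain of validity and evaluation is refused with diagnostics rather
  than returning a number.

All evaluation is strictly SI (m, kg, s).  The population-vectorised
entry point :func:`evaluate_structure` broadcasts a (pop, k) constant
matrix against n observations and is what the genetic-algorithm fitter
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import BuoyancyError, DomainError, ValidityError
from .medium import MediumProperties
from .traits import ParticleTraits

__all__ = [
    "ModelSpec",
    "VelocityPrediction",
    "MODEL_A",
    "MODEL_B",
    "MODEL_C",
    "preset",
    "general_velocity",
    "riazi_velocity",
    "drag_riazi",
    "model_a",
    "model_b",
    "model_c",
    "predict",
    "evaluate_structure",
    "prediction_surface",
]

CONSTANT_NAMES = {
    "A": ("k_drag",),
    "B": ("k_drag",),
    "C": (
        "k_lam0",
        "k_lam1",
        "k_turb0",
        "k_turb1",
        "p_turb1",
        "k_turb2",
        "p_turb2",
        "p_outer",
    ),
    "generic_riazi": ("X1", "X2", "X3"),
}

_PRESETS = {
    "A": (4567661.0,),
    "B": (4146.337,),
    "C": (198.3826, 34121.98, 0.8906959, 9939.812, 2.972455, 87764.06, 52.04557, 5.566767),
}


@dataclass(frozen=True)
class ModelSpec:
    """A model structure together with its constant vector.

    ``structure`` is one of ``"A"``, ``"B"``, ``"C"`` or
    ``"generic_riazi"``; ``constants`` must match the structure's arity.
    Constants are bound to SI inputs (see module docstring).
    """

    structure: str
    constants: tuple = field(default=())
    units_note: str = "SI-bound"

    def __post_init__(self) -> None:
        if self.structure not in CONSTANT_NAMES:
            raise ValidityError(f"unknown model structure {self.structure!r}")
        object.__setattr__(self, "constants", tuple(float(c) for c in self.constants))
        expected = len(CONSTANT_NAMES[self.structure])
        if len(self.constants) != expected:
            raise ValidityError(
                f"structure {self.structure} takes {expected} constants, "
                f"got {len(self.constants)}"
            )

    @property
    def constant_names(self) -> tuple:
        return CONSTANT_NAMES[self.structure]

    def as_dict(self) -> dict:
        return dict(zip(self.constant_names, self.constants))


def preset(structure: str) -> ModelSpec:
    """The published fitted constants for structure A, B or C."""
    if structure not in _PRESETS:
        raise ValidityError(f"no preset constants for structure {structure!r}")
    return ModelSpec(structure, _PRESETS[structure])


MODEL_A = preset("A")
MODEL_B = preset("B")
MODEL_C = preset("C")


@dataclass(frozen=True)
class VelocityPrediction:
    """One model evaluation: settling velocity, drag, and validity."""

    omega: float
    c_d: float
    in_domain: bool
    diagnostics: str = ""


def _pow(base, exponent):
    # exp(p * log s): numerically exact for positive base, underflow -> 0
    with np.errstate(under="ignore"):
        return np.exp(np.asarray(exponent) * np.log(base))


def _check_buoyant(rho, rho_sw):
    if np.any(np.asarray(rho) < np.asarray(rho_sw)):
        raise BuoyancyError(
            f"particle density {rho!r} is below the water density {rho_sw!r}: "
            "the particle floats and has no settling velocity"
        )


def general_velocity(
    rho: float, medium: MediumProperties, d: float, c_d: float
) -> float:
    """Settling velocity from the drag/weight balance, m s^-1.

    omega = sqrt((4/3) * (rho/rho_sw - 1) * g * d / C_D).  Requires
    rho >= rho_sw (floats raise :class:`BuoyancyError`) and C_D > 0.
    """
    _check_buoyant(rho, medium.rho_sw)
    if d <= 0:
        raise ValidityError(f"diameter must be positive, got {d!r}")
    if c_d <= 0:
        raise DomainError(f"drag coefficient must be positive, got {c_d!r}")
    return float(np.sqrt((4.0 / 3.0) * (rho / medium.rho_sw - 1.0) * medium.g * d / c_d))


def riazi_velocity(
    traits: ParticleTraits, medium: MediumProperties, c_d: float
) -> float:
    """Ellipsoid-corrected settling velocity: numerator carries S_f^(2/3)."""
    if not (0.0 < traits.s_f <= 1.0):
        raise ValidityError(f"s_f must lie in (0, 1], got {traits.s_f!r}")
    return general_velocity(
        traits.rho, medium, traits.d_n * _pow(traits.s_f, 2.0 / 3.0), c_d
    )


def drag_riazi(
    traits: ParticleTraits, medium: MediumProperties, x1: float, x2: float, x3: float
) -> float:
    """Drag coefficient C_D = (X2 * nu / (d_n^1.5 g^0.5) + X3)^X1.

    The group nu / (d_n^1.5 g^0.5) is dimensionless, so the constants
    are pure numbers.  A non-positive base is a :class:`DomainError`.
    """
    base = x2 * medium.nu / (traits.d_n**1.5 * medium.g**0.5) + x3
    if base <= 0:
        raise DomainError(f"drag base is non-positive: base = {base!r}")
    return float(_pow(base, x1))


def _omega_squared_numerator(rho, rho_sw, g, d_n, sf_factor):
    return (4.0 / 3.0) * (rho / rho_sw - 1.0) * g * d_n * sf_factor


def evaluate_structure(structure, constants, d_n, s_f, rho, rho_sw, nu, g):
    """Vectorised model evaluation.

    Parameters
    ----------
    constants : array, shape (k,) or (pop, k)
        One constant vector or a population of them.
    d_n, s_f, rho : array, shape (n,)
        Particle descriptors (SI).
    rho_sw, nu, g : array, shape (n,) or scalar
        Medium state per observation.

    Returns
    -------
    omega, c_d, in_domain : arrays broadcast to (n,) or (pop, n)
        ``omega`` is NaN where ``in_domain`` is False.  Buoyant cells
        (rho < rho_sw) are out of domain; neutral buoyancy gives
        omega = 0 exactly.
    """
    theta = np.atleast_2d(np.asarray(constants, dtype=float))[:, :, None]  # (pop,k,1)
    d_n = np.asarray(d_n, dtype=float)
    s_f = np.asarray(s_f, dtype=float)
    rho = np.asarray(rho, dtype=float)
    rho_sw = np.asarray(rho_sw, dtype=float)
    nu = np.asarray(nu, dtype=float)
    g = np.asarray(g, dtype=float)

    lam_group = nu / (_pow(d_n, 1.5) * np.sqrt(g))  # dimensionless laminar group
    if structure == "A":
        c_d = theta[:, 0] * nu / (d_n * g)
        sf_factor = 1.0
    elif structure == "B":
        c_d = theta[:, 0] * lam_group
        sf_factor = _pow(s_f, 2.0 / 3.0)
    elif structure == "C":
        k_lam0, k_lam1, k_turb0, k_turb1, p_turb1, k_turb2, p_turb2, p_outer = (
            theta[:, i] for i in range(8)
        )
        base = (
            (k_lam0 + k_lam1 * s_f) * lam_group
            + k_turb0
            - k_turb1 * _pow(s_f, p_turb1)
            - k_turb2 * _pow(s_f, p_turb2)
        )
        with np.errstate(invalid="ignore", divide="ignore", under="ignore"):
            c_d = np.where(base > 0, _pow(np.where(base > 0, base, 1.0), p_outer), np.nan)
        sf_factor = _pow(s_f, 2.0 / 3.0)
    elif structure == "generic_riazi":
        x1, x2, x3 = (theta[:, i] for i in range(3))
        base = x2 * lam_group + x3
        with np.errstate(invalid="ignore", under="ignore"):
            c_d = np.where(base > 0, _pow(np.where(base > 0, base, 1.0), x1), np.nan)
        sf_factor = _pow(s_f, 2.0 / 3.0)
    else:
        raise ValidityError(f"unknown model structure {structure!r}")

    numerator = _omega_squared_numerator(rho, rho_sw, g, d_n, sf_factor)
    numerator = np.broadcast_to(numerator, c_d.shape)
    in_domain = np.isfinite(c_d) & (c_d > 0) & (numerator >= 0)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        omega = np.where(in_domain, np.sqrt(np.where(in_domain, numerator / c_d, 0.0)), np.nan)

    if np.asarray(constants).ndim == 1:
        return omega[0], c_d[0], in_domain[0]
    return omega, c_d, in_domain


def _predict_single(spec: ModelSpec, traits: ParticleTraits, medium: MediumProperties):
    _check_buoyant(traits.rho, medium.rho_sw)
    if spec.structure in ("B", "C") and not (0.0 < traits.s_f <= 1.0):
        raise ValidityError(f"s_f must lie in (0, 1], got {traits.s_f!r}")
    omega, c_d, ok = evaluate_structure(
        spec.structure,
        np.asarray(spec.constants),
        np.array([traits.d_n]),
        np.array([traits.s_f]),
        np.array([traits.rho]),
        medium.rho_sw,
        medium.nu,
        medium.g,
    )
    if not ok[0]:
        raise DomainError(
            f"model {spec.structure} drag base is non-positive at "
            f"d_n = {traits.d_n:.4g} m, s_f = {traits.s_f:.4g}: the structure "
            "is outside its domain of validity (high shape factors)"
        )
    return VelocityPrediction(
        omega=float(omega[0]), c_d=float(c_d[0]), in_domain=True
    )


def predict(
    spec: ModelSpec, traits: ParticleTraits, medium: MediumProperties
) -> VelocityPrediction:
    """Evaluate any model spec for one specimen (SI inputs only)."""
    return _predict_single(spec, traits, medium)


def model_a(traits: ParticleTraits, medium: MediumProperties) -> VelocityPrediction:
    """Shape-blind model: C_D = 4567661 * nu / (d_n g)."""
    return _predict_single(MODEL_A, traits, medium)


def model_b(traits: ParticleTraits, medium: MediumProperties) -> VelocityPrediction:
    """Shape in the numerator only: C_D = 4146.337 * nu / (d_n^1.5 g^0.5)."""
    return _predict_single(MODEL_B, traits, medium)


def model_c(traits: ParticleTraits, medium: MediumProperties) -> VelocityPrediction:
    """Shape both in the numerator and inside C_D (best for macrophytes).

    Refuses evaluation (DomainError) when the inner drag base is
    non-positive, which occurs for sphere-like shapes (high S_f).
    """
    return _predict_single(MODEL_C, traits, medium)


def prediction_surface(
    spec: ModelSpec,
    medium: MediumProperties,
    rho: float,
    d_n_grid,
    s_f_grid,
):
    """Evaluate a model over a (s_f, d_n) grid at fixed particle density.

    Returns ``(omega, in_domain)`` arrays of shape
    ``(len(s_f_grid), len(d_n_grid))``; out-of-domain cells are masked
    (NaN omega, False mask) instead of raising, so a partially valid
    surface can still be drawn.
    """
    d_n_grid = np.asarray(d_n_grid, dtype=float)
    s_f_grid = np.asarray(s_f_grid, dtype=float)
    if d_n_grid.size == 0 or s_f_grid.size == 0:
        raise ValidityError("grids must be non-empty")
    if np.any(d_n_grid <= 0) or np.any(s_f_grid <= 0):
        raise ValidityError("grid values must be strictly positive")
    dd, ss = np.meshgrid(d_n_grid, s_f_grid)
    omega, _, ok = evaluate_structure(
        spec.structure,
        np.asarray(spec.constants),
        dd.ravel(),
        ss.ravel(),
        np.full(dd.size, rho),
        medium.rho_sw,
        medium.nu,
        medium.g,
    )
    return omega.reshape(dd.shape), ok.reshape(dd.shape)
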