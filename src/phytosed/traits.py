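"""Particle descriptors: nominal diameter, mass density, Corey shape factor.

Three measurable traits — volume V, wet weight W and shape — suffice to
predict the still-water settling velocity of a macrophyte or plastic
object.  Shape enters through the Corey shape factor

    S_f = c / sqrt(a b)

over the longest (a), intermediate (b) and shortest (c) mutually
perpendicular axes; S_f = 1 for a sphere and << 1 for blades and
filaments.  For irregular thalli the three axes cannot all be measured
directly, so two derivation routes are used, both resting on the
ellipsoid-like closure V = a*b*c:

* flattened thalli (leaves, blades, also unbranched cylinders scanned
  flat): the scanned projection area P is taken as a*b and the thickness
  follows as c = V/P, hence S_f = V * P^(-3/2);
* three-dimensionally branched thalli: the mean width of the youngest
  branches is taken as c and a*b = V/c, hence S_f = c^(3/2) / sqrt(V);
* rigid objects (disks, balls): axes (a, b, c) measured directly.

The nominal diameter d_n = 2 * (3V / 4 pi)^(1/3) is the diameter of the
volume-equivalent sphere and carries the size dependence of the models.
All functions are SI-only (m, kg); unit conversion happens at the table
I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidityError
from .medium import MediumProperties

__all__ = [
    "ParticleTraits",
    "nominal_diameter",
    "corey_shape_factor",
    "shape_factor_flattened",
    "shape_factor_branched",
    "mass_density",
    "classify_buoyancy",
    "average_replicates",
    "MORPHOLOGIES",
]

MORPHOLOGIES = ("flattened", "cylindrical_or_branched", "direct_axes")


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidityError(f"{name} must be strictly positive and finite, got {value!r}")
    return arr


def nominal_diameter(volume):
    """Diameter of the sphere with the particle's volume, m.

    d_n = 2 * (3 V / (4 pi))**(1/3).  Strictly increasing in V and
    independent of shape.  Accepts scalars or arrays (m^3 in, m out).
    """
    v = _require_positive("volume", volume)
    d = 2.0 * np.cbrt(3.0 * v / (4.0 * np.pi))
    return d if d.ndim else float(d)


def volume_from_nominal_diameter(d_n):
    """Inverse of :func:`nominal_diameter`: V = pi d_n^3 / 6."""
    d = _require_positive("d_n", d_n)
    v = np.pi * d**3 / 6.0
    return v if v.ndim else float(v)


def corey_shape_factor(a: float, b: float, c: float) -> float:
    """Corey shape factor S_f = c / sqrt(a b) from the three axes, m.

    Axes must be the longest, intermediate and shortest mutually
    perpendicular diameters; unsorted inputs are reordered with a
    warning.  Result lies in (0, 1], reaching 1 only for a = b = c.
    """
    for name, v in (("a", a), ("b", b), ("c", c)):
        _require_positive(name, v)
    if not (a >= b >= c):
        tol = 1e-9 * max(a, b, c)
        if (b - a) > tol or (c - b) > tol:
            warnings.warn(
                "axes not in descending order; reordering (a >= b >= c)", stacklevel=2
            )
        a, b, c = sorted((a, b, c), reverse=True)
    return c / np.sqrt(a * b)


def _clamp_unit_sf(s_f: float, message: str) -> float:
    # rounding in the derived routes can push an exact sphere a few ulp
    # past 1; anything beyond noise is a real misclassification
    if s_f > 1.0 + 1e-9:
        raise ValidityError(message.format(s_f))
    return min(s_f, 1.0)


def shape_factor_flattened(projection_area: float, volume: float) -> tuple[float, float]:
    """Shape factor via the flattened-thallus route.

    The scanned projection area P stands in for the axis product a*b, and
    the thickness follows from the volume closure: c = V/P.  Returns
    ``(c, s_f)`` with s_f = c / sqrt(P) = V * P^(-1.5).

    Raises
    ------
    ValidityError
        If the derived s_f exceeds 1 — the shape is then not flattened
        and the morphology was misclassified.
    """
    p = float(_require_positive("projection_area", projection_area))
    v = float(_require_positive("volume", volume))
    c = v / p
    s_f = _clamp_unit_sf(
        c / np.sqrt(p),
        "flattened route gives s_f = {:.4g} > 1: thickness exceeds the "
        "planform scale, so the specimen is not flattened",
    )
    return c, s_f


def shape_factor_branched(branch_width: float, volume: float) -> tuple[float, float]:
    """Shape factor via the branched-thallus route.

    The mean width of the youngest branches stands in for the shortest
    axis c, and a*b = V/c by the volume closure.  Returns ``(ab, s_f)``
    with s_f = c / sqrt(V/c) = c^(1.5) / sqrt(V).

    Raises
    ------
    ValidityError
        If the derived s_f exceeds 1 (branch width too large for the
        volume: morphology misclassified).
    """
    c = float(_require_positive("branch_width", branch_width))
    v = float(_require_positive("volume", volume))
    ab = v / c
    s_f = _clamp_unit_sf(
        c / np.sqrt(ab),
        "branched route gives s_f = {:.4g} > 1: branch width is larger "
        "than the volume supports",
    )
    return ab, s_f


def mass_density(wet_weight: float, volume: float) -> float:
    """Particle mass density rho = W / V, kg m^-3 (blotting weight over volume)."""
    w = float(_require_positive("wet_weight", wet_weight))
    v = float(_require_positive("volume", volume))
    return w / v


def classify_buoyancy(rho: float, medium: MediumProperties) -> tuple[str, bool]:
    """Classify a particle as ``"sinking"`` or ``"floating"`` in a medium.

    Returns ``(label, tie)``.  Sinking requires rho strictly above the
    water density; exact neutral buoyancy is classed floating with the
    tie flag set (no settling velocity exists either way).
    """
    _require_positive("rho", rho)
    if rho > medium.rho_sw:
        return "sinking", False
    return "floating", rho == medium.rho_sw


def average_replicates(values, rel_tol: float = 0.05) -> float:
    """Mean of replicate measurements with a quality-control warning.

    Replicate volume/weight measurements are averaged; when the spread
    (max - min) exceeds ``rel_tol`` of the mean the measurement protocol
    would have demanded a further replicate, so a warning is raised but
    no data are discarded.
    """
    arr = _require_positive("replicates", values)
    if arr.ndim == 0:
        return float(arr)
    mean = float(arr.mean())
    if arr.size > 1 and (arr.max() - arr.min()) > rel_tol * mean:
        warnings.warn(
            f"replicates diverge by more than {rel_tol:.0%} of their mean",
            stacklevel=2,
        )
    return mean


@dataclass
class ParticleTraits:
    """Measured and derived descriptors of one specimen (SI units).

    Built through :meth:`from_measurements`, which dispatches on the
    morphology class to the matching axis-derivation route and fills the
    derived fields (rho, d_n, s_f).
    """

    specimen_id: str
    volume: float
    wet_weight: float
    morphology: str
    species: str = ""
    projection_area: float | None = None
    branch_width: float | None = None
    axes: tuple[float, float, float] | None = None
    rho: float = field(init=False)
    d_n: float = field(init=False)
    s_f: float = field(init=False)

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValidityError(
                f"morphology must be one of {MORPHOLOGIES}, got {self.morphology!r}"
            )
        self.rho = mass_density(self.wet_weight, self.volume)
        self.d_n = nominal_diameter(self.volume)
        if self.morphology == "flattened":
            if self.projection_area is None:
                raise ValidityError("flattened morphology requires projection_area")
            _, self.s_f = shape_factor_flattened(self.projection_area, self.volume)
        elif self.morphology == "cylindrical_or_branched":
            if self.branch_width is None:
                raise ValidityError(
                    "cylindrical_or_branched morphology requires branch_width"
                )
            _, self.s_f = shape_factor_branched(self.branch_width, self.volume)
        else:
            if self.axes is None:
                raise ValidityError("direct_axes morphology requires axes (a, b, c)")
            self.s_f = corey_shape_factor(*self.axes)

    @classmethod
    def from_measurements(
        cls,
        specimen_id: str,
        morphology: str,
        volume_replicates,
        weight_replicates,
        species: str = "",
        **route_fields,
    ) -> "ParticleTraits":
        """Construct from replicate raw measurements (SI units)."""
        return cls(
            specimen_id=specimen_id,
            volume=average_replicates(volume_replicates),
            wet_weight=average_replicates(weight_replicates),
            morphology=morphology,
            species=species,
            **route_fields,
        )

    def is_sinking(self, medium: MediumProperties) -> bool:
        return classify_buoyancy(self.rho, medium)[0] == "sinking"
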