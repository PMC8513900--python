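"""Fruit surface-area geometry.

Converts caliper measurements of a developing fruit (length and two
orthogonal equatorial diameters, in mm) into surface areas (cm^2), and
corrects the cross-sectional area of a punched skin disc for the local
curvature of the fruit surface.

Two area models are provided: a sphere on the mean diameter and a spheroid
(prolate or oblate, closed forms) that uses all three measured dimensions.
The spheroid is the package default because it uses the full measurement;
the sphere is retained for comparability with the simpler convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FruitDimensions",
    "DiscGeometry",
    "surface_area_sphere",
    "surface_area_spheroid",
    "curvature_corrected_disc_area",
    "equivalent_sphere_radius_mm",
]

MM2_PER_CM2 = 100.0


class GeometryError(ValueError):
    """Raised for geometrically impossible inputs (e.g. punch wider than fruit)."""


@dataclass(frozen=True)
class FruitDimensions:
    """Caliper measurements of one fruit.

    Parameters
    ----------
    length_mm : float
        Polar-axis length in mm.
    diam1_mm, diam2_mm : float
        Two orthogonal equatorial diameters in mm.
    mass_g : float, optional
        Fresh mass in g; carried through for reporting only.
    max_diameter_ratio : float
        Sanity gate: the two equatorial diameters must be within this
        factor of each other (default 10).
    """

    length_mm: float
    diam1_mm: float
    diam2_mm: float
    mass_g: float | None = None
    max_diameter_ratio: float = 10.0

    def __post_init__(self) -> None:
        for name in ("length_mm", "diam1_mm", "diam2_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        lo, hi = sorted((self.diam1_mm, self.diam2_mm))
        if hi / lo > self.max_diameter_ratio:
            raise ValueError(
                f"equatorial diameters differ by more than {self.max_diameter_ratio}x"
            )

    @property
    def equatorial_diameter_mm(self) -> float:
        return 0.5 * (self.diam1_mm + self.diam2_mm)


@dataclass(frozen=True)
class DiscGeometry:
    """A biopsy punch on a curved fruit surface.

    ``fruit_radius_mm`` is the local radius of curvature; ``None`` means the
    disc is treated as flat.
    """

    punch_diameter_mm: float
    fruit_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.punch_diameter_mm <= 0:
            raise ValueError("punch_diameter_mm must be > 0")
        if self.fruit_radius_mm is not None:
            if self.fruit_radius_mm <= 0:
                raise ValueError("fruit_radius_mm must be > 0 when given")
            if self.punch_diameter_mm / 2.0 > self.fruit_radius_mm:
                raise GeometryError(
                    "punch radius exceeds fruit radius of curvature "
                    f"({self.punch_diameter_mm / 2.0} > {self.fruit_radius_mm} mm)"
                )


def surface_area_sphere(mean_diameter_mm: float) -> float:
    """Surface area (cm^2) of a sphere with the given diameter (mm)."""
    if mean_diameter_mm <= 0:
        raise ValueError("mean_diameter_mm must be > 0")
    return math.pi * mean_diameter_mm**2 / MM2_PER_CM2


def surface_area_spheroid(dims: FruitDimensions) -> float:
    """Surface area (cm^2) of a spheroid fit to the measured dimensions.

    The two equatorial diameters are averaged into a single equatorial
    radius ``b``; the polar radius is ``a = length/2``.  The exact prolate
    (a > b), oblate (a < b) or sphere (a == b) closed form is used; the
    three branches join continuously.
    """
    a = dims.length_mm / 2.0  # polar radius
    b = dims.equatorial_diameter_mm / 2.0  # equatorial radius
    area_mm2 = _spheroid_area_mm2(a, b)
    return area_mm2 / MM2_PER_CM2


def _spheroid_area_mm2(a: float, b: float) -> float:
    # relative eccentricity below ~1e-7 is numerically a sphere
    if math.isclose(a, b, rel_tol=1e-12):
        return 4.0 * math.pi * a * b
    if a > b:  # prolate: rotation about the long (polar) axis
        e = math.sqrt(1.0 - (b / a) ** 2)
        return 2.0 * math.pi * b**2 * (1.0 + (a / (b * e)) * math.asin(e))
    # oblate: polar axis shorter than equator
    e = math.sqrt(1.0 - (a / b) ** 2)
    return 2.0 * math.pi * b**2 * (1.0 + ((1.0 - e**2) / e) * math.atanh(e))


def curvature_corrected_disc_area(geom: DiscGeometry) -> float:
    """Area (mm^2) of skin removed by a punch, as a spherical cap.

    A punch of radius r on a fruit of local radius R removes a cap of area
    2*pi*R*(R - sqrt(R^2 - r^2)), slightly larger than the flat cross
    section pi*r^2.  With no fruit radius the flat area is returned.
    """
    r = geom.punch_diameter_mm / 2.0
    if geom.fruit_radius_mm is None:
        return math.pi * r**2
    R = geom.fruit_radius_mm
    # h = R - sqrt(R^2 - r^2) cancels catastrophically for R >> r;
    # the conjugate form is exact and stable in the flat limit
    h = r**2 / (R + math.sqrt((R - r) * (R + r)))
    return 2.0 * math.pi * R * h


def equivalent_sphere_radius_mm(fruit_area_cm2: float) -> float:
    """Radius (mm) of the sphere with the given surface area (cm^2).

    Default local radius of curvature for disc correction when no
    region-specific curvature is available.
    """
    if fruit_area_cm2 <= 0:
        raise ValueError("fruit_area_cm2 must be > 0")
    return math.sqrt(fruit_area_cm2 * MM2_PER_CM2 / (4.0 * math.pi))
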