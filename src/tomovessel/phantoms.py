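"""Analytic ellipse-based phantoms and rasterization.

A phantom is an ordered list of ellipses, each contributing an additive
intensity ``rho`` wherever it contains a point.  Overlapping ellipses add,
so the analytic value at ``(x, y)`` is the sum of ``rho`` over all ellipses
containing the point.  All coordinates are physical, with the image
half-width equal to 1: the reconstruction grid spans ``[-1, 1]^2`` and is
centered at the origin, x rightward, y upward.

Two phantom families are provided: the classic ten-ellipse Shepp-Logan
head phantom, the field's standard reconstruction benchmark, and a
configurable coronary-vessel cross-section with a bright lumen, a
percent-diameter stenosis, and optional calcified (hyperintense) or
noncalcified (hypointense relative to the lumen) wall plaques.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Ellipse",
    "Phantom",
    "ImageGrid",
    "VesselGroundTruth",
    "VesselLevels",
    "make_shepp_logan",
    "make_vessel_phantom",
    "rasterize",
]


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: center, semi-axes, rotation and intensity.

    ``phi_rot`` is the counterclockwise rotation of the ``a`` semi-axis
    away from the x-axis, in radians.  ``rho`` is the additive intensity
    (dimensionless attenuation); negative values carve intensity out of
    whatever lies underneath, which is how the Shepp-Logan interior and
    the vessel stenosis are built.
    """

    cx: float
    cy: float
    a: float
    b: float
    phi_rot: float = 0.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"semi-axes must be positive, got a={self.a}, b={self.b}")

    def contains(self, x, y):
        """Boolean mask of points inside (or on) the ellipse. Vectorized."""
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        c, s = math.cos(self.phi_rot), math.sin(self.phi_rot)
        u = (dx * c + dy * s) / self.a
        v = (-dx * s + dy * c) / self.b
        return u * u + v * v <= 1.0

    def rotated(self, angle: float) -> "Ellipse":
        """Ellipse rotated counterclockwise by ``angle`` about the origin."""
        c, s = math.cos(angle), math.sin(angle)
        return Ellipse(
            cx=self.cx * c - self.cy * s,
            cy=self.cx * s + self.cy * c,
            a=self.a,
            b=self.b,
            phi_rot=self.phi_rot + angle,
            rho=self.rho,
        )


@dataclass(frozen=True)
class Phantom:
    """An ordered collection of additive ellipses with a label."""

    ellipses: tuple[Ellipse, ...]
    name: str = "phantom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipses", tuple(self.ellipses))

    def value(self, x, y):
        """Analytic phantom value at physical points ``(x, y)``; vectorized."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for e in self.ellipses:
            out += np.where(e.contains(x, y), e.rho, 0.0)
        return out if out.ndim else float(out)

    def rotated(self, angle: float) -> "Phantom":
        return Phantom(tuple(e.rotated(angle) for e in self.ellipses), name=self.name)

    def __add__(self, other: "Phantom") -> "Phantom":
        return Phantom(self.ellipses + other.ellipses, name=f"{self.name}+{other.name}")


@dataclass
class ImageGrid:
    """N x N raster on the centered ``[-1, 1]^2`` grid.

    ``values[j, i]`` is the intensity at pixel center
    ``x_i = (i - (N-1)/2) * spacing``, ``y_j = (j - (N-1)/2) * spacing``
    (row index = y, column index = x, both increasing).  ``spacing = 2/N``
    so the raster spans the unit square exactly for any N, and the grid
    center is exactly (0, 0), which keeps symmetry tests exact.
    """

    values: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"image must be square 2-D, got shape {self.values.shape}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def x(self) -> np.ndarray:
        """Pixel-center x coordinates (length N)."""
        n = self.n
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing

    @property
    def y(self) -> np.ndarray:
        """Pixel-center y coordinates (length N)."""
        return self.x.copy()

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays shaped like ``values``."""
        return np.meshgrid(self.x, self.y)

    def circle_mask(self, radius: float = 1.0) -> np.ndarray:
        xx, yy = self.meshgrid()
        return xx * xx + yy * yy <= radius * radius

    @classmethod
    def zeros(cls, n: int) -> "ImageGrid":
        return cls(np.zeros((n, n)), spacing=2.0 / n)

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.values.copy(), self.spacing)


@dataclass(frozen=True)
class VesselLevels:
    """Absolute intensity plateaus of the vessel phantom.

    The scale is arbitrary attenuation; only the ordering matters for the
    measurement operators: background < wall < noncalcified plaque < lumen
    < calcified plaque, mirroring the hypo/hyperintense appearance of the
    two plaque types relative to a contrast-filled lumen.
    """

    background: float = 0.2
    wall: float = 0.35
    lumen: float = 1.0
    noncalcified: float = 0.6
    calcified: float = 1.6


@dataclass(frozen=True)
class VesselGroundTruth:
    """Generator-side truth for one synthetic vessel cross-section."""

    lumen_reference_diameter: float
    lumen_minimal_diameter: float
    stenosis_pct: float
    plaque_calcified: bool = False
    plaque_noncalcified: bool = False
    levels: VesselLevels = field(default_factory=VesselLevels)

    def __post_init__(self) -> None:
        if not (0.0 <= self.stenosis_pct <= 100.0):
            raise ValueError("stenosis_pct must lie in [0, 100]")


# Classic Shepp-Logan parameter table: (a, b, cx, cy, phi_deg, rho).
# The "modified" column swaps in the high-contrast intensities commonly
# used for display.
_SHEPP_LOGAN = [
    # a       b       cx      cy      phi   rho     rho_mod
    (0.69,   0.92,   0.0,    0.0,     0.0,  2.0,    1.0),
    (0.6624, 0.8740, 0.0,   -0.0184,  0.0, -0.98,  -0.8),
    (0.11,   0.31,   0.22,   0.0,   -18.0, -0.02,  -0.2),
    (0.16,   0.41,  -0.22,   0.0,    18.0, -0.02,  -0.2),
    (0.21,   0.25,   0.0,    0.35,    0.0,  0.01,   0.1),
    (0.046,  0.046,  0.0,    0.1,     0.0,  0.01,   0.1),
    (0.046,  0.046,  0.0,   -0.1,     0.0,  0.01,   0.1),
    (0.046,  0.023, -0.08,  -0.605,   0.0,  0.01,   0.1),
    (0.023,  0.023,  0.0,   -0.606,   0.0,  0.01,   0.1),
    (0.023,  0.046,  0.06,  -0.605,   0.0,  0.01,   0.1),
]


def make_shepp_logan(modified: bool = False) -> Phantom:
    """The canonical ten-ellipse Shepp-Logan head phantom.

    Parameters
    ----------
    modified:
        If True, use the high-contrast ("modified") intensity column
        instead of the classic near-unity attenuation values.  Geometry is
        identical; only ``rho`` changes.
    """
    ells = tuple(
        Ellipse(cx=cx, cy=cy, a=a, b=b, phi_rot=math.radians(phi),
                rho=(rho_mod if modified else rho))
        for a, b, cx, cy, phi, rho, rho_mod in _SHEPP_LOGAN
    )
    return Phantom(ells, name="shepp-logan" + ("-modified" if modified else ""))


def make_vessel_phantom(
    reference_diameter: float = 0.3,
    stenosis_pct: float = 0.0,
    plaque: str | Sequence[str] | None = None,
    levels: VesselLevels | None = None,
    wall_thickness: float = 0.07,
    vessel_halflength: float = 0.85,
    stenosis_halflength: float = 0.12,
    background_radius: float = 0.95,
) -> tuple[Phantom, VesselGroundTruth]:
    """Synthetic longitudinal coronary-vessel section with optional stenosis
    and plaque.

    The vessel runs horizontally through the image center: a bright lumen
    tube of diameter ``reference_diameter`` inside a darker wall, over a
    uniform soft-tissue background disc.  A stenosis is modeled by a pair
    of symmetric wall indentations at x = 0 whose radial depth narrows the
    lumen to ``reference_diameter * (1 - stenosis_pct/100)``.  A calcified
    plaque is a hyperintense ellipse embedded in the wall just above the
    narrowed lumen; a noncalcified plaque is a hypointense (relative to
    lumen) ellipse just below it.  Plaques are separated from the lumen
    boundary by a thin rim of wall so that the lumen edge stays a clean
    half-maximum crossing.

    Returns the phantom together with the generator-side ground truth
    (the synthetic stand-in for an angiographic gold standard).
    """
    if not (0.0 <= stenosis_pct < 100.0):
        raise ValueError("stenosis_pct must lie in [0, 100)")
    if not (0.0 < reference_diameter < 1.0):
        raise ValueError("reference_diameter must lie in (0, 1)")
    lv = levels or VesselLevels()

    if plaque is None:
        plaque_kinds: tuple[str, ...] = ()
    elif isinstance(plaque, str):
        plaque_kinds = (plaque,)
    else:
        plaque_kinds = tuple(plaque)
    for kind in plaque_kinds:
        if kind not in ("calcified", "noncalcified"):
            raise ValueError(f"unknown plaque kind {kind!r}")

    r_ref = reference_diameter / 2.0
    depth = r_ref * stenosis_pct / 100.0          # radial indentation depth
    r_min = r_ref - depth
    minimal_diameter = 2.0 * r_min

    ells: list[Ellipse] = [
        Ellipse(0.0, 0.0, background_radius, background_radius,
                rho=lv.background),
        Ellipse(0.0, 0.0, vessel_halflength, r_ref + wall_thickness,
                rho=lv.wall - lv.background),
        Ellipse(0.0, 0.0, vessel_halflength, r_ref,
                rho=lv.lumen - lv.wall),
    ]
    if depth > 0.0:
        # Symmetric indentations tucked fully inside the lumen with their
        # outer edge on the lumen boundary, so they restore the wall level
        # over [r_min, r_ref] at the throat without touching the wall band.
        for sign in (+1.0, -1.0):
            ells.append(Ellipse(0.0, sign * (r_ref - depth / 2.0),
                                stenosis_halflength, depth / 2.0,
                                rho=lv.wall - lv.lumen))

    # Plaques: small ellipses riding in the wall outside the (possibly
    # narrowed) lumen.  A thin rim of wall separates plaque from lumen so
    # the lumen edge stays a clean half-maximum crossing, and the plaque
    # stays within wall-level material so its plateau is not diluted.
    rim = 0.025
    b_plaque = max(0.02, 0.5 * depth)
    a_plaque = 0.6 * stenosis_halflength
    plaque_level = {"calcified": lv.calcified, "noncalcified": lv.noncalcified}
    side = {"calcified": +1.0, "noncalcified": -1.0}
    for kind in plaque_kinds:
        cy = side[kind] * (r_min + rim + b_plaque)
        top = abs(cy) + b_plaque
        if top > background_radius:
            raise ValueError("plaque ellipse would exceed the background disc")
        # Underneath the plaque the phantom shows the wall level both
        # inside the original lumen (where an indentation restored the wall
        # level) and outside it, so one additive offset suffices.
        ells.append(Ellipse(0.0, cy, a_plaque, b_plaque,
                            rho=plaque_level[kind] - lv.wall))

    if r_ref + wall_thickness > background_radius:
        raise ValueError("vessel does not fit inside the background disc")

    truth = VesselGroundTruth(
        lumen_reference_diameter=reference_diameter,
        lumen_minimal_diameter=minimal_diameter,
        stenosis_pct=100.0 * (1.0 - minimal_diameter / reference_diameter),
        plaque_calcified="calcified" in plaque_kinds,
        plaque_noncalcified="noncalcified" in plaque_kinds,
        levels=lv,
    )
    return Phantom(tuple(ells), name="vessel"), truth


def rasterize(phantom: Phantom, n: int, supersample: int = 1) -> ImageGrid:
    """Rasterize a phantom onto the centered N x N grid spanning [-1, 1]^2.

    By default each pixel takes the analytic value at its center (point
    sampling; exact additivity, bit-for-bit reproducible).  With
    ``supersample = s > 1`` each pixel averages an s x s grid of
    subsamples, which renders edges with graded intensities — useful when
    a raster feeds sub-pixel measurements.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    grid = ImageGrid.zeros(n)
    if supersample == 1:
        xx, yy = grid.meshgrid()
        grid.values[:] = phantom.value(xx, yy)
        return grid
    s = supersample
    offs = (np.arange(s) - (s - 1) / 2.0) * (grid.spacing / s)
    acc = np.zeros((n, n))
    for oy in offs:
        for ox in offs:
            xx, yy = grid.meshgrid()
            acc += phantom.value(xx + ox, yy + oy)
    grid.values[:] = acc / (s * s)
    return grid
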