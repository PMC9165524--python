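"""Parallel-beam forward models: analytic and discrete projection.

A parallel-beam acquisition is a set of line integrals p(t, theta) over
ray offset t and angle theta.  Angles step by a fixed increment Delta over
a half turn (theta_m = m * Delta, m = 0..M-1); detector bins step by a
fixed spacing d and are centered like the image grid
(t_n = (n - (K-1)/2) * d).  The sinogram stores one row per angle.

Two forward models are provided.  ``analytic_project`` evaluates the exact
Radon transform of an ellipse phantom via the closed-form chord-length
expression, so reconstruction error can be measured against a
discretization-free reference.  ``discrete_project`` is a pixel-driven
projector built as the exact transpose of the back-projector's linear
interpolation footprint; that matched adjoint pair is what makes the
iterative (SIRT) reconstructor provably convergent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .phantoms import ImageGrid, Phantom

__all__ = [
    "Geometry",
    "Sinogram",
    "ray_coordinate",
    "analytic_project",
    "discrete_project",
    "add_noise",
]


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam scan geometry.

    M angles with increment Delta (radians) covering at most a half turn;
    K detector bins with spacing d, centered on the rotation axis.
    """

    M: int
    Delta: float
    K: int
    d: float

    def __post_init__(self) -> None:
        if self.M < 1 or self.K < 2:
            raise ValueError("need M >= 1 angles and K >= 2 detector bins")
        if self.Delta <= 0 or self.d <= 0:
            raise ValueError("Delta and d must be positive")
        if self.M * self.Delta > math.pi + 1e-9:
            raise ValueError("M * Delta must not exceed pi (half-turn coverage)")
        if self.d * self.K < 2.0 * math.sqrt(2.0):
            warnings.warn(
                "detector span d*K = %.3f < 2*sqrt(2); sinogram of the unit "
                "square will be truncated" % (self.d * self.K),
                stacklevel=2,
            )

    @property
    def angles(self) -> np.ndarray:
        """theta_m = m * Delta for m = 0..M-1."""
        return np.arange(self.M) * self.Delta

    @property
    def t(self) -> np.ndarray:
        """Detector bin coordinates t_n = (n - (K-1)/2) * d."""
        return (np.arange(self.K) - (self.K - 1) / 2.0) * self.d

    @classmethod
    def for_grid(cls, n: int, m_angles: int = 180) -> "Geometry":
        """Geometry matched to an N-pixel [-1, 1]^2 grid.

        Detector spacing equals the pixel spacing 2/N; the bin count is
        odd (a bin center at t = 0) and spans the grid diagonal.
        """
        d = 2.0 / n
        k = int(math.ceil(2.0 * math.sqrt(2.0) / d)) + 3
        if k % 2 == 0:
            k += 1
        return cls(M=m_angles, Delta=math.pi / m_angles, K=k, d=d)


@dataclass
class Sinogram:
    """M x K projection data with its acquisition geometry."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.M, self.geometry.K):
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"(M={self.geometry.M}, K={self.geometry.K})"
            )

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)


def ray_coordinate(x, y, theta):
    """Ray offset of the ray through (x, y) at angle theta:
    t = x cos(theta) + y sin(theta).  Vectorized in all arguments."""
    return np.asarray(x) * np.cos(theta) + np.asarray(y) * np.sin(theta)


def analytic_project(phantom: Phantom, geometry: Geometry) -> Sinogram:
    """Exact Radon transform of an ellipse phantom.

    For one ellipse with semi-axes (a, b) rotated by phi, the line integral
    along the ray (t, theta) is the chord length scaled by rho:

        s^2(theta') = a^2 cos^2(theta') + b^2 sin^2(theta'),  theta' = theta - phi
        p(t', theta) = 2 rho a b sqrt(s^2 - t'^2) / s^2   for t'^2 < s^2

    with t' the offset re-centered on the ellipse.  Contributions add over
    ellipses.
    """
    theta = geometry.angles[:, None]          # (M, 1)
    t = geometry.t[None, :]                   # (1, K)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    out = np.zeros((geometry.M, geometry.K))
    for e in phantom.ellipses:
        tp = t - (e.cx * cos_t + e.cy * sin_t)
        th = theta - e.phi_rot
        s2 = (e.a * np.cos(th)) ** 2 + (e.b * np.sin(th)) ** 2
        under = s2 - tp * tp
        chord = np.where(under > 0.0, 2.0 * e.a * e.b * np.sqrt(np.maximum(under, 0.0)) / s2, 0.0)
        out += e.rho * chord
    return Sinogram(out, geometry)


def _interp_indices(image: ImageGrid, geometry: Geometry, m: int):
    """Shared pixel-to-detector mapping for the matched projector pair.

    Returns (n0, delta, valid) for every pixel at angle index m, with n0
    clipped to [0, K-2] so n0 + 1 is always addressable; ``valid`` is False
    for rays falling outside the detector.
    """
    theta = m * geometry.Delta
    xx, yy = image.meshgrid()
    t = xx * math.cos(theta) + yy * math.sin(theta)
    idx = t / geometry.d + (geometry.K - 1) / 2.0
    valid = (idx >= 0.0) & (idx <= geometry.K - 1)
    n0 = np.clip(np.floor(idx).astype(np.int64), 0, geometry.K - 2)
    delta = idx - n0
    return n0, delta, valid


def discrete_project(image: ImageGrid, geometry: Geometry) -> Sinogram:
    """Pixel-driven discrete projection (the transpose of back-projection).

    Each pixel scatters its value onto the two detector bins bracketing
    its ray offset with linear-interpolation weights.  By construction
    <A f, p> = M <f, B p> where A is this operator and B the averaged
    back-projector, which is the adjoint relation the SIRT reconstructor
    relies on.
    """
    out = np.zeros((geometry.M, geometry.K))
    vals = image.values
    for m in range(geometry.M):
        n0, delta, valid = _interp_indices(image, geometry, m)
        w = np.where(valid, vals, 0.0).ravel()
        n0f = n0.ravel()
        df = delta.ravel()
        row = np.bincount(n0f, weights=w * (1.0 - df), minlength=geometry.K)
        row += np.bincount(n0f + 1, weights=w * df, minlength=geometry.K)
        out[m] = row
    return Sinogram(out, geometry)


def add_noise(sinogram: Sinogram, sigma: float, seed: int | None = None) -> Sinogram:
    """Additive i.i.d. zero-mean Gaussian noise on every line integral.

    ``sigma = 0`` returns an identical copy; a fixed seed gives an
    identical noisy sinogram on every call.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return sinogram.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=sinogram.values.shape)
    return Sinogram(sinogram.values + noise, sinogram.geometry)
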