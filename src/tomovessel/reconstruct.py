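"""Image reconstruction from parallel-beam sinograms.

The core operator is back-projection with linear interpolation: the value
of a pixel is the average over angles of the projection value of the ray
through that pixel,

    f(i, j) = (1/M) * sum_m  p~( t_m(i, j), m Delta ),
    t_m(i, j) = x_i cos(theta_m) + y_j sin(theta_m),

where p~ linearly interpolates each projection row between the two
detector bins bracketing t_m (t_m = (n0 + delta) d, value
(1 - delta) p[n0] + delta p[n0 + 1]).  Rays falling outside the detector
contribute zero.

Filtered back-projection (FBP) applies a ramp-type filter to each row
first and rescales the angular average by M * Delta (= pi for a full
half-turn) so amplitudes match the continuous inverse Radon transform.
Two comparison reconstructors are provided: a direct Fourier method using
the central-slice theorem (1-D spectra of the projections resampled onto a
Cartesian 2-D frequency grid, then inverse 2-D DFT) and SIRT, a
simultaneous iterative solver for the discrete projection linear system
built on the matched projector/back-projector adjoint pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .filters import FilterKernel, build_filter, filter_sinogram
from .phantoms import ImageGrid
from .projection import Geometry, Sinogram, discrete_project

__all__ = [
    "InterpolationState",
    "split_ray",
    "interp_projection",
    "back_project",
    "fbp_reconstruct",
    "fourier_reconstruct",
    "sirt_reconstruct",
]


@dataclass(frozen=True)
class InterpolationState:
    """Decomposition t = (n0 + delta) d of a ray offset into a lower
    detector bin and a fractional offset, plus an out-of-range flag."""

    n0: int
    delta: float
    in_range: bool


def split_ray(t: float, d: float, K: int) -> InterpolationState:
    """Split a ray offset into bin index and fractional offset.

    The detector is centered: bin n sits at t_n = (n - (K-1)/2) d.  Returns
    n0 in [0, K-2] and delta in [0, 1] with (n0 + delta) matching t in
    index coordinates; offsets outside [t_0, t_{K-1}] are flagged
    out-of-range (their interpolated value is defined as zero).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    idx = t / d + (K - 1) / 2.0
    in_range = 0.0 <= idx <= K - 1
    n0 = int(np.clip(math.floor(idx), 0, K - 2))
    return InterpolationState(n0=n0, delta=idx - n0, in_range=in_range)


def interp_projection(row: np.ndarray, state: InterpolationState) -> float:
    """Linearly interpolated projection value for one ray.

    (1 - delta) row[n0] + delta row[n0 + 1]; zero when the ray is outside
    the detector.
    """
    if not state.in_range:
        return 0.0
    return (1.0 - state.delta) * row[state.n0] + state.delta * row[state.n0 + 1]


def _default_n(geometry: Geometry) -> int:
    return max(2, int(round(2.0 / geometry.d)))


def back_project(sinogram: Sinogram, n_pixels: int | None = None) -> ImageGrid:
    """Average the projection values of all rays through each pixel.

    Plain (unfiltered) back-projection with the 1/M angular average; no
    reconstruction-circle masking, so the operator is exactly the linear
    map whose transpose is ``discrete_project``.
    """
    geom = sinogram.geometry
    n = n_pixels or _default_n(geom)
    img = ImageGrid.zeros(n)
    xx, yy = img.meshgrid()
    acc = np.zeros((n, n))
    half = (geom.K - 1) / 2.0
    for m in range(geom.M):
        theta = m * geom.Delta
        t = xx * math.cos(theta) + yy * math.sin(theta)
        idx = t / geom.d + half
        valid = (idx >= 0.0) & (idx <= geom.K - 1)
        n0 = np.clip(np.floor(idx).astype(np.int64), 0, geom.K - 2)
        delta = idx - n0
        row = sinogram.values[m]
        val = (1.0 - delta) * row[n0] + delta * row[n0 + 1]
        acc += np.where(valid, val, 0.0)
    img.values[:] = acc / geom.M
    return img


def fbp_reconstruct(
    sinogram: Sinogram,
    kind: str = "ram-lak",
    n_pixels: int | None = None,
    kernel: FilterKernel | None = None,
    mask_circle: bool = True,
) -> ImageGrid:
    """Filtered back-projection: filter each row, back-project, rescale.

    The angular Riemann weight M * Delta (pi for half-turn coverage)
    replaces the plain 1/M average so that amplitudes match the continuous
    inverse Radon transform.  Pixels outside the inscribed unit circle are
    zeroed by default (detector coverage there is incomplete).
    """
    geom = sinogram.geometry
    if kernel is None:
        kernel = build_filter(kind, geom.K, geom.d)
    filtered = filter_sinogram(sinogram, kernel)
    img = back_project(filtered, n_pixels=n_pixels)
    img.values *= geom.M * geom.Delta
    if mask_circle:
        img.values[~img.circle_mask()] = 0.0
    return img


def fourier_reconstruct(
    sinogram: Sinogram,
    n_pixels: int | None = None,
    pad_factor: int = 4,
    mask_circle: bool = True,
) -> ImageGrid:
    """Direct Fourier reconstruction via the central-slice theorem.

    The 1-D DFT of the projection at angle theta equals the radial slice at
    angle theta of the object's 2-D Fourier transform.  Each row's spectrum
    (zero-padded by ``pad_factor`` to densify the radial frequency
    sampling) is placed on its radial line; the Cartesian 2-D frequency
    grid of the output image is then filled by bilinear interpolation in
    (angle, signed radial frequency), using the conjugate/reflection
    symmetry P_{theta+pi}(nu) = P_theta(-nu) to cover the full plane from
    half-turn data.  A final inverse 2-D DFT with the centered-grid phase
    gives the image.
    """
    geom = sinogram.geometry
    if geom.M < 2:
        raise ValueError("fourier_reconstruct needs M >= 2 angles")
    n = n_pixels or _default_n(geom)
    spacing = 2.0 / n

    k_pad = 1
    while k_pad < pad_factor * geom.K:
        k_pad <<= 1
    # P[m, k] = d * sum_n p[m, n] exp(-2 pi i nu_k t_n), t_n centered.
    nu = np.fft.fftfreq(k_pad, geom.d)
    phase = np.exp(2j * np.pi * nu * ((geom.K - 1) / 2.0) * geom.d)
    spectra = geom.d * np.fft.fft(sinogram.values, n=k_pad, axis=1) * phase
    # Sorted radial axis from -nu_max to +nu_max.
    order = np.argsort(nu)
    nu_sorted = nu[order]
    spectra = spectra[:, order]
    dnu = nu_sorted[1] - nu_sorted[0]

    # Wrap row for angle index M (theta = M Delta): if coverage is a full
    # half turn this is theta = pi, i.e. the theta = 0 row radially
    # flipped; with partial coverage it still provides the bracketing row
    # for interpolation at angles just below M Delta.
    wrap = spectra[0, ::-1][None, :]
    spectra = np.vstack([spectra, wrap])

    # Cartesian frequency grid of the output image (unshifted DFT order).
    freqs = np.fft.fftfreq(n, spacing)
    u, v = np.meshgrid(freqs, freqs)
    r = np.hypot(u, v)
    phi = np.arctan2(v, u)
    neg = phi < 0.0
    phi = np.where(neg, phi + np.pi, phi)
    r = np.where(neg, -r, r)
    at_pi = phi >= np.pi - 1e-12
    phi = np.where(at_pi, 0.0, phi)
    r = np.where(at_pi, -r, r)

    a_idx = phi / geom.Delta
    r_idx = (r - nu_sorted[0]) / dnu
    a0 = np.clip(np.floor(a_idx).astype(np.int64), 0, geom.M - 1)
    fa = a_idx - a0
    inside = (r_idx >= 0.0) & (r_idx <= k_pad - 1)
    r0 = np.clip(np.floor(r_idx).astype(np.int64), 0, k_pad - 2)
    fr = r_idx - r0

    def gather(ai, ri):
        return spectra[ai, ri]

    f2d = (
        (1 - fa) * (1 - fr) * gather(a0, r0)
        + (1 - fa) * fr * gather(a0, r0 + 1)
        + fa * (1 - fr) * gather(a0 + 1, r0)
        + fa * fr * gather(a0 + 1, r0 + 1)
    )
    f2d = np.where(inside, f2d, 0.0)

    # f(x_i, y_j) = sum F(u, v) e^{2 pi i (u x + v y)} du dv with centered
    # pixel coordinates x_i = (i - (n-1)/2) spacing: fold the half-grid
    # shift into a phase ramp and use the inverse FFT.
    shift = np.exp(-2j * np.pi * np.fft.fftfreq(n) * ((n - 1) / 2.0))
    f2d = f2d * shift[None, :] * shift[:, None]
    img_vals = np.fft.ifft2(f2d) / spacing**2
    img = ImageGrid(np.real(img_vals), spacing)
    if mask_circle:
        img.values[~img.circle_mask()] = 0.0
    return img


def sirt_reconstruct(
    sinogram: Sinogram,
    n_iters: int = 50,
    relax: float = 1.0,
    n_pixels: int | None = None,
    return_residuals: bool = False,
):
    """Simultaneous iterative reconstruction (SIRT).

    Solves the discrete projection system A f = p by relaxed, weighted
    updates

        f <- f + relax * C At R (p - A f)

    with A = ``discrete_project``, At = M * ``back_project`` (the exact
    transpose), R the inverse row sums and C the inverse column sums of A.
    With 0 < relax <= 2 this iteration is convergent and the data residual
    ||A f - p|| is nonincreasing on consistent data.  f starts from zeros;
    pixels outside the inscribed unit circle are frozen at zero by zeroing
    their column weight.
    """
    if n_iters < 0:
        raise ValueError("n_iters must be >= 0")
    if not (0.0 < relax <= 2.0):
        raise ValueError("relax must lie in (0, 2]")
    geom = sinogram.geometry
    n = n_pixels or _default_n(geom)

    ones_img = ImageGrid(np.ones((n, n)), 2.0 / n)
    row_sums = discrete_project(ones_img, geom).values
    r_w = np.zeros_like(row_sums)
    np.divide(1.0, row_sums, out=r_w, where=row_sums > 1e-12)

    ones_sino = Sinogram(np.ones((geom.M, geom.K)), geom)
    col_sums = geom.M * back_project(ones_sino, n_pixels=n).values
    c_w = np.zeros_like(col_sums)
    np.divide(1.0, col_sums, out=c_w, where=col_sums > 1e-12)
    c_w[~ones_img.circle_mask()] = 0.0

    f = ImageGrid.zeros(n)
    residuals = []
    for _ in range(n_iters):
        proj = discrete_project(f, geom)
        resid = sinogram.values - proj.values
        residuals.append(float(np.linalg.norm(resid)))
        update = geom.M * back_project(Sinogram(resid * r_w, geom), n_pixels=n).values
        f.values += relax * c_w * update
    final = discrete_project(f, geom)
    residuals.append(float(np.linalg.norm(sinogram.values - final.values)))
    if return_residuals:
        return f, residuals
    return f
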