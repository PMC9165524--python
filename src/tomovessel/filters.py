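"""Reconstruction filters for filtered back-projection.

The ramp (Ram-Lak) filter is the |nu| frequency weighting that inverts the
Radon transform; it is sharp but amplifies high-frequency measurement
noise.  The Shepp-Logan filter softens the ramp by convolving its spatial
kernel with sin(x)/x — equivalently, by the convolution theorem,
multiplying the ramp by a sinc window in the frequency domain:

    H_SL(nu) = |nu| * sinc(nu / (2 nu_N)),   nu_N = 1/(2 d)

with sinc(x) = sin(pi x)/(pi x) and d the detector spacing.  Both filters
remove the DC component.  Filtering is applied row-by-row in the DFT
domain after zero-padding each projection to the next power of two >= 4K,
which suppresses circular-convolution wraparound within the cropped output
and samples the ramp densely enough at low frequencies to avoid the mean-
level bias of a coarsely sampled ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import Sinogram

__all__ = ["FilterKernel", "FILTER_KINDS", "build_filter", "filter_sinogram"]

FILTER_KINDS = ("none", "ram-lak", "shepp-logan")


@dataclass(frozen=True)
class FilterKernel:
    """Discrete reconstruction filter in frequency and spatial form.

    ``frequency_response`` holds H(nu_k) at the physical DFT frequencies
    nu_k = fftfreq(K_pad, d); ``spatial_kernel`` is its inverse DFT divided
    by d, i.e. samples h(n d) of the continuous band-limited kernel (for
    the ramp: h(0) = 1/(4 d^2), h(n odd) = -1/(pi^2 n^2 d^2), even taps 0).
    """

    kind: str
    K: int
    K_pad: int
    d: float
    frequency_response: np.ndarray
    spatial_kernel: np.ndarray


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p <<= 1
    return p


def build_filter(kind: str, K: int, d: float) -> FilterKernel:
    """Build a reconstruction filter for K-bin projections with spacing d.

    ``kind`` is one of ``none`` (all-ones response: plain back-projection),
    ``ram-lak`` (ideal band-limited ramp |nu|) or ``shepp-logan`` (ramp
    windowed by sinc(nu/(2 nu_N))).
    """
    if kind not in FILTER_KINDS:
        raise ValueError(f"unknown filter kind {kind!r}; expected one of {FILTER_KINDS}")
    if K < 2:
        raise ValueError("K must be >= 2")
    if d <= 0:
        raise ValueError("d must be positive")
    # >= 4K: 2K already suppresses circular-convolution wraparound, but the
    # frequency-sampled ramp underestimates the lowest frequencies (the
    # classic DC deficiency); denser frequency sampling keeps the
    # reconstructed mean level of extended objects within a fraction of a
    # percent while the response stays exactly |nu| with a zeroed DC bin.
    k_pad = _next_pow2(4 * K)
    nu = np.fft.fftfreq(k_pad, d)
    if kind == "none":
        resp = np.ones(k_pad)
    elif kind == "ram-lak":
        resp = np.abs(nu)
    else:  # shepp-logan; np.sinc is the normalized sinc, and nu/(2 nu_N) = nu*d
        resp = np.abs(nu) * np.sinc(nu * d)
    spatial = np.real(np.fft.ifft(resp)) / d
    return FilterKernel(kind=kind, K=K, K_pad=k_pad, d=d,
                        frequency_response=resp, spatial_kernel=spatial)


def filter_sinogram(sinogram: Sinogram, kernel: FilterKernel) -> Sinogram:
    """Convolve every projection row with the reconstruction filter.

    Rows are zero-padded to K_pad, multiplied by the frequency response,
    inverse-transformed and cropped back to K bins.  The Riemann weight d
    of the continuous convolution integral cancels against the 1/d carried
    by the sampled spatial kernel, so in the frequency domain the response
    is applied directly.  ``kind == "none"`` returns the input unchanged
    (up to round-off).
    """
    geom = sinogram.geometry
    if kernel.K != geom.K or kernel.d != geom.d:
        raise ValueError(
            f"filter built for K={kernel.K}, d={kernel.d} but sinogram has "
            f"K={geom.K}, d={geom.d}"
        )
    spec = np.fft.fft(sinogram.values, n=kernel.K_pad, axis=1)
    filtered = np.real(np.fft.ifft(spec * kernel.frequency_response, axis=1))[:, : geom.K]
    return Sinogram(filtered, geom)
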