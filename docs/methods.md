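# Methods

This note documents the models, discretizations and design choices behind
`tomovessel`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the known limits are.

## Geometry and conventions

Images live on an N×N raster spanning [−1, 1]² with pixel spacing
s = 2/N and centered pixel coordinates x_i = (i − (N−1)/2)·s (likewise in
y); the grid center is exactly the origin for every N, which makes
symmetry and adjointness tests exact rather than approximate. Arrays are
indexed `values[j, i]` with the row index along y.

Acquisition covers a half turn: θ_m = mΔ with MΔ ≤ π. The default is
M = 180, Δ = π/180 — the standard acquisition count for parallel-beam
data, and sufficient because p(t, θ+π) = p(−t, θ). The detector is
centered like the image grid, t_n = (n − (K−1)/2)·d; `Geometry.for_grid`
picks d equal to the pixel spacing and an odd K covering the grid diagonal
(d·K ≥ 2√2), so a central bin sits exactly at t = 0. Detectors that do
not cover the diagonal are allowed but warn: their sinograms are
truncated.

## Forward models

**Analytic projector.** The Radon transform of an ellipse has a closed
form: with effective half-width
r²(θ′) = a² cos²θ′ + b² sin²θ′ (θ′ the angle in the ellipse frame) the
line integral is 2ρab·√(r²−t′²)/r² for |t′| < r, zero otherwise, and
ellipse contributions add. This is exact — no discretization error — so
reconstruction error measured against it isolates the reconstruction
method itself. Verified in tests against dense numerical quadrature along
random rays (10⁵ samples, agreement to 1e−4).

**Discrete projector.** `discrete_project` is pixel-driven: every pixel
scatters its value onto the two detector bins bracketing its ray offset,
with the same linear-interpolation weights the back-projector uses to
gather. The pair therefore satisfies ⟨A f, p⟩ = M·⟨f, B p⟩ exactly (B is
the 1/M-averaged back-projector), which is what makes the SIRT iteration
provably convergent. A Siddon-type ray tracer would be more physical but
would break the exact adjoint property; since the discrete projector's
role here is to close the iterative loop, the matched pair wins. Note the
scaling: the pixel-driven sum approximates the line integral divided by d
(tested: `discrete_project(raster)·d → analytic_project` as N grows).

**Noise.** Additive i.i.d. zero-mean Gaussian noise on the line
integrals, seeded. Quantum (Poisson) transmission noise is deliberately
out of scope; Gaussian noise keeps the filter-comparison experiments
controlled and exactly reproducible. Noise levels elsewhere in the
package are expressed as a fraction of the maximum sinogram value.

## Back-projection and FBP

`back_project` implements the discrete accumulation literally: for each
angle, compute every pixel's ray offset t = x cos θ + y sin θ, split it as
t = (n₀ + δ)d, gather (1−δ)p[n₀] + δp[n₀+1] (zero when the ray leaves the
detector), accumulate over angles, divide by M. The vectorized
implementation is tested bit-for-bit against a literal triple loop.

FBP = back_project ∘ filter, rescaled by MΔ (= π at half-turn coverage),
which is the Riemann weight of the angular integral in the inverse Radon
transform; with it, amplitudes are quantitatively correct (a unit-density
disc reconstructs to 1.000 ± 0.02, tested). Pixels outside the inscribed
unit circle are zeroed — detector coverage there is incomplete — except in
plain `back_project`, which stays the pure linear operator.

**Filters.** Built in the frequency domain on physical DFT frequencies
ν_k = fftfreq(K_pad, d): Ram-Lak H(ν) = |ν|; Shepp-Logan
H(ν) = |ν|·sinc(ν d) (the spatial convolution of the ramp kernel with
sin(x)/x expressed through the convolution theorem; at Nyquist the gain is
2/π of the ramp's). The stored spatial kernel is ifft(H)/d, i.e. samples
of the continuous band-limited kernel — for the ramp, h(0) = 1/(4d²),
h(odd n) = −1/(π²n²d²), even taps 0, which the implementation matches to
~1e−6 relative. Rows are zero-padded to the next power of two ≥ 4K before
filtering: ≥ 2K is enough to avoid circular-convolution wraparound, but
the coarsely sampled ramp then underweights the lowest frequencies and
depresses the mean level of extended objects by ~3%; at ≥ 4K the DC level
of a constant background is recovered to better than 1% (tested at 2%).
The d Riemann weight of the convolution integral cancels against the 1/d
of the sampled kernel, so the frequency response is applied directly.

## Direct Fourier reconstruction

By the central-slice theorem the 1-D spectrum of a projection is a radial
line of the object's 2-D spectrum. The implementation zero-pads each row
4×, corrects the phase for the centered detector, sorts the radial
frequency axis, and fills the output image's Cartesian frequency grid by
bilinear interpolation in (angle index, signed radius), using
P_{θ+π}(ν) = P_θ(−ν) to cover the half-plane not acquired. A final
inverse 2-D FFT with the centered-grid phase ramp and 1/s² scaling yields
the image. Bilinear polar-to-Cartesian interpolation is the crudest
workable gridding; it leaves low-level swirl artifacts, which is why FBP
is the reference method — the cross-validation tests require only that
both correlate > 0.95 with the truth and that the Fourier method's RMSE
stays within 2× of FBP's on a disc.

The slice theorem itself is verified directly at N = 256: the 1-D
spectrum of the analytic θ = 0 projection matches the x-axis slice of the
raster's 2-D spectrum with relative L2 error ≈ 0.6% (point-sampling
aliasing accounts for most of it).

## SIRT

f ← f + λ·C·Aᵀ·R·(p − A f), with R = diag(1/row sums of A),
C = diag(1/column sums of A), Aᵀ = M·back_project, f₀ = 0, and relaxation
0 < λ ≤ 2. With these weights the iteration matrix is a contraction on
the data residual, so ‖A f − p‖ is nonincreasing — asserted per iteration
in tests. Pixels outside the unit circle get zero column weight (frozen).
One property worth knowing: with these weights a constant image is
recovered *exactly* after a single iteration (the textbook one-ray,
one-pixel example generalizes), which the tests use as an exactness probe.
Convergence speed is strongly frequency-dependent: smooth objects reach
< 0.1% residual in 50 iterations, hard-edged rasters only ~1.7% — the
convergence acceptance test therefore uses a smooth (Hann-bump) object,
and the cohort default gives SIRT 40 iterations.

## The vessel phantom and what it emulates

`make_vessel_phantom` builds a longitudinal section of a contrast-filled
vessel from ≤ 7 ellipses on a soft-tissue background disc: intensity
plateaus background 0.2, wall 0.35, lumen 1.0, noncalcified plaque 0.6,
calcified plaque 1.6 (arbitrary attenuation units; only the ordering
matters, mirroring hypo-/hyperintensity relative to the lumen on
contrast imaging). A stenosis of severity q% is a symmetric pair of wall
indentations at x = 0 whose depth narrows the lumen diameter to
reference·(1 − q/100) exactly; plaques are small ellipses embedded in
wall-level material just outside the narrowed lumen, separated from it by
a 0.025 rim so the lumen edge remains a clean half-maximum crossing.
Defaults: reference diameter 0.3 (image half-width = 1), wall thickness
0.07, stenotic segment half-length 0.12.

What it does **not** emulate: curved or branching vessels, eccentric
stenoses, calcium blooming, beam hardening, motion, Poisson statistics,
and 3-D partial-volume effects. Passing tests therefore demonstrate that
the reconstruction-measurement chain is self-consistent under the stated
noise model — not clinical performance.

## The vessel reader

Stenosis is measured on intensity profiles perpendicular to the vessel
axis (all columns with |x| ≤ 0.45): each profile's lumen width is the
half-maximum crossing width around the axis, with sub-pixel edges from
linear interpolation; the background level is the per-profile median far
from the vessel and the peak is seeded near the axis (so a bright
calcification cannot hijack the threshold). Because an ellipse-built
lumen tapers along its length, the reference diameter is the
interpolated-normal width of quantitative coronary angiography: a
quadratic taper model fit to width-vs-x, refit excluding a ±0.16 window
around the throat (located as the centroid of the width dip), evaluated at
the throat. The minimal diameter is the smallest width near the throat.
Images are presmoothed with a symmetric 3×5-pixel boxcar — symmetric
smoothing does not displace half-maximum crossings of a step edge but
suppresses the high-frequency noise that ramp filtering injects.
Accuracy on N = 256 ground-truth rasters: MAE ≈ 1.6 points over
10–90% severities (≈ 1.0 with anti-aliased rasters).

Plaque is read from a wall window just outside the lumen edge
(offsets 0.012–0.067) on both sides of every profile: a window whose 90th
percentile exceeds lumen + 0.35·contrast over ≥ 2 columns flags a
calcified plaque; windows mostly filled (≥ 50%) with intermediate
intensity over ≥ 7 columns flag a noncalcified plaque, after gating out
columns where the lumen edge changes steeply (the blurred shoulder of a
narrowing reads intermediate) and columns adjacent to detected
calcification (its blurred skirt does too). Thresholds are relative to
the image's own lumen/background contrast so the reader transfers across
reconstruction methods and amplitude scales; they were calibrated on
noiseless and 5%-noise synthetic reconstructions. On noiseless inputs the
reader is exact across the tested grid of severities and plaque types; at
5% noise specificity degrades before sensitivity, and at 10% noise the
measurement degrades substantially — reported per case, never hidden.

## The synthetic cohort

`run_cohort_experiment(config, seed)` draws case parameters (stenosis
present with probability 0.8, severity uniform on [10, 90]%, each plaque
type independently with probability 0.35), projects each phantom
analytically, adds seeded noise (default 5% of the sinogram maximum),
reconstructs with each configured method at N = 256, M = 180, reads
stenosis/grade/plaque, and aggregates per-method contingency tables (per
plaque type, and one-vs-rest per grade with the 50/70 cut-offs). The
generator's ground truth is the gold standard. Everything is a pure
function of (config, seed); failed reads are first-class records counted
as disagreements, so no denominator silently shrinks. Problem sizes
(20–40 cases, N = 256) were chosen so a full study runs in seconds while
keeping the reader's sub-pixel assumptions valid.

## Numerical details and edge cases

- Rasterization is pixel-center point sampling (bit-reproducible,
  exactly additive); `supersample=s` averages s² subsamples per pixel and
  is used where sub-pixel edge positions matter (cohort truth rasters use
  s = 2).
- Rays outside the detector contribute zero to back-projection and are
  flagged, not errors, in `split_ray`.
- `interp_projection` clamps n₀ to [0, K−2] so the right neighbor always
  exists; δ = 0 at the last bin.
- psnr of identical images is +inf by definition, never an error;
  contingency rates with zero denominators are `None`, never 0.
- File formats are flat little-endian float32 + JSON sidecars (bit-exact
  round trips, tested); PNG export is windowed 8-bit and lossy by design.

## Known limitations

- Parallel-beam only; no fan/cone geometry or rebinning.
- The Fourier reconstructor's bilinear gridding is adequate for
  cross-validation, not state of the art (no oversampled gridding kernel
  or density compensation).
- SIRT has no stopping rule beyond the iteration budget and no
  regularization; semi-convergence on noisy data is the user's problem.
- The vessel reader assumes a horizontal axis through the image center
  (by construction of the generator); it is a measurement operator for
  this phantom family, not a general vessel-tracking algorithm.
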