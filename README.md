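# tomovessel

Parallel-beam tomographic reconstruction with synthetic coronary-vessel
phantoms and a diagnostic-accuracy harness.

`tomovessel` is for people who want a small, fully self-contained testbed
for filtered back-projection and its competitors: algorithm courses,
method prototyping, and benchmark experiments where every input has an
analytic ground truth. It implements the classical reconstruction chain
from first principles — discretized back-projection with linear
interpolation, ramp-type reconstruction filters, a direct Fourier
(central-slice) reconstructor and an iterative SIRT solver — and wraps it
in a clinically flavored evaluation problem: reading percent-diameter
stenosis and wall plaque from reconstructed cross-sections of a synthetic
contrast-filled vessel.

## The model

A parallel-beam scan measures line integrals of a 2-D attenuation map
f(x, y):

    p(t, θ) = ∫ f(t cos θ − s sin θ, t sin θ + s cos θ) ds,

sampled at angles θ_m = mΔ (m = 0 … M−1, half-turn coverage) and detector
offsets t_n = (n − (K−1)/2) d. Back-projection averages, over angles, the
projection value of the ray through each pixel,

    f̂(i, j) = (1/M) Σ_m p̃( x_i cos θ_m + y_j sin θ_m , θ_m ),

where p̃ interpolates each row linearly between the two detector bins
bracketing the ray offset (t = (n₀ + δ) d ⇒ p̃ = (1−δ) p[n₀] + δ p[n₀+1]).
Filtered back-projection (FBP) convolves each projection with a ramp-type
filter first and rescales the average by MΔ (= π), which inverts the Radon
transform. Two filters are built in frequency space:

* **Ram-Lak** — the ideal band-limited ramp H(ν) = |ν| up to the detector
  Nyquist ν_N = 1/(2d); sharp, but it amplifies high-frequency noise.
* **Shepp-Logan** — the ramp convolved (in space) with sin(x)/x,
  equivalently H(ν) = |ν| · sinc(ν/(2ν_N)); trades a little resolution for
  noise suppression.

Two comparison reconstructors are included: a direct Fourier method that
places the 1-D spectra of the projections on radial lines of the 2-D
frequency plane (the central-slice theorem) and inverts with a 2-D FFT,
and SIRT, which solves the discrete projection system A f = p by relaxed,
row/column-weighted iterations using a projector/back-projector pair that
is an exact adjoint by construction.

The evaluation side quantifies **% diameter stenosis**,
100 · (1 − minimal/reference lumen diameter), from half-maximum width
profiles perpendicular to the vessel axis (with the interpolated-normal
reference of quantitative angiography), grades it with the conventional
50%/70% cut-offs (mild / moderate / severe), detects calcified
(hyperintense) and noncalcified (hypointense) wall plaque, and aggregates
a synthetic reading study into sensitivity / specificity / accuracy
against the generator's ground truth.

## Worked example

```bash
tomovessel demo --outdir demo --seed 1 --n-pixels 128 --m-angles 180
```

projects the Shepp-Logan head phantom to 180 analytic projections, adds 5%
Gaussian noise, reconstructs with every method and prints the error table
(also written to `demo/metrics.csv`, with PNG renderings alongside):

```
method,rmse,psnr
bp,0.691147027,9.22919103
fbp_ram_lak,0.313263256,16.1024107
fbp_shepp_logan,0.266583611,17.503931
fourier,0.492712687,12.168725
sirt,0.894070627,6.99316337
```

Reading the numbers: unfiltered back-projection (`bp`) is heavily blurred
(RMSE 0.69 against the rasterized truth inside the reconstruction circle);
ramp filtering cuts the error by half; the sinc-windowed ramp
(`fbp_shepp_logan`, RMSE 0.27) beats the pure ramp on noisy data exactly
as the filter theory predicts; the direct Fourier method lands between
them, and 30 SIRT iterations have not yet converged on data this noisy.

The same machinery is available as a library:

```python
from tomovessel import (make_vessel_phantom, rasterize, Geometry,
                        analytic_project, fbp_reconstruct, measure_stenosis)

phantom, truth = make_vessel_phantom(reference_diameter=0.3,
                                     stenosis_pct=62.0, plaque="calcified")
sino = analytic_project(phantom, Geometry.for_grid(256, 180))
image = fbp_reconstruct(sino, kind="shepp-logan", n_pixels=256)
print(measure_stenosis(image).stenosis_pct)   # ≈ 62
```

A full synthetic reading study (`tomovessel cohort --n-cases 40 ...` or
`run_cohort_experiment`) writes a per-case CSV and a JSON summary of
plaque sensitivity/specificity and per-grade accuracy.

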