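# arspect

Adaptive autoregressive (AR) denoising for SPECT, with everything needed
to evaluate it end-to-end on simulated data: a mathematical cylinder
phantom, an ideal parallel-beam projector with Poisson counting noise,
FBP and OSEM reconstruction, Butterworth reference filters, and the
image-quality metrics (CoV%, CR%, FWHM) used to compare denoising
strategies at matched noise.

## The problem

SPECT images are photon-starved: a typical projection image in this
study carries ~12 counts per pixel, and reconstruction amplifies that
noise. The classical remedies filter globally in the frequency domain
(e.g. a Butterworth low-pass before FBP or after OSEM), trading
resolution for noise uniformly across the image. The block-adaptive AR
filter instead adapts locally: each pixel is regressed on its
neighbourhood,

    x̂(n₁,n₂) = Σ_{(k₁,k₂)∈R} a(k₁,k₂) · x(n₁+k₁, n₂+k₂),

with the coefficients a(k₁,k₂) re-estimated by least squares in small
overlapping blocks (5×5, 75% overlap). The predictable image x̂ is a
data-adaptive low-pass component; the residual w = x − x̂ carries noise
plus edge detail. The full cascade re-filters the predictable image
once, sums the two residual images, recovers the structured part of
that sum with a second AR model (3×3 region, 6×6 blocks), and adds it
back — returning edge counts that a plain low-pass would discard. The
3D variant averages the cascade applied slice-wise along the three
orthogonal orientations. The filter has no tunable parameters.

The package implements the comparison protocol around it: AR filtering
before and after OSEM (AR-OSEM-AR) versus Butterworth-prefiltered FBP
(BW-FBP) and Butterworth-postfiltered OSEM (OSEM-BW), with the
Butterworth cutoffs tuned by bisection until all methods show the same
coefficient of variation in a uniform region of the phantom, so that
contrast (CR% = 100·|M−m|/M) and resolution (FWHM of line spread
functions) are compared at equal noise.

## Worked example

```python
from arspect import ar_cascade_denoise, make_test_slice, mse

truth, noisy = make_test_slice(size=64, structures=3, seed=7, total_counts=100_000)
denoised = ar_cascade_denoise(noisy)
print(mse(noisy, truth), mse(denoised, truth), denoised.sum())
```

prints (see `examples/01_ar_denoise_planar.py`):

```
MSE noisy  vs truth:    23.52
MSE output vs truth:    10.99
output counts:   99671   (input: 99678)
```

The cascade removes roughly half of the Poisson noise variance while
conserving total counts to within a fraction of a percent — the
behaviour that makes it usable as a projection-domain prefilter for
quantitative reconstruction. `examples/` contains one short script per
capability (phantom simulation, reconstruction, metrics, the full
noise-matched comparison), each printing the numbers it computes.

A thin CLI mirrors the library for shell use:

```bash
arspect simulate --counts 50000 --seed 1 proj.nii
arspect filter proj.nii filtered.nii
arspect reconstruct --algorithm OSEM filtered.nii vol.nii
arspect evaluate vol.nii --report metrics.csv
arspect experiment --seeds 1,2,3 --out results/
```

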