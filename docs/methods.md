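# Methods

## The AR model and the denoising cascade

A two-dimensional autoregressive model predicts each pixel from a small
symmetric neighbourhood (the *prediction region*): the four orthogonal
neighbours for the main filter, the full 3×3 ring for the error-branch
filter. Because count statistics vary strongly across an emission
image, one global model fits poorly; the filter is therefore
block-adaptive. The image is tiled with overlapping square blocks
(default 5×5 with stride 1, i.e. 75% overlap; 6×6 with stride 2 for the
error branch), and in each block the coefficients are estimated by
ordinary least squares:

* the block is mean-centred first (the model has no intercept and count
  images are far from zero-mean), and the mean is restored after
  prediction;
* the block is edge-replicated by the region radius so every block
  pixel has a complete neighbourhood and contributes one row to the
  normal equations;
* rank-deficient systems (constant blocks) get the minimum-norm
  solution via the pseudo-inverse of the Gram matrix, with an absolute
  centred-energy floor of 1e−30 below which the block is treated as
  constant (this guards against denormal-scale backgrounds that
  multiplicative EM reconstruction produces outside the object);
* each pixel's predicted value is the unweighted mean of the
  predictions of all blocks covering it.

The decomposition is exactly additive by construction: the error image
is defined as input minus blended prediction, so `predicted + error`
reproduces the input to the last bit.

The cascade (all defaults, no tunable parameters): decompose the input;
re-filter the predictable image once with the same model; sum the two
error images; filter the sum once with the 3×3/6×6 model; add its
predictable part back to the twice-filtered image. The error-recovery
step returns structured counts (mostly object edges) that leak into the
residuals, which is what distinguishes the cascade from a plain
low-pass. The 3D filter applies the cascade slice-by-slice along each
of the three orthogonal orientations and averages the three volumes;
averaging is our choice — the merge rule is otherwise unconstrained —
and the final activity estimate is clamped at zero (the regression can
undershoot by ~1e−6 of the signal scale; the clamped mass is logged).

## Phantom and simulation conditions

The digital phantom is a 200 mm (diameter and length) cylinder of
relative activity 1 containing three stacks of five coaxial cylinders
(diameters 4, 10, 20, 40, 60 mm, each 30 mm long, stacked end-to-end
and centred axially) with relative activities 0, 2 and 4. Stack axes
sit at 120° spacing on a 55 mm radius — placement is unpublished; this
choice keeps a 15 mm margin to the body wall and >65 mm between stack
edges, and is recorded in the spec so every ROI derives from geometry.
Rasterization assigns each voxel the activity of the innermost cylinder
containing its centre (no anti-aliasing — the phantom is mathematical).
The 4 mm cylinder is generated but excluded from metrics; it is below
the resolution of the simulated system.

Acquisition: 120 parallel-beam views over 360°, 64 detector bins of
4 mm, projection images 64×64 (the volume is rasterized with 64 axial
slices so the projection matrix matches; slices beyond the 200 mm body
are empty). The projector is voxel-driven: each voxel's centre maps to
a detector coordinate and its value is split linearly between the two
adjacent bins, so per-view totals are conserved exactly; the matrix
transpose is the exact adjoint. No attenuation, scatter or resolution
model. Each projection image is scaled to the study count level
(50 000 / 100 000 / 150 000 expected counts per view, giving mean pixel
counts of 12.2 / 24.4 / 36.6) and each pixel is replaced by a Poisson
draw from a seeded generator.

## Reconstruction

FBP: per-slice ramp filtering in the frequency domain using the exact
band-limited discrete ramp kernel (0.25 at lag zero, −1/(πn)² at odd
lags; zero-padded to the next power of two, at least 2×, against
circular wrap), interpolating back projection via the projector's
adjoint, and normalization by π/(2·n_angles), which is correct for both
180° and 360° arcs (a full turn measures each line twice and the
doubled sum absorbs the factor). FBP output is signed.

OSEM: multiplicative Poisson-EM updates over angle subsets (angle *i*
goes to subset *i* mod S; default 8 subsets × 10 iterations), uniform
positive initialization, 0/0 → 0 guards, matched projector/adjoint
pair. With one subset this is MLEM and the Poisson log-likelihood is
non-decreasing, which the tests check on noise-free data.

Butterworth: amplitude form 1/√(1+(f/f_c)^{2n}) — the convention of
clinical nuclear-medicine software — applied radially in 2D or 3D
frequency space, frequencies in cycles/cm (Nyquist 1.25 cycles/cm at
4 mm samples). Order 2 throughout. Cutoffs above Nyquist raise an
error; a clamp mode and an explicit allow mode (for the identity limit)
exist because the three behaviours serve different callers.

## The noise-matched comparison

AR-OSEM-AR runs first (it has no adjustable parameter): AR cascade on
each projection image, negatives clamped to zero before OSEM (the
Poisson model needs nonnegative data; the clamped mass is logged), OSEM
8×10, then the 3D AR filter. Its CoV% — 100·sd/mean in a 150 mm
circular ROI on uniform transaxial slices between the body end and the
stacks (8 mm margin from the volume edge, 4 mm from the stacks) —
becomes the target, and the BW-FBP and OSEM-BW cutoffs are found by
bisection (tolerance 0.05 CoV points; CoV% is monotone in the cutoff,
which the search verifies on its trace).

Per-cylinder metrics: CR% = 100·|M−m|/M, where m is the mean in a
circular ROI with the cylinder's own diameter over slices within 9 mm
of its axial centre and M is the uniform-ROI mean. The magnitude
convention makes hot objects report positive contrast (ideal values:
100 cold, 100 for ×2, 300 for ×4; partial volume only lowers them).
FWHM is measured on profiles through the cylinder centre, tangential to
the radius so both 80 mm tails sample uniform background, with
thickness 1/2/4/6 pixels for the 10/20/40/60 mm cylinders; the baseline
is the mean of the outermost 10% of samples per side (the background is
warm, so the half level must sit above it), cold wells are inverted,
and crossings are linearly interpolated.

## Problem sizes

The test suite runs the full-scale geometry (64×64×64 volume, 120
views) with five noise realizations at the low count level for the
stochastic checks, and a coarse 32×32 geometry with 40 views for the
experiment-driver contract tests. The acceptance script averages three
realizations. A complete single-seed, single-level three-method run
takes roughly half a minute on one core.

## Known limitations

* The uniform-region CoV% of our reconstructions (~17% for AR-OSEM-AR
  at the low count level; ~31% for BW-FBP at a 0.83 cycles/cm cutoff,
  and ~40% for an independent FBP implementation on the same sinograms)
  is several times the published phantom-study values. At 12 counts per
  projection pixel this noise level is what Poisson statistics dictate
  for a single-slice measurement; the published values evidently
  include additional, unpublished smoothing in the measurement chain
  (e.g. slab averaging or display interpolation in the clinical ROI
  software). Noise *matching between methods* — the fairness mechanism
  of the comparison — is unaffected, and contrast and resolution
  metrics, which are ratio- and width-based, reproduce the published
  values closely.
* CR% of large hot cylinders saturates ~3–4% below the ideal because
  the measurement ROI has the cylinder's own diameter: rim voxels are
  partial-volume suppressed even in the noise-free limit (the noise-free
  measurement gives 290 against an ideal 300 for the 60 mm ×4 cylinder).
* The synthetic planar test slice used for AR model selection is
  piecewise-constant with Poisson noise; it emulates count statistics
  and sharp anatomical boundaries but not continuous activity gradients
  or anatomical texture, so model-selection results on it show
  reproducibility of the protocol, not anatomy-specific rankings.
* No attenuation, scatter or collimator response anywhere — by design;
  conclusions transfer to ideal-geometry comparisons only.
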