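# Methods

This note records the models, conventions and numerical choices behind
`fodfsr`, and what the synthetic experiments do and do not establish.

## Spherical-harmonic representation

Symmetric fODFs are expanded in the real, even-order SH basis built from
Condon–Shortley-phase complex harmonics: `√2·Re(Y_ℓ^{|m|})` for `m < 0`,
`Y_ℓ^0` for `m = 0`, `√2·Im(Y_ℓ^m)` for `m > 0`, indexed by `ℓ` ascending
then `m` ascending. With `lmax = 8` (default) there are 45 basis
functions; the convention is pinned by golden-value tests against
textbook closed forms for `ℓ ≤ 4`.

Normalization divides the coefficient vector by `√(4π)·A₀`, making the
fODF integrate to exactly 1 and the leading coefficient redundant (44
free numbers per voxel). Voxels with `|A₀| ≤ ε` (default `ε = 1e-8`) are
zeroed and flagged in a validity mask rather than dropped, keeping arrays
dense; in practice Rician rectification keeps `A₀` well away from zero
even in free water, so the mask matters mainly for padded background.

Quadrature oracles use a Gauss–Legendre × uniform-azimuth product grid,
exact for band-limited integrands; tessellations for peak finding and
constraints are subdivided icosahedra (1281 hemisphere orientations for
peaks, 321 for the CSD constraint set).

## Phantom simulation

The generator emulates a single-shell acquisition: 1 b0 volume plus 60
directions at b = 3000 s/mm², directions spread by seeded electrostatic
repulsion with antipodal symmetry. Voxels hold at most five discrete
fibers; the signal is the fraction-weighted sum of prolate-tensor
responses `exp(-b(λ⊥ + (λ∥−λ⊥)(g·u)²))` with defaults
`λ∥ = 1.7e-3`, `λ⊥ = 0.2e-3` mm²/s (typical coherent white matter);
fiber-free voxels decay isotropically with `D_iso = 3.0e-3` mm²/s (free
water). Noiseless b0 is exactly 1, so signals are attenuations and
`SNR = 1/σ_g` fixes the noise scale directly. Noise is Rician (magnitude
of the complex signal after adding independent Gaussian noise of std
`σ_g` to both channels); a pure-Gaussian option exists for Monte-Carlo
oracle tests.

The default layout splits the volume into three slabs: a single-fiber
region whose orientation bends smoothly with position (±15° across the
volume), an orthogonal-crossing region (fractions 0.5/0.5), and an
isotropic region. Slab boundaries sit at odd high-resolution indices so
2×2×2 blocks straddle them — the situation where an upsampler must
actually resolve sub-voxel structure. Phantoms model subjects drawn from
a shared anatomy: one canonical fiber frame, rotated per phantom by a
small seeded rotation (≤ 8°). This mirrors the fact that real training
and test subjects share anatomy statistics; with fully independent random
frames per phantom, a small training corpus could not generalize to a
held-out phantom at all, which would test corpus size rather than the
method.

Low-resolution data arise two ways, both used deliberately:
block-averaging a measured (noisy) high-resolution volume — how training
pairs are built from an existing scan — and direct simulation at
`SNR_lr = 8√2·SNR_hr` — a genuine low-resolution acquisition whose SNR
gain combines the 8× voxel volume with a √2 repetition gain.

What the phantom does **not** emulate: real anatomical variability and
partial-volume mixtures beyond slab boundaries, multi-shell q-space
structure, spatially varying response functions, relaxation/proton-density
contrast, motion and eddy artifacts. Passing tests show the pipeline's
machinery is correct and that the method's qualitative orderings emerge
under controlled conditions — not that effect sizes transfer to brains.

## Constrained spherical deconvolution

Per voxel, the measured shell attenuation `s` (signal divided by the mean
b0) is modeled as the spherical convolution of the fODF with the
single-fiber response. Response degree factors `r_ℓ` come from
Gauss–Legendre quadrature of the axially symmetric response against
`Y_ℓ0`; the forward matrix applies `√(4π/(2ℓ+1))·r_ℓ` per degree so that
a unit delta fODF reproduces the response exactly (up to the order-8 band
limit, whose truncation residual is ~5e-3 for the default response — the
fODF model is band-limited by construction).

The solver iterates Tikhonov-regularized least squares: starting from an
unconstrained fit truncated at ℓ = 4, directions on the constraint
tessellation whose current fODF amplitude falls below
`τ × mean(initial amplitude)` are penalized with weight `λ` (scaled by
`n_gradients·r₀/n_constraints` to keep the two terms commensurate), and
the active set is recomputed until it stabilizes (`max_iter = 50`,
typically < 10 iterations). Defaults `λ = 1`, `τ = 0.1` follow standard
published practice. The soft penalty leaves negative lobes of a few
percent of the peak amplitude; they shrink as `λ` grows but are never
clipped.

Correctness is cross-checked against two independent routes: a
hard-constrained quadratic program (`min ‖Fa − s‖², Ba ≥ 0`) solved
exactly via the classical least-squares-with-inequalities →
least-distance-program → NNLS reduction, which the soft iteration
provably approaches as `λ` grows (normalized-coefficient correlation
≥ 0.99 at `λ = 10`, ≈ 0.97 at the default `λ = 1`, where soft and hard
formulations legitimately differ); and a direct nonnegative
amplitude-grid deconvolution (NNLS over candidate orientations) that
confirms dominant peak placement.

Response estimation from data is supported as: user-supplied mask →
per-voxel log-linear tensor fit → mean eigenvalues. No automatic
anatomical localization is attempted.

## The DSR network

Architecture exactly as specified by the patch contract: 1188 inputs
(3×3×3 voxels × 44 normalized coefficients, flattened C-order with the
coefficient index innermost), three `dense(1000) → batch-norm → ReLU`
blocks, linear 352-output layer; 3,549,352 trainable parameters counting
weights, biases and two batch-norm parameters per hidden unit (the 5×5×5
input variant computes to 7,861,352 ≈ 7.86 million). Border neighborhoods
are zero-padded so every masked low-resolution voxel is a datapoint.

The implementation is plain numpy — forward, backprop (including the
batch-statistics batch-norm gradient) and Adam — which keeps runs
bit-reproducible under a seed. Batch norm uses per-batch statistics in
training and exponential running averages (momentum 0.1, ε = 1e-5) at
inference; He initialization; learning rate 1e-3; batches of size 1 are
skipped because batch statistics degenerate. Training MSE is recorded
per epoch; validation MSE when a validation set is supplied. Splits are
assigned at phantom granularity only, so leakage across splits is
structurally impossible.

Spline baselines evaluate `scipy.ndimage.map_coordinates` on the
coordinate mapping `j = (x − 0.5)/2` (low-resolution voxel `j` centered
at high-resolution coordinate `2j + 0.5`), with mirror boundary handling
and exact prefiltering for order 2. Order 0 reproduces 2×2×2 block
replication exactly, which also makes it the proxy for "use the
low-resolution data as is".

## Peaks and the angular EMD

Peaks: local maxima over the tessellation adjacency, antipodally unique,
ordered by descending amplitude with lexicographic tie-break on direction
components, thresholded at 0.5 of the voxel maximum, greedily suppressed
within 25°, truncated to 5 — the standard extraction settings, used
everywhere.

Angular EMD: amplitudes are normalized to unit mass per set and the
minimum-cost transport is solved under `c(u, v) = arccos(|u·v|)` in
degrees (antipodal symmetry: peaks are orientations, so costs cap at
90°). Closed forms handle the 1×n and 2×2 cases; larger cases go through
the HiGHS transportation LP. Conventions for degenerate voxels: both
sets empty → 0; exactly one empty → 90 (all mass at maximal cost),
flagged by construction since genuine transports are strictly below 90
almost surely. The solver is verified against exhaustive enumeration of
transportation-polytope vertices and against a min-cost-flow
formulation, and satisfies the metric axioms (symmetry, bounds, triangle
inequality) under property tests.

Best-method fractions flag every method within 1e-9° of the per-voxel
minimum, so ties count for all tied methods and fractions may sum to
more than 1 — the tally semantics used for method comparison.

SH similarity tables report MSE, Pearson correlation and MAE per
coefficient over masked voxels (correlation of a constant map is
reported missing), plus PSNR and SSIM per coefficient on the 3D maps
(window 7³ or the largest odd size that fits; dynamic range =
ground-truth max − min per coefficient; masked-out voxels zeroed in both
volumes).

## The end-to-end experiment

`run_experiment` trains the network once on phantoms that emulate a
high-quality acquisition (`train_snr = 20`; training low-resolution
volumes are block-averages of the noisy high-resolution ones, exactly
how low-resolution data would be derived from measured scans), then
sweeps `SNR_hr` over test data only: per sweep value the test phantom
yields a noiseless high-resolution dataset (ground truth), a noisy
high-resolution one, and a directly-acquired low-resolution one at
`8√2·SNR_hr`. Upsampled fields (network and splines 0–2) and the noisy
high-resolution field are scored by mean white-matter angular EMD
against the clean peaks. Training is not repeated per noise level — the
trained upsampler is a fixed instrument applied across conditions.

Problem sizes are chosen for a desk machine: 24³ phantoms, three
training phantoms (5184 patch pairs), reduced network widths
(256, 256, 256), 30 epochs, sweep {2, 5, 20}; the full sweep runs in
about six minutes on one CPU. At this scale the qualitative results are:
the network beats nearest-neighbor replication and beats the noisy
high-resolution acquisition at `SNR_hr = 5`, and its advantage over the
noisy high-resolution arm decreases monotonically with SNR, turning
negative by `SNR_hr = 20` — the low-SNR regime is where upsampling a
cleaner low-resolution scan pays. Higher-order splines remain strong on
this phantom because its fields are smooth away from slab boundaries;
desk-scale magnitudes are not transferable to anatomical data, only the
orderings are asserted. Every stage seed derives deterministically from
the master seed, and reruns reproduce metric tables bit for bit.

## Known limitations

- The fODF model is band-limited at order 8; very sharp crossings below
  ~25° separation are unresolvable by construction.
- The soft-constrained CSD keeps small negative lobes (see above); use
  the QP route where exact nonnegativity matters and runtime permits.
- The numpy network trains on CPU; at the full published scale
  (millions of patches, widths of 1000, 100 epochs) a GPU framework
  would be the practical choice — the architecture and training contract
  here are identical, just smaller.
- The empty-vs-nonempty EMD convention (90°) is a choice; it brands
  complete peak-set disagreement as maximal error and is flagged in the
  documentation rather than configurable.
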