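# Methods

## Sensor model

The simulated imager measures one 3-channel triplet per pixel: visible
(R, G, B) where `(r + c) % 2 == phase`, NIR (NIR1, NIR2, NIR3) elsewhere.
Which parity is visible at the sensor origin is hardware-specific, so the
phase is an explicit parameter everywhere (default 0). Coordinates are
row-major, 0-based, origin top-left. Pixel values live in [0, 1]; 8/16-bit
files are normalized on read and re-quantized on write. Unmeasured pixels in
a half-sampled stream are stored as 0 with an authoritative boolean validity
mask — a stored 0 is never read as data, and masked storage (rather than
NaN) keeps convolution paths clean.

## Baseline interpolation

The two streams are offset by one pixel *horizontally*, so the baseline
averages the left/right measured neighbours of each missing pixel ("1D"
bilinear). At the left/right border a missing pixel has a single horizontal
neighbour, which is replicated — the least surprising rule, and it keeps
every output value inside the measured range of its row. Measured pixels
pass through bit-exactly. A vertical-axis variant and a 4-neighbour 2D
variant exist behind flags for sensitivity checks; they are not the baseline.
The operator is linear in the measured values (tested to 1e-12) and exact
for row-constant signals.

## Residual network

* Architecture: N convolutional layers, 3×3 kernels, one-pixel padding (the
  output always matches the input size), 64 filters in layers 1…N−1, 3 in
  layer N. Kernels span the full channel depth of their input (a first-layer
  kernel is a 3×3×3 volume). Hidden layers apply convolution → batch
  normalization → SELU, in that order; the final layer is convolution only.
* SELU constants default to the canonical self-normalizing fixed-point
  values λ = 1.0507009873554805, α = 1.6732632423543772, overridable via
  `SeluParams`.
* Batch normalization: per-channel over (batch, height, width), ε = 1e-5,
  running statistics with momentum 0.1. Training mode normalizes with batch
  statistics; demosaicing (inference) uses the stored running statistics.
* Default depth is 20 — at full training scale, deeper models reconstruct
  better up to that point — but depth is a config parameter throughout, and
  the desk-scale experiment uses depth 5.
* The forward pass, backpropagation (including through batch-norm batch
  statistics), MSRA/He initialization and Adam are implemented on numpy via
  im2col + BLAS matmul. Float32 is the working precision; float64 is used
  where exactness matters (gradient verification).
* A model whose final layer is zero predicts a zero residual, making the CNN
  demosaicer *bit-identical* to the bilinear baseline — the anchor point of
  the residual formulation, and a tested invariant.
* Checkpoints are an `.npz` of named arrays plus a JSON manifest (depth,
  filters, SELU constants, dtype, provenance including seeds).
* CNN output is clipped to [0, 1] after the residual is added; the
  unclipped reconstruction is available via `reconstruct()`.
* The visible and NIR networks share one architecture, and by default the
  NIR stream reuses the color-trained weights: the two spectra carry
  comparable high-frequency structure (thin fluorescent vessels are edges
  too), so a color-trained model transfers. Independent NIR weights can be
  supplied.

## Training

Ground truth for one stream is any full-resolution 3-channel image. The
pipeline per patch: checkerboard-sample → 1D bilinear fill → the pair
(interpolated Y, truth X); the network learns the residual X − Y by
minimizing the batch mean of the squared L2 norm of
(residual + Y − X). The mean is over patches in the batch (not pixels),
matching a per-patch squared-norm objective.

Patches: 50×50 at uniformly random offsets, sampled with replacement under a
seed; 100 per image by default. Augmentation: the 8 dihedral variants
(4 rotations × horizontal flip); the sensor simulation is re-applied *after*
augmenting the ground-truth patch, so the horizontal interpolation geometry
is identical for every variant. Train/test splits are by whole images, never
by patches.

Optimizer: Adam at a constant learning rate (1e-5 default), He-initialized
convolutions, zero biases, unit/zero batch-norm scale/shift. Batch size,
step budget and stopping are free parameters (defaults: batch 64, budget
from config); a non-finite loss aborts with a diagnostic. Runs are
reproducible under a fixed seed.

## Desk-scale reference experiment

Full-scale training needs a large external color corpus and GPU time. The
package's reference experiment (`hexademosaic.experiments`, also what
`scripts/acceptance.py` runs) is sized for minutes on one CPU:

* 8 synthetic training scenes (96×96), 5 patches each, ×8 augmentation →
  320 patches; 20 held-out scenes; split by scene.
* depth 5, 64 filters, batch 32, 200 Adam steps at constant 1e-3. At 200
  steps the batch size sets the gradient-noise floor; 32 keeps the late-run
  loss stable where 16 still fluctuates visibly.
* Two deliberate accommodations of the short step budget, decided from the
  structure of Adam rather than tuned:
  - **learning rate 1e-3** instead of 1e-5: Adam's per-step parameter
    movement is ≈ the learning rate, so 200 steps at 1e-5 move weights by
    ~2e-3 — too little to train He-initialized layers at all. 1e-3 is
    Adam's canonical step size and suits a 200-step budget.
  - **zero-initialized final layer** (`zero_init_final=True`): with He
    initialization everywhere the initial residual is O(1), dwarfing the
    true residual (~1e-2), and a short run is spent shrinking scale.
    Starting the residual branch at zero makes the untrained model exactly
    the bilinear baseline, so training starts from parity and can only build
    improvement — the standard zero-init-residual-branch device. At full
    scale neither accommodation is needed and the defaults (1e-5, pure He)
    apply.
* Measured outcome (seed 1): held-out visible MSE 5–10% below bilinear on
  all three channels — directionally consistent with the much larger
  reductions a 20-layer model reaches at full training scale, at ~1/1000 of
  the compute.

## Synthetic scenes

Each scene stacks, per the spec of structures that make demosaicing hard:
smooth low-order background gradients; step edges at random orientations
(the zipper-artifact regime); optional texture patches; thin anti-aliased
random-walk curves 1–3 px wide, bright in NIR channel 1 (fluorescent-vessel
analogue, drawn by disk-stamping on a 2× supersampled grid); NIR channels
built as ρ·(visible luminance) + (1−ρ)·independent content. With ρ = 1 and
no curves, NIR 1 equals the visible luminance exactly. Scenes are
deterministic functions of their spec via the counter-based Philox
generator, and a dataset manifest allows bit-exact regeneration.

What the generator does **not** emulate: optics (blur, vignetting), sensor
noise statistics (only optional additive Gaussian noise), spectral quantum
efficiency, and the chromatic statistics of natural and surgical imagery.
Passing the desk-scale comparison therefore shows the pipeline and the
learning dynamics are correct, not that a model trained here transfers to
real tissue.

## Metrics

* PSNR = 10·log10(peak²/MSE) per channel, +inf for identical images; the
  PSNR/MSE identity is asserted on every report.
* SSIM uses the standard 11×11 Gaussian window (σ = 1.5), K1 = 0.01,
  K2 = 0.03, dynamic range 1 (computed with scikit-image);
  DSSIM = (1 − SSIM)/2; for triplets the SSIM map is channel-averaged before
  the percentile. The *95th percentile* over pixels is reported, on the 0–1
  scale.
* ΔE is the per-pixel Euclidean distance across the 3 channels as a percent
  of the maximum √3·peak — one formula for visible and NIR triplets, keeping
  the domains comparable (Lab space is undefined for NIR). A CIE76 Lab
  variant is available for the visible triplet behind a flag.
* FFT comparison: centered log-magnitude spectra with a −120 dB floor; the
  central vertical column of the shifted spectrum is the vertical-frequency
  line profile; the high-frequency deficit is the mean |difference| over the
  top quartile of vertical frequencies.

## Known limitations

* Absolute MSE/ΔE/DSSIM values are scale-convention dependent; comparisons
  across implementations are only meaningful directionally.
* The numpy training loop is single-threaded BLAS-bound; full-scale (20
  layers, 4.6k images × 100 patches) training is out of its intended range.
* NIR reconstruction reuses color-trained weights by default; scenes whose
  NIR statistics differ strongly from the visible stream would need
  independently trained NIR weights.
* Batch-norm running statistics come from 200 short-run batches in the
  desk-scale experiment; inference/training normalization mismatch is small
  but nonzero.
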