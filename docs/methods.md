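# Methods

## The pipeline

`synthdetect` studies how detectable GAN-generated 28×28 grayscale
bioimages are, as a function of generator training time.  One *case study*
is: train a DCGAN on 1000 real images for 50 epochs, snapshot 1000 generated
images after every epoch, and for every (descriptor filter, classifier,
epoch) cell train and evaluate a real-vs-generated classifier on the 1000
real + 1000 generated images of that epoch.  Detection accuracy per epoch is
the realism curve: high accuracy means the generated images are still easy
to tell apart; accuracy falling towards 0.5 means the generator's output
distribution is approaching the real one (as seen by that descriptor and
classifier).

## Generator and discriminator

Both networks are fixed-architecture DCGANs operating on 28×28×1 images in
[−1, 1].  Kernel sizes are 5×5 with stride 2 and SAME padding throughout;
these are forced by the per-layer parameter accounting (e.g. the first
transposed convolution's 819 328 parameters = 5²·256·128 + 128).  Batch
normalisation carries 4 parameters per channel — scale and shift trainable,
moving mean and variance not — which yields the non-trainable totals of
25 472 (generator) and 384 (discriminator) exactly.  The generator's output
activation is tanh, consistent with the [−1, 1] pixel normalisation.

The layers, backpropagation and the Adam optimiser are implemented directly
on NumPy arrays (float32 for training; layer classes accept float64, which
the test suite uses for finite-difference gradient checks at 1e−7
tolerance).  Convolutions use an im2col/col2im formulation; the transposed
convolution is implemented as the exact adjoint of the strided convolution,
verified by an inner-product identity test.

Training choices where convention had to fill gaps, all configurable in
`GanConfig`:

- latent prior: standard normal, dimension 100 (fixed; other dimensions are
  rejected because the dense layer's parameter count pins the architecture);
- batch size 256; LeakyReLU slope 0.2; dropout rate 0.3; Adam
  lr = 2·10⁻⁴, β₁ = 0.5, β₂ = 0.999, ε = 10⁻⁷; batch-norm momentum 0.99,
  ε = 10⁻³;
- update schedule: one discriminator step (real batch and fake batch as two
  forward/backward passes with summed gradients) then one generator step per
  minibatch;
- losses clip probabilities to [10⁻⁷, 1 − 10⁻⁷] before the logarithm; a
  non-finite loss aborts with the epoch and step named;
- epoch snapshots are drawn *after* each epoch's updates from fresh latent
  vectors, seeded per epoch by a `SeedSequence` derived from the config
  seed; sampling runs the network in inference mode (moving batch-norm
  statistics).

All randomness — weight initialisation, shuffling, dropout masks, latent
draws — flows from the single `GanConfig.seed`, so runs are bitwise
reproducible on a given platform.

## Descriptors

The three filters reduce an image to a fixed-length vector whose length
never depends on content.  Their named sources (Weka/LIRE-style filters) do
not publish parameter values, so defaults were fixed once:

- **jpeg_coefficient** — edge-replicate the 28×28 image to 32×32, take the
  orthonormal type-II DCT of the 16 non-overlapping 8×8 blocks, zigzag-order
  the coefficients, and histogram each of the first 9 positions (DC + 8 AC)
  across blocks into 16 equal-width bins (length 144).  Histogram ranges are
  fixed — DC in [0, 2048] (the DC of a uint8 block is 8×mean ≤ 2040), AC in
  [−1024, 1024] — and out-of-range values are counted in the nearest edge
  bin so each histogram always sums to 16.
- **auto_color_correlogram** — quantize intensities to 64 levels
  (bin = ⌊v·levels/256⌋); for each level c and distance d ∈ {1, 3, 5, 7},
  the fraction of ordered pixel pairs (p, q) with p of colour c and q
  in-bounds at Chebyshev (L∞) distance exactly d from p, where q is also
  colour c (length 256, colour-major).  Pairs leaving the image are excluded
  from the denominator; absent colours contribute 0.
- **colour_layout** — partition the image into an 8×8 grid by even index
  boundaries (3- or 4-pixel blocks for side 28; no padding, whole-image
  coverage), take each block's mean in YCbCr (grayscale: Y = intensity,
  Cb = Cr = 128), DCT the 8×8 block-mean matrix per channel and keep the
  first 6 Y + 3 Cb + 3 Cr zigzag coefficients, real-valued (length 12).
  The MPEG-7 coefficient quantization step is deliberately omitted: the
  classifiers consume real values and quantization would only discard
  separability signal.

Chroma channels are kept constant rather than dropped so the vector layout
matches the colour-native filters the defaults are modelled on.  Each
descriptor is checked against an independent brute-force reference
(direct-summation DCT, exhaustive pair enumeration, per-block loops) to
1e−9 in the test suite.

## Classifiers and evaluation

The four families are exposed behind one interface: `c45_tree` (entropy
decision tree), `rep_tree` (entropy tree with small-leaf and
cost-complexity pruning, the fast pruned-tree analogue), `random_forest`
(100 trees, the reference family, and the best performer in this setting),
and `logistic_model_tree` (depth-3 entropy tree with a logistic regression
fitted in each two-class leaf).  These are standard scikit-learn estimators
(plus a thin LMT wrapper); no claim of bit-exact agreement with the Weka
implementations of the same names is made.

The evaluation protocol is a seeded stratified 10-fold cross-validation
whose out-of-fold predictions are pooled into one confusion matrix (a
stratified 70/30 holdout is available as `protocol="holdout"`).  Real
images are the positive class; accuracy, the headline metric, is invariant
to that choice.  Zero-denominator metrics are reported as 0 with an
explicit flag so aggregate tables contain no undefined entries.

The experiment grid derives a per-cell seed from
(master seed, dataset, filter, classifier, epoch) via CRC32 tags and a
`SeedSequence`, so any single cell can be recomputed independently.
Features are computed once per (filter, epoch) and may additionally be
cached on disk keyed by a content hash (`cache_dir=`).

## Synthetic fixtures

`synthetic_data` generates seeded 28×28 uint8 images from six families
(Gaussian blobs, annular rings, sinusoidal stripes, coarse speckle, lobed
gradient "organs", and a mixed family) plus additive Gaussian noise
(default σ = 8 intensity units, clipped to [0, 255]).  They mimic the
qualitative variety of small biomedical collections — compact bright cells,
membranes, textured tissue, smooth organ fields — but make no claim of
statistical fidelity to any real dataset.  Consequently, passing
fixture-scale tests demonstrates that the machinery is correct and that the
realism-tracking logic behaves as designed; it does not predict detection
accuracy on real bioimages.

`make_morphed_fakes(reals, λ, seed)` produces fakes of tunable realism as
the pixelwise mixture λ·real + (1−λ)·uniform-noise; λ = 0 is pure seeded
noise and λ = 1 reproduces its input exactly.  The monotonicity property
(detection accuracy non-increasing in λ, ≈0.5 at λ = 1) is evaluated with
morphs of an *independent* fixture draw from the same distribution, because
that is how GAN fakes relate to real images: same distribution, not copies.
Morphing the identical real batch at λ = 1 creates duplicate feature
vectors with opposite labels, and pooled cross-validation then
systematically *inverts* (a test point's identical twin sits in the
training folds with the opposite label, driving accuracy far below
chance, ~0.06 measured) — an instructive degenerate case, not a meaningful
measure of realism.

## Problem sizes

The full reference grid (6 datasets × 3 filters × 4 classifiers × 50
epochs, 1000 images per side) is supported by the code and sized by
`dry_run`.  The test suite and the acceptance script exercise the pipeline
at fixture scale — 200 real images, 5 epochs, 200 generated images per
epoch, colour-layout + random forest — which preserves every qualitative
property of interest (trivially separable early epochs, seeded
reproducibility, realism monotonicity) at a few minutes of single-core CPU.
Runs on real MedMNIST archives use the loader in `io_formats`, which
samples 1000 images per collection from locally downloaded NPZ files.

## Known limitations

- A NumPy training loop is orders of magnitude slower than a GPU framework;
  the 50-epoch × 1000-image reference configuration is hours of CPU per
  case study.
- Bitwise reproducibility holds for a fixed platform/BLAS; across BLAS
  builds results may differ in the last float32 bits.
- The descriptor defaults are reasoned reconstructions of the named
  Weka/LIRE filters, not bit-identical reimplementations.
- Single-channel images only; the colour-native descriptors see constant
  chroma.
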