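# Methods

This note records the model, the conventions, and the design decisions made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Spectral enhancer

A patch is an H×W×3 array in [0, 1]. Decomposition uses the unnormalized
forward 2-D DFT with the origin at bin (0, 0) (no center shift) and the
1/(HW)-normalized inverse; the conventions cancel in the round trip and are
fixed so that the direct-summation oracle used in the tests is bin-for-bin
comparable. The transform is applied to R, G and B independently: the goal
of the amplitude swap is to transfer per-channel color statistics, and a
channel-wise swap does exactly that (a grayscale-luminance variant would
discard the color information the method is meant to randomize).

Substitution is over the **full spectrum**, exactly as the defining
equation states — there is no low-frequency band hyperparameter as in
band-limited Fourier domain adaptation variants; the enhancer is the
documented extension point if a band-limited swap is ever wanted. After the
inverse transform the (numerical) imaginary residue is discarded and pixels
are clipped to [0, 1]; out-of-range excursions are artifacts of the swap,
which is also why enhancement is applied stochastically rather than always.

Enhancement policy: each source patch is enhanced independently with
probability 0.5 (the reported optimum lies in [0.4, 0.6]); the partner is
drawn uniformly **with replacement** from the current target mini-batch
(the pairing rule is otherwise unconstrained, and within-batch pairing
avoids holding a second dataset pass of spectra in memory). All patches
must share dimensions; the data pipeline resizes upstream.

## Adversarial network

Block indexing: block 1 is the stem, blocks 2–5 the residual stages of the
18-layer reference backbone, so tapping block 4 reads the 256-channel map
at 1/16 resolution — for 512×512 inputs, exactly the ℝ^(m×32×32)
discriminator input. The discriminator head is
flatten → 256 → 100 → 1(sigmoid); the 1-unit sigmoid output is the minimal
completion of the stated 256/100 hidden sizes. Feature maps larger than
32×32 are average-pooled onto a 32×32 grid first; smaller maps (the tiny
backbone) are flattened as-is. The label head is a global average pool
followed by a linear layer — the standard residual-net classifier head.

The gradient reversal constant λ defaults to 1.0 and is held constant (no
schedule). Early stopping monitors the **validation-fold source label
loss** (a patient-grouped hold-out of the source slides): "network loss"
without a validation set cannot detect the overfitting the method is meant
to prevent. Both the label predictor and the discriminator see the
*enhanced* source patches — the architecture routes one shared extractor,
and making the discriminator see raw source while the predictor sees
enhanced source would give the two heads inconsistent feature statistics;
this is configurable in principle but the shared route is the default and
the tested path.

Optimizer: Adam, no weight decay. Paper-scale defaults (learning rate
1e-4, batch 256, ≤20 epochs, patience 10, 3 folds, 5 seeds) are the
`TrainingConfig` defaults. Patch labels inherit slide labels verbatim.
Cross-validation folds are split by patient, never by patch or slide, to
prevent leakage. Backbone weights initialize from a seeded He-normal draw;
a `pretrained` flag exists but no pretrained weights are bundled.

Since torch is not available as a dependency, the entire network stack
(conv2d via im2col, batch norm, max/average pooling, linear layers, fused
cross-entropy, gradient reversal, Adam) runs on a ~500-line reverse-mode
autodiff engine over float32 NumPy arrays (`stainadapt.nn`). Gradients are
verified against central finite differences in the test suite, and the
engine is fully deterministic on one machine, which is what makes the
training-reproducibility contracts exact rather than approximate.

## Slide pipeline

Patch extraction walks the non-overlapping patch-size grid in seed-shuffled
order before falling back to uniform random offsets, so a request matching
the grid tiles the slide exactly; with an annotation mask only positions
whose center lies inside the mask are eligible. Coordinates are 0-based
half-open boxes. Defaults mirror the WSI protocol: 150 patches per slide at
1024², resized to 512².

VLAD uses intra-normalization (per-centroid ℓ2) followed by global ℓ2 —
the cited encoding's standard practice. Accumulations with norm below
1e-12 are treated as the documented all-zero degenerate case rather than
normalizing rounding residue. The codebook is fitted per fold on
training-fold **source** embeddings only, preventing target/validation
leakage; k defaults to 4 for multi-class and 1 for binary tasks. The slide
classifier is a linear-kernel SVM, C=1, one-vs-rest, with balanced class
weights (the histotype settings this pipeline targets are imbalanced);
per-class scores are softmax-calibrated margins, used for AUC.

## Synthetic benchmark

The generator emulates the premise the method rests on: class information
in phase/structure, domain information in amplitude/color.

* Classes: blob fields vs. oriented stripes (distinct geometry, identical
  palette), rendered into an H&E-like two-color palette on 256² slides.
* Domain shift: a 3×3 channel-mixing matrix (hue rotation plus global
  darkening; rows scaled so the subsequent gain does not clip), a smooth
  radial amplitude gain g(r) = 1 + (γ−1)·exp(−(r/r₀)²) with γ=1.6,
  r₀=0.06 cycles/pixel, and additive Gaussian noise (σ=0.02 target, 0.01
  source). Both domains share identical motif parameters by construction.
* Scale: 2 classes × 20 slides per class per domain, 16 patches of 64² per
  slide — sized so the full two-arm, five-seed comparison runs in a few
  minutes on one CPU with the tiny backbone (four stride-2 conv blocks of
  8 channels).
* Benchmark training settings: learning rate 1e-3, batch 64, ≤25 epochs,
  patience 8 — the paper-scale 1e-4 is calibrated to a deep pretrained
  backbone and does not converge a small randomly initialized network at
  this data scale. These conditions were fixed after a single calibration
  run and are frozen as the defaults.

What the generator does **not** emulate: nucleus-level morphology, stain
deconvolution physics (the mixing matrix is a linear RGB operator, not a
Beer–Lambert optical-density model), scanner compression artifacts, tissue
folds, or pyramidal WSI structure. A passing benchmark therefore shows that
the pipeline removes amplitude/color-borne domain signal while preserving
structure-borne class signal — it does not certify clinical-grade
performance on real WSIs.

The shift-severity score applies both domain transforms (noise-free) to
the *same* probe content and reports the mean |log amplitude ratio| over
spectra bins: identical transforms score exactly 0 and the score increases
with the gain's deviation from 1.

## Statistics and visualization

Balanced accuracy is the unweighted mean of per-class recalls (0–100
scale); classes absent from the truth vector are excluded with a warning.
AUC is one-vs-rest macro-averaged (the multiclass scheme is otherwise
unspecified). The Wilcoxon signed-rank test is exact for ≤25 non-zero
paired differences via a dynamic program over (mid)ranks — ties handled
exactly, zeros dropped — and a normal approximation above; an all-zero
difference vector reports p=1 with a zero-variance flag (library behaviors
differ here; fixed for reproducibility). Significance level 0.05.

Heatmaps map per-patch probability through a blue→red colormap,
alpha-blended at the recorded patch coordinates with overlaps averaged.
Importance maps are the gradient-weighted channel combination of the
**final** conv block's activations (regardless of the discriminator tap),
rectified, min-max scaled, bilinearly upsampled; patch ranking is by the
predicted probability of the slide's ground-truth class with ties broken
by slide-order index.

## Seeding and reproducibility

One master seed fans out to named substreams (slide rendering, patch
sampling, augmentation, enhancer masks/pairings, validation split, k-means,
SVM, probes) via CRC-keyed `SeedSequence`s, all below 2³¹. Every artifact —
trained weights, reports, rendered PNGs — is a pure function of
(config, seed), and configs are recorded as a SHA-1 hash in all outputs.

## Known limitations

* The tiny backbone has four blocks, so a discriminator tap of 5 exists
  only for the 18-layer reference backbone; the tap sweep skips infeasible
  taps with a log message.
* The NumPy engine is single-threaded and CPU-bound; training the
  reference 18-layer backbone at WSI scale is out of its intended range.
* Flat RGB images only; pyramidal WSI decoding is out of scope.
* With very few slides per class, slide-level balanced accuracy is coarse
  (steps of 1/slides-per-class), which is why benchmark conclusions use
  medians over five seeds.
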