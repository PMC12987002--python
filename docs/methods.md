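# Methods

`embryofuse` re-creates, at desk scale, the computational chain of a soft
optical sensor for embryo assessment: multi-focal acquisition, all-in-focus
fusion, embryo localization, developmental-stage classification, and
consensus-grounded reporting.  This note records the models, the defaults and
why they were chosen, what the synthetic benchmark does and does not show,
and the numerical conventions a maintainer would need.

## Synthetic phantoms (`embryofuse.phantom`)

**What is emulated.**  A time-lapse incubator camera observes an embryo in a
culture well through a shallow depth of field and steps its focus motor
through seven planes F−3…F+3 at increments Δz of 0.5–1.5 µm.  The phantom
generator produces scenes with a bright well background (smooth seeded
texture, level 0.78), a dark zona pellucida ring (contrast −0.22, rendered at
the equatorial depth z = 0), one to several granular blastomeres (contrast
−0.30 with clipped Gaussian texture of RMS 0.11 and ~1.6 px correlation, a
darker membrane rim, depths drawn from ±3, ±2.5, ±1.5, ±0.5 and 0 µm), and
small anucleate fragments.  Seven stage classes are supported — `1cell`,
`2cells`, `3cells`, `4cells`, `more` (≥5 cells standing in for the
morula/blastocyst pool), `empty`, and `not_defined` (debris without a zona) —
with default class proportions 19.2 / 18.5 / 4.7 / 17.4 / 21.5 / 7.6 / 11.0 %
(printed values sum to 99.9 % and are renormalized; integer counts use
largest-remainder apportionment).  Splits are 68 / 12 / 20 % by seeded
shuffle.

**Depth and defocus model.**  Each feature carries one scalar depth (a
thin-feature approximation; real embryos are volumetric but no depth map is
available for a 2-D phantom).  A plane at focal offset f renders a feature at
depth z through an isotropic Gaussian of σ = `blur_scale`·|z − f|/Δz pixels
(default `blur_scale` = 2 px), the standard thin-lens defocus approximation;
σ = 0 reproduces the sharp rendering exactly.  Additive Gaussian sensor
noise (σ = 0.01 of full scale) is applied to every plane.

**The all-in-focus reference** renders every feature sharp and carries the
same sensor-noise model (an independent realization): it emulates an ideal
extended-depth-of-field capture by the same camera.  A noise-free reference
would make sharpness comparisons ill-posed — the defocused planes would carry
noise-gradient energy that the reference lacks.

**What the phantoms do not capture.**  No photorealistic cytology, no
overlapping or compacting blastomeres (cells are kept disjoint so the class
label is verifiable by connected components), no temporal dynamics, no
illumination drift, and defocus is modelled as a single Gaussian rather than
the full optical point-spread function.  Passing tests therefore demonstrate
correct mechanics of the pipeline and the direction of physical effects (what
defocus destroys, fusion recovers), not clinical performance.

## Laplacian-pyramid fusion (`embryofuse.pyramid`)

Each plane is decomposed into band-pass levels plus a low-pass residual with
the 5-tap binomial kernel [1,4,6,4,1]/16, reflect padding and ceil-halving;
up-sampling uses normalized zero-insertion interpolation (smoothed samples
divided by the smoothed sampling indicator) so constants are preserved at
borders, and `collapse` inverts `build_laplacian` exactly by construction
(round-trip ≤ 1e−6 is asserted; in float64 it is ~1e−16).  Fusion keeps, at
every band-pass coefficient, the input with the maximum absolute value (ties
resolve to the lowest plane index, deterministically).  The low-pass residual
is fused by element-wise mean by default: applying max-abs selection to a
non-zero-mean low-pass band systematically biases brightness toward extreme
planes; `residual="max-abs"` is available for literal per-level selection.
Four levels are used for 256² inputs.  Outputs are clipped to [0, 1] because
pyramid recombination can overshoot.

## Neural fusion (`embryofuse.fusion_nets`)

Three U-Net variants consume the seven planes stacked channel-wise
(F−3…F+3 order is semantic) and emit one sigmoid-bounded image:

* **UNet-DC** — double Conv-BatchNorm-ReLU units per stage;
* **UNet-SC** — single units (the lightweight engine);
* **AFU-Net** — SC-style encoder plus an attention-gated bottleneck
  (channel layer-norm → 1×1 convolution → sigmoid gate, multiplicative).

All share the 64→128→256 encoder with 2× max-pooling, a 512-channel
bottleneck, nearest-neighbour-upsampling decoders with channel-concatenation
skips, and require spatial dimensions divisible by 8 (no silent padding).
Parameter counts order DC (8.57 M) > AFU (4.92 M) > SC (4.65 M).

Training distills the classical fusion: the loss is the pixel mean-squared
error against the Laplacian fusion of the same stack.  Defaults: Adam,
learning rate 1e−3, batch 8, seeded dihedral augmentation applied jointly to
stack and target (an eightfold variety multiplier that desk-scale training
sets need).  Stacks rendered by the phantom generator are already in [0, 1];
file inputs are normalized by their integer dtype range at read time, so no
further per-stack normalization is applied.

**Desk-scale distillation study** (used by the tests and the reproduction
script): 90 phantoms at 64² (61 training stacks), UNet-SC, 8 epochs.  This
reduces the epoch-mean loss by roughly 40× and brings the held-out MSE to the
LP target below 10× the irreducible noise floor (the floor is measured as
the MSE between LP fusions of two different noise realizations of the same
scenes).  One caveat is recorded deliberately: the trained network's average
gradient reaches only ≈ 0.55× of its LP target at this budget — the network
converges to the denoised solution first and would need far longer training
to reproduce the noise-borne high frequencies of the target (the target is a
deterministic function of the input planes, so a fully trained network
approaches ratio 1); reported sharpness gains of fusion networks over the
classical baseline belong to training budgets orders of magnitude larger.
The study therefore asserts the loss-reduction, the fidelity floor and a
1.5× upper sharpness bound, and reports the measured ratio.

## Sharpness metrics (`embryofuse.metrics`)

Two gradient conventions coexist deliberately.  The fusion-quality score
`average_gradient` is mean √((Gx²+Gy²)/2) with forward differences on the
(H−1)×(W−1) interior — the fusion-literature convention; absolute values are
comparable only within one image size and content class, so tests assert
orderings, never absolute figures.  The localization path uses Sobel
operators (reflect padding) for per-pixel `gradient_magnitude` — the
noise-robust choice for edge search.

## Embryo localization (`embryofuse.roi`)

**Coarse detection** replaces a cascade detector that would need thousands of
labelled training images: the Sobel magnitude of the blurred image is
thresholded into an edge map (floor = 2.5× median gradient), and ring
templates over a 16-step radius sweep score every (center, radius) by the
fraction of the circle lying on edges.  A candidate needs ≥ 50 % edge support
on its (border-normalized) visible circle, ≤ 25 % support on a circle 22 %
larger — the exterior of a true embryo boundary is quiet background, which is
what rejects interior cell membranes — and ≥ 20 % of the circle in bounds
(this stops mostly-out-of-frame arcs from qualifying through border
normalization alone, while corner-clipped objects still detect and are
flagged).  Among candidates within 85 % of the best support the largest
radius wins, because the zona pellucida is the outermost circular structure.
Structureless images raise a no-detection error — the "empty well" path.  A
hook accepts any external detector with the same contract.

**Radial refinement** casts `n_rays` (default 180) equally spaced rays from
the candidate center, takes the per-ray arg-max of the gradient magnitude
within [r_min, r_max] with parabolic sub-pixel interpolation, sets the radius
to the median per-ray radius, re-centers on the centroid of the edge points,
and repeats until the center moves < 0.3 px (≤ 5 passes; a single re-run
already lands within ~2 px, the loop removes the residual centroid bias of
ray-casting from an off-center origin).  If every per-ray peak falls below
3× the median gradient the edge is declared too weak.  The final crop is a
square of side 2·radius·(1 + margin) (margin 0.1), edge-padded where needed,
bilinearly resized to 224².

Measured on 100 fused phantoms (20 seeds × 5 embryo-bearing classes, 256²):
median radius error ≈ 0.04 %, median center error ≈ 0.3 px; the acceptance
bounds are ≤ 4 % and ≤ 2 px.

## Classification (`embryofuse.backbones`, `embryofuse.classify`)

The three reference backbones are constructed faithfully — ViT-Base/16
(patch 16, width 768, 12 blocks/heads), Swin-Tiny (patch 4, window 7, widths
96–768, depths 2/2/6/2, shifted-window attention with learned relative
position bias and border masking), ConvNeXt-Tiny (depths 3/3/9/3, widths
96–768, 7×7 depthwise convolutions, inverted-bottleneck MLPs, per-channel
layer scale) — so that the parameter accounting with a 7-class head comes out
at 27.52 M (Swin-Tiny), 85.80 M (ViT-Base) and 27.83 M (ConvNeXt-Tiny; the
published table prints 27.82, a rounding-convention difference within the
documented ±0.01 M tolerance).  Grayscale crops are replicated to three
channels at the input; no pretrained weights are used anywhere.  A traced
MAC counter is provided for informational FLOP figures (it reproduces
Swin-Tiny's ~4.5 G).

Everything runs on a small numpy reverse-mode autograd engine written for
this package (`embryofuse.nn`): convolution via `sliding_window_view` +
BLAS, verified against numerical gradients.  Training the 27–86 M-parameter
backbones from random initialization is far outside a single-CPU budget, so
the trainable benchmark model is `small_cnn` (three Conv-BN-ReLU-pool
stages, ~24 k parameters, 48² inputs by default) — the architecture
benchmarks above are structural (construction, forward pass, parameter
accounting).

**Fused-vs-single-plane study.**  The embryo is localized on the fused image
and the identical crop geometry is applied to both sources (the fused image
or the raw F0 plane), so the paired accuracy difference isolates fusion
itself.  Class imbalance is handled by seeded rotation/flip oversampling of
minority classes to the majority count each epoch.  The desk-scale study
uses 500 phantoms at 96², five paired seeds and a small epoch budget, with
crops presented to the classifier at 64² — down-sampling the crops further
(48² and below) was observed to erase the fused-vs-single-plane gap
entirely, because it discards exactly the fine structure fusion recovers, so
the input resolution is part of the study design.  The study asserts only
the *direction* — fused accuracy ≥ single-plane accuracy in most seeds —
never the clinical accuracy figures, which belong to a dataset five hundred
times larger.

## Reporting (`embryofuse.reporter`)

Retrieval is exact-key over a bundled structured knowledge base (one
validated entry per stage: paraphrased consensus criteria, typical features,
forbidden terms, source tag); a similarity hook may append related entries
but nothing is fabricated.  Reports have three mandatory sections —
observation, confidence, consensus alignment — templated exclusively from the
prediction and the retrieved entry, which yields a closed vocabulary: every
stage-specific morphological term in a report is traceable to the entry.
Confidence tiers are High ≥ 0.9, Moderate ≥ 0.7, else Low (configurable; the
source system only ever shows "High confidence", so the lower tiers are
artifact choices).  A quality grade is emitted only when a grade mapping is
configured.  The validator re-checks any report (including hook-rewritten
ones) for stage-forbidden terms with case-insensitive word-boundary matching
— the canonical guard being that a 2-cell report must never mention an
"inner cell mass" — and for missing sections.

## Pipeline and I/O

The default stage order is fuse → localize → crop → classify → report;
crop-first operation is supported but fusion-first is the default because
boundary localization is most reliable on the sharpest image.  Stacks are
stored as 7-page 16-bit TIFFs (page k ↔ F_{k−3}) or seven 8-bit PNGs named
`<stem>_F-3 … _F0 … _F+3`; integer images normalize to [0, 1] by dtype range
on read.  Datasets are JSON-lines manifests.  Pipeline artifacts are keyed
by a hash of configuration and input, never mutate inputs, and are reused on
re-runs with a matching hash.

## Degenerate inputs and numerical conventions

Uniform images: no-detection (coarse) / weak-edge (refinement) errors.
Empty wells: the pipeline classifies the uncropped resize and flags
`no_detection`.  Ties in max-abs selection: lowest plane index.  Constant
images: average gradient exactly 0.  Pyramid depth limited so the coarsest
level keeps ≥ 4 px.  Probabilities are validated to [0, 1]; F1 of a class
absent from truth and predictions is reported as 0 and flagged.  All
generators, trainings and retrievals are pure functions of integer seeds;
reruns are bit-identical on the same platform (floating-point reductions can
differ across BLAS builds).

## Problem sizes

Test-suite and reproduction-script study sizes were chosen to exercise every
claim on a single CPU: 64² stacks for distillation (90 phantoms, 8 epochs),
96² for the modality comparison (500 phantoms, 5 seeds), 256² for
localization (100 phantoms) and fusion-recovery (20 depth-split phantoms)
studies.  They are the package's reference configurations, not tuning knobs:
enlarging them sharpens every measured effect.
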