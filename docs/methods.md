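# Methods

## Problem and model

Bright-field images of cultured cells (the motivating case is glioma
stem-cell cultures) are low-contrast, noisy, and crowded: cells span
roughly an order of magnitude in diameter, adhere in clumps, and have
faint outlines. The package segments every cell instance in such an image
and derives two culture-state indicators: confluence (percentage of the
image covered by the union of instance masks — overlapping pixels counted
once) and cell count (instances surviving suppression).

The segmentation network is a single-stage detector with prototype masks.
A cross-stage-partial backbone with an SPPF block produces features at
strides 8/16/32; a PAN-style neck fuses them top-down and bottom-up; a
decoupled head predicts, per cell of each pyramid level, a 16-bin discrete
distribution for each box side (decoded to an extent by softmax
expectation), a class score, and 32 mask coefficients. Instance masks are
sigmoid-activated linear combinations of 32 shared prototype maps at a
quarter of the input resolution, cropped to the box and thresholded at
0.5. Four variants form an ablation ladder: plain concat fusion with hard
NMS (`baseline_s_seg`); the same network scored with Gaussian Soft-NMS
(`plus_softnms`); weighted bidirectional fusion in the neck
(`plus_bifpn_softnms`); and additionally adaptive-kernel convolutions in
the neck (`akb_full`).

## Reconstruction choices pinned by parameter counts

The neck wiring of the published variants is shown only as a block
diagram, so the reconstruction is disciplined by the published parameter
counts. Three choices follow from them:

* **Weighted bidirectional neck.** Concat fusion nodes become per-edge
  learnable fast-normalized weights (rectified, ε = 1e-4), and the middle
  bottom-up node gains a same-level skip edge from the backbone, making it
  the three-edge fusion characteristic of bidirectional pyramids. This
  adds 65.5 K parameters (the widened node projection) plus nine scalar
  weights: 11.856 M total, about 0.7 % above the baseline's 11.790 M.
* **Adaptive-kernel substitution.** Replacing a whole cross-stage block
  with one AKConv at equal channel widths would *increase* parameters at
  the wide neck nodes (AKConv(768→256, N=3) costs 632 K against the
  block's 591 K), contradicting the published reduction. The reading
  consistent with the numbers replaces the 3×3 convolutions inside the
  neck blocks and the two strided neck downsamplers with AKConv (N=3,
  bias-free): −1.637 M parameters, i.e. 10.219 M total and a 13.8 %
  reduction relative to the weighted-fusion variant.
* **Single bidirectional pass.** Stacking further bidirectional repeats of
  the full-width neck would add ~3.2 M parameters per repeat, which no
  published count accommodates; the assembled model therefore defaults to
  one pass (`bifpn_layers=1`), and additional repeats are supported as
  lightweight depthwise-separable pyramid layers appended after the neck.
  The standalone `bifpn` module keeps the conventional five-repeat default.

Parameter accounting treats suppression as parameter-free, counts
trainable scalars only (the fixed expectation vector of the box decoder is
not trainable), and is checked against closed-form expressions: an AKConv
layer holds `C_in·k²·2N + C_in·N·C_out + 2·C_out` parameters — affine in
N — while a square convolution grows quadratically in its kernel size.

## Training objective and assignment

The objective is the plain printed form: mean two-class cross-entropy on
cell/background scores over every pyramid cell; coordinate squared error
on decoded, normalized (cx, cy, w, h) boxes over positive cells, scaled by
λ_cor (the trainer sets λ_cor to 1/#positives so batches of different
density are comparable); and mean binary cross-entropy between assembled
mask probabilities and the instance raster, evaluated inside the
ground-truth box region at prototype resolution. The total is a weighted
sum; term weights default to 1. The squared-error form is the default box
objective; a complete-IoU alternative (overlap, center-distance and
aspect terms) is selectable via `box_form="ciou"` for experiments, with
no claim about which form the headline results were trained with.

Assignment is a documented center-based rule: an instance is routed to the
pyramid level whose stride is closest (in log2) to a quarter of its longer
side; cells whose centers fall inside the ground-truth box shrunk to 60 %
(always including the center cell) are positive, larger instances being
assigned first so that smaller ones win conflicted cells. Probabilities
are clipped to (1e-7, 1−1e-7) before logarithms.

## Numerical and engineering choices

* **Autodiff engine.** All trainable components run on a small float32
  reverse-mode engine over numpy (im2col convolution, transposed
  convolution, max-pooling, nearest upsampling, batch normalization,
  bilinear grid sampling with gradients to both features and sampling
  positions). Gradients are verified against central finite differences in
  the test suite.
* **Batch normalization.** Running statistics store the *biased* batch
  variance, and training ends with a re-estimation pass over the training
  images using a cumulative moving average (momentum 1/t). Rationale:
  per-layer normalization mismatches between train-mode (batch statistics)
  and eval-mode (running statistics) are amplified multiplicatively
  through the deep stack; with exact re-estimation, eval-mode inference
  reproduces train-mode behavior to float precision on the training
  distribution.
* **Box decoder initialization.** The final bias of each 16-bin side
  distribution is initialized to −0.35·bin, so the initial expectation
  sits near 1.5 cells instead of the uniform-softmax midpoint; class
  towers start at a rare-positive prior (bias −4). Both measurably speed
  up convergence on small objects.
* **Soft-NMS.** Decay applies only when IoU ≥ N_t (the piecewise printed
  rule; some variants decay all boxes). Defaults: N_t = 0.5, σ = 0.5,
  final-score floor 0.001. Ties are broken by score, then lexicographic
  box coordinates, making the output order-invariant. In the σ → 0 limit
  the keep set equals classical NMS, which the suite asserts on random
  instances. The confidence threshold of `predict` is applied to
  post-decay scores as well, so soft-suppressed duplicates do not inflate
  instance counts.
* **CLAHE.** The clip limit is a multiple of the uniform bin height
  (tile_area/256); clipped mass is redistributed uniformly; tile mappings
  are blended bilinearly; images are reflection-padded to a whole number
  of tiles. RGB images are equalized on a luminance channel. With one tile
  and an unbounded clip limit the operation reduces to global histogram
  equalization, which is pinned against a direct CDF-mapping oracle.
  Enhancement is applied identically to training and inference images.
* **Gaussian blur** uses a finite-support sampled kernel
  (`exp(−(dx²+dy²)/2σ²)`, normalized) with mirrored borders; the default
  σ is derived from the kernel size (0.3·((k−1)/2 − 1) + 0.8).
* **Letterboxing** pads with mid-gray (114/255) and keeps float precision
  end to end; boxes and masks are mapped back to the original frame and
  clipped to its bounds.

## Synthetic scenes

The generator emulates the four stresses of dense stem-cell imagery:
irregular outline (deformed ellipses with low-frequency radial
perturbation, amplitude 0.12), dense adhesion (with probability 0.3 a cell
is placed touching or overlapping a neighbor), multi-scale size spread
(log-uniform radii, default 4–40 px at 640², about the order-of-magnitude
spread of 10–100 μm cells under a 20× objective; no physical calibration
is claimed), and unclear outlines (boundary blur σ = 1.5 px, foreground
contrast 0.25 on a 0.55 background with a mild illumination gradient and
Gaussian noise σ = 0.03, optional Poisson shot noise). Masks and polygons
are recorded before blur and noise, so the ground truth is unambiguous,
and the scene's analytic coverage equals the union of its masks. Scenes
are fully determined by the seed. What the generator does *not* model:
optical point-spread functions, debris and out-of-focus artifacts, tiled
acquisition, and the morphological diversity of real cultures — passing
tests on synthetic scenes demonstrate that the pipeline is implemented
correctly and can learn, not that trained weights transfer to microscopes.

## Desk-scale protocol

Full-scale training defaults follow the standard recipe (640² inputs,
batch 16, 200 epochs, SGD with momentum 0.9, learning rate 0.001, weight
decay 5e-4). The tested end-to-end runs use a deliberately small
configuration chosen to fit single-CPU numpy execution: the `akb_full`
topology at width multiple 0.125 (≈ 0.95 M parameters), 128² inputs, 200
training scenes with well-separated cells, batch 8, 10 epochs, learning
rate 0.02, box-term weight 7.5. Under that protocol held-out box/mask
mAP50 reaches ≈ 0.95/0.98; the acceptance threshold is 0.8. A model
overfit on a single scene recovers all of its instances at IoU ≥ 0.5.

## Known limitations

* Scores are localization-unaware (plain cross-entropy targets), so
  adjacent cells can yield confident near-duplicate boxes below the
  suppression overlap threshold early in training; counting therefore uses
  a stricter confidence threshold (0.5) than detection.
* Mask quality is bounded by the quarter-resolution prototypes; very small
  cells lose boundary detail.
* The FLOP estimate counts convolution multiply-accumulates only and is
  convention-dependent; it is informational, not a tested surface.
* The engine is single-threaded numpy; full-width 640² training is out of
  its intended scope.
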