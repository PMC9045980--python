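# Methods

## The segmentation problem

Breast tumors in axial DCE-MRI slices occupy a tiny fraction of the image;
the chest wall, background tissue and the breast itself dominate. Two
consequences drive the design of this package: (i) a single network wastes
capacity rejecting background structures, and bright non-breast tissue it
never saw in training produces false positives; (ii) pixel-wise losses that
weigh all pixels equally barely feel a small lesion. The framework answers
(i) with a two-stage cascade — segment the breast region of interest (ROI)
first, blank everything outside it, then segment the tumor inside — and
(ii) with the Tversky loss, an asymmetric generalization of Dice.

## Networks

Both stages are five-stage encoder/decoder networks at **half the classic
U-Net width**: the encoder channel ladder is `base × (1, 2, 4, 8, 16)`,
i.e. 32–512 at the reference width (`base = 32`) against the classic
64–1024. Downsampling is 2×2 max pooling (four times — inputs must be
divisible by 16), upsampling is a 2×2 stride-2 transposed convolution, and
skip connections concatenate encoder and decoder maps of equal spatial
size. Every convolution block is conv → group normalization → PReLU; the
head is a 1×1 convolution to two classes with a per-pixel softmax
(channel 0 = foreground).

Choices that the architecture leaves open, and how this package resolves
them:

* **Group count for GN**: `min(8, C)`, falling back to a single group when
  `C` is not divisible. GN (rather than batch norm) keeps normalization
  statistics independent of the batch, which matters at batch size 4.
* **PReLU**: one learned slope per channel, initialized at 0.25; weights
  use He fan-in initialization with the PReLU gain `sqrt(2 / (1 + a²))`.
* **Padding**: zero padding sized `d(k−1)/2` so every convolution —
  dilated ones included — preserves spatial size.

### Dense residual module (stage-2 encoder)

Encoder stages 2–5 (the fifth being the bottleneck) end in a dense
residual module: three residual units with 3×3 convolutions dilated at
rates (1, 2, 3). A dilated kernel spans `k + (k−1)(d−1)` pixels
(3 → 3, 5, 7), so the cascade widens the receptive field without extra
parameters; because the rates increase stepwise, the union of taps is a
contiguous, hole-free square — the test suite asserts this on the gradient
footprint. Each unit squeezes `N → N/2` channels with a 1×1 conv block,
applies the dilated 3×3 block at `N/2`, and restores `N` channels with a
1×1 convolution followed by GN only. The unit output is
`x_{t+1} = PReLU(x_1 + … + x_t + x_t³)`: all *earlier unit inputs* are
accumulated (dense connectivity inside one module; the sums never span
encoder stages). The module output feeds both the pooling path and the
skip connection.

### Recurrent attention module (stage-2 decoder)

Each decoder stage concatenates the upsampled map with the skip connection
(2N channels) and passes it to a recurrent attention module. A first conv
block halves the channels to N; then for `l = 1 … L` (default `L = 2`):

1. global max pooling compresses the map to one value per channel;
2. a GRU (input N, hidden N/2, hidden state initialized to zero) updates
   its hidden state from the pooled vector — the hidden state carries
   attention information across iterations;
3. the hidden state is mapped to N per-channel weights
   `α ∈ (0,1)^N` by a **learned linear projection followed by a sigmoid**;
4. the stage output is `y_l = PReLU(x_l + x_l ⊙ α_l)` (channel-wise
   multiply with a residual shortcut); iterations beyond the first feed
   `y_{l−1}` through a channel-preserving conv block.

The projection-plus-sigmoid in step 3 is a package decision: the attention
weights must match the N-channel map they multiply, and the sigmoid bounds
multiplicative gains; a parameter-free broadcast of the N/2 hidden state
would leave the product ill-typed. Feeding `y_{l−1}` (not `x_{l−1}`) to
later conv blocks is likewise a resolved ambiguity.

The stage-1 ROI network is the same U-Net skeleton (PReLU/GN, half width)
without dense residual or attention modules.

## Objective

With lesion/non-lesion probabilities `p0, p1` and one-hot ground truth
`g0, g1`, the Tversky index over a slice's pixels is

    T(α, β) = Σ p0·g0 / (Σ p0·g0 + α·Σ p0·g1 + β·Σ p1·g0)

and the loss is `1 − T`. Defaults **α = 0.3, β = 0.7** penalize false
negatives more than false positives, trading precision for sensitivity on
imbalanced data; `α = β = 0.5` recovers soft Dice exactly. Numerical
choices: a smoothing constant of 1e-6 in numerator and denominator guards
lesion-free slices; the loss is computed per slice and averaged over the
batch so small lesions are not swamped by large ones sharing a batch.

## Training protocol

Adam (lr 1e-3, β = (0.9, 0.999), ε = 1e-8) wrapped by Lookahead with
k = 5, α_slow = 0.5: every five inner steps the slow weights move halfway
toward the fast weights and the fast weights restart from them. Batch
size 4; slices are z-scored per slice before stage 1 and re-standardized
after ROI masking before stage 2. Stage-2 training uses ground-truth ROI
masks (teacher forcing) by default; training on stage-1 predictions is
available. All randomness (init, data order, augmentation) derives from
one seed, so a (config, seed) pair reproduces a checkpoint bit-for-bit.
When a validation set is supplied, the best-validation-DSC epoch is kept.

The networks and optimizer run on a compact reverse-mode autodiff engine
over numpy arrays written for this package (`raunet._tensor`,
`raunet._nn`), with fused convolution / transposed-convolution / pooling /
group-norm / PReLU kernels; its gradients are finite-difference-checked in
the test suite to ~1e-6 relative error.

## ROI application

Between the stages the ROI can be applied two ways (`RoiApplication`):

* **mask** (default): pixels outside the thresholded ROI — dilated by a
  Euclidean margin, default 16 px, echoing the practice of extending the
  breast area toward the chest so no tumor is cut off — are set to the
  median outside intensity, and the slice is re-standardized. Geometry is
  preserved, so predictions map back to the original frame trivially.
* **crop**: the bounding box of the dilated ROI plus margin is cropped,
  edge-padded to a multiple of 16, and the transform recorded so
  predictions are inverse-mapped exactly.

An empty ROI prediction falls back to the whole slice with a warning; a
case is never silently dropped.

## Evaluation

Ratio metrics from pooled confusion counts: Jaccard, DSC, sensitivity,
specificity, positive predictive value, accuracy. The Hausdorff distance
is the symmetric max-of-directed-max Euclidean distance between the two
**full foreground pixel sets** (not boundaries), in pixel units, computed
via exact distance transforms and cross-checked in tests against both a
brute-force double loop and an independent point-set implementation.
Aggregation (mode `case`, the default) pools counts over a case's slices,
takes the worst per-slice HD, and averages unweighted over cases; a
per-slice macro mode exists. Empty-foreground convention: both masks
empty → overlap metrics 1 and HD 0; exactly one empty → ratios 0 and HD
undefined (NaN, excluded from means with a logged count).

## Synthetic phantoms

Clinical data being private, the generator builds what the method needs
and nothing more: two half-disk "breasts" (20–60% of the image) bulging
from a bright chest band on a dark background, Gaussian-blurred noise
texture, and one elliptical lesion per case occupying < 10% of the breast.
Two morphologies mirror the clinical dichotomy: **mass** lesions are
sharp, high-contrast ellipses; **nonmass** lesions threshold smoothed
noise inside the ellipse and blur the rendered intensity (σ = 2 px), so
their boundary gradients are strictly lower at equal nominal contrast.
Defaults: 128×128 slices (512×512 supported), 3 slices per case with
ellipsoid-like radius modulation along the stack, lesion contrast 0.4,
noise σ = 0.04, lesion semi-axis 4–8% of the image side. Optional bright
distractor blobs outside the breast emulate confounding background
tissue. Augmentation (mirroring, central scaling, elastic deformation via
a Gaussian-smoothed random displacement field; bilinear for images,
nearest-neighbour for masks) can expand a training set by a configurable
multiplier (default ×4 in `expand_with_augmentation`; the training
fixtures use ×1 since generated phantoms are already diverse).

What the phantoms do **not** emulate: contrast-agent kinetics, scanner
physics (coil profiles, bias fields), anatomical texture of real breast
tissue, or inter-reader label noise. Passing tests therefore demonstrate
that the implementation learns and evaluates correctly under controlled
conditions — not clinical-grade performance.

## Problem sizes

The tested desk-scale study uses 40 training cases (2 slices each) at
128×128 with base width 8, 30 epochs, batch 4 — about 600 optimizer
steps — plus two held-out sets of 8 cases: one in-distribution, one with
distractor blobs absent from training. Training data contain no
distractors, so the distractor set probes exactly the robustness the
cascade is meant to buy; under this shift the single-stage model's DSC
drops far more than the cascade's. `scripts/acceptance.py` repeats the
study at 32 training cases and 25 epochs. The paper-scale profile
(512×512, base 32, 200 epochs, ≈8.5× augmentation) is expressible through
the same configs but is not exercised by the test suite.

## Known limitations

* 2-D slices only; no 3-D context beyond per-case mask stacking.
* Single-threaded CPU training: practical at desk scale, not at
  paper scale.
* The attention projection and the ROI-application mode are package
  resolutions of genuinely open design points (see above); alternatives
  (broadcast attention, crop-based stage 2) are exposed but less tested.
* Checkpoint selection uses a small validation set; with few cases the
  selected epoch is noisy.
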