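# Methods

This note documents the model, the training and evaluation procedures, the
synthetic benchmark, and the numerical/design choices behind `uniland`.

## Problem setting and assumptions

The package detects 2D anatomical landmarks in grayscale radiographs from a
*fixed, registered* set of anatomies (domains). Each domain `i` declares its
landmark count `C'_i`, working resolution `(W_i, H_i)` (divisible by 16, as
the encoder halves resolution four times), and a spacing convention:
`fixed_mm` (calibrated acquisition, e.g. 0.1 mm/px cephalograms), `pixel`
(uncalibrated; errors stay in px), or `wrist_width_mm` (per-image isotropic
spacing `s = 50 mm / ‖a − b‖₂` from two wrist landmarks — the standard hand
radiograph convention when DICOM spacing is absent). An image from an
*unregistered* anatomy is rejected: the model holds no domain-specific
parameters for it, so it cannot produce meaningful output — a structural
property, not a recoverable error.

Coordinates are 0-based with x = column, y = row and pixel centers at
integer positions; everything (files, heatmaps, metrics, augmentation) uses
this one convention. Resizing maps `x → x·W_new/W_old` and rescales spacing
by the inverse factor, so physical distances are exactly preserved;
anisotropic stretch is allowed and radial errors later apply spacing per
axis before the norm. For wrist-calibrated domains the spacing is computed
from the coordinates in whatever frame the sample currently is — the two
definitions are self-consistent under resize.

## Heatmap codec

A landmark is encoded as `Y(x) = γ/(2πσ)·exp(−‖x − c‖²/2σ²)` evaluated at
pixel centers, σ = 3 px, γ = 2πσ so the printed prefactor is 1. Two
details:

* **Integer-pixel targets.** Training targets center the Gaussian on the
  nearest integer pixel (`center="round"`), so the channel maximum is
  exactly 1 at that pixel even for fractional annotations; `center="exact"`
  is available for sub-pixel encodings. Decoding is plain per-channel
  argmax anyway (ties → first position in row-major order), so either
  choice round-trips within 0.5 px per axis. No sub-pixel peak refinement
  is applied.
* **No cross-channel interaction.** Channels are independent; overlapping
  Gaussians of nearly coincident landmarks are neither clipped nor
  renormalized.

Local and global predictions are fused by element-wise multiplication; with
both branches sigmoid-squashed into (0, 1), the product stays in (0, 1).

## Architecture

**Local branch.** A U-Net-shaped trunk whose convolution unit is
depth-wise separable with the split that makes multi-domain routing work:
domain-specific channel-wise 3×3 (grouped convolution, groups = channels,
no bias) → domain-specific batch norm → leaky ReLU (slope 0.1) → shared
point-wise 1×1 (with bias) → shared batch norm → leaky ReLU. Normalization
that sits inside the domain-specific sub-block is replicated per domain so
running statistics never mix across anatomies; normalization after the
shared 1×1 is shared. Encoder levels use two such units per resolution
(widths 64/128/256/512 by default), 2×2 max pooling between levels, a
double-unit bottleneck capped at the deepest width, nearest-neighbor ×2
upsampling with skip concatenation, and a *single* unit per decoder level.
Per-domain 1×1 heads map the finest features to `C'_i` channels through a
logistic sigmoid (the squashing keeps the cross-entropy well defined; the
final activation is otherwise unconstrained by the architecture).

**Global branch.** Per domain: the image and the local heatmap are
bilinearly downsampled ×4, combined by channel concatenation (`cat`, the
default) or by addition after a per-domain 1×1 projection (`add`), then
passed through five dilated 3×3 convolutions with dilations (1, 2, 5, 2, 1)
— receptive field 23×23 at quarter resolution, ≈ 92×92 px at full
resolution — each followed by batch norm and plain ReLU except the last,
which maps to `C'_i` channels, is sigmoid-squashed, and bilinearly
upsampled ×4.

**Parameter budget.** A separable block with t domains, N in- and M
out-channels has `9tN + NM` convolution weights versus `9tNM` for t
standard convolutions. With the default widths, double-conv encoder,
single-conv decoder and global width 160, the four-anatomy model totals
5.04 M trainable parameters — by design about one third of the
standard-convolution U-Net baseline (16.46 M) built at the same widths with
one shared trunk and a single head over the union of all landmark channels.
The encoder/decoder block layout and the global width are the calibrated
quantities here; both are config-exposed.

**Ablation variants.** `local_only` (global map ≡ 1), `global_only` (no
local branch; the global branch receives an all-ones heatmap, and the model
then holds only domain-specific parameters), `unet_baseline` (standard
convolutions, all parameters shared).

**Parameter partition and exchange.** Every parameter is tagged shared or
domain-`i` at construction; `partition_params` verifies the partition is
disjoint and exhaustive. `swap_domain_params(i, j)` exchanges the private
sets (including batch-norm running statistics); sites whose shapes differ
between the domains — the heads and the global branch's first/last
convolutions when landmark counts differ — are excluded and reported, or
raise under `strict=True`. Swapping twice restores the model bit-exactly.

## Training

* Loss: soft-label binary cross entropy on the **final fused** map, summed
  over pixels and channels, averaged over the batch. Predictions are
  clamped to [1e−6, 1 − 1e−6] before the logs, with zero gradient where
  the clamp is active. Auxiliary supervision of the local/global maps
  exists behind `aux_supervision` but is off by default.
* Optimizer: Adam (β = 0.9/0.999), batch size 4, up to 100 epochs.
* Learning rate: cosine-shaped cycles (default cycle length 10 epochs)
  whose amplitude decays linearly from 1e−2 to 1e−4 across the run — the
  trace starts at 1e−2 and ends at 1e−4. The cycle shape and length are
  package choices; only the endpoints and the cyclic decay are fixed by the
  recipe.
* Mixed-domain sampling: each batch is homogeneous in domain; the batch's
  domain is drawn with probability proportional to training-set size, and
  per-domain shuffled queues make every image appear once per epoch in
  expectation. Homogeneous batches are what make per-sample routing and
  per-domain batch-norm statistics well defined; within-batch mixing is
  deliberately not implemented.
* Augmentation (on the fly): with probability 0.1 a rotation uniform in
  [−2°, +2°] about the image center, and with probability 0.1 an integer
  translation uniform in [−10, +10] px per axis. Landmarks follow the same
  rigid map; targets are re-encoded from the transformed landmarks, never
  warped. Draws that push a landmark out of frame are re-drawn (bounded
  retries, then identity). Images are z-scored per image (constant images
  → zeros) before entering the network.
* Model selection: pooled (sample-weighted) validation loss each epoch;
  the returned model is the epoch-argmin snapshot. If no validation sets
  are supplied, 10% of each domain's training list is held out
  deterministically by seed. A non-finite training loss aborts the run and
  restores the last finite best snapshot.
* Determinism: all randomness flows from one integer seed through
  `numpy.random.Generator`; repeated runs in the same environment are
  bit-identical.

## Evaluation

Radial error per landmark is `‖(Δx·s_x, Δy·s_y)‖₂`; MRE pools all
(image, landmark) pairs of a test set (matching the flat indicator sum in
the SDR definition), STD is the population standard deviation, and SDR(k)
counts errors **strictly** below k, in percent — an error exactly at the
threshold does not count. Default reporting grids: (2, 3, 4) mm for the
head domain, (2, 4, 10) mm hand, (3, 6, 9) px chest/pelvis. Mixed-dataset
pooling concatenates per-pair errors and therefore equals the
sample-weighted average of per-domain results. `cross_anatomy_matrix`
evaluates every (private-parameters-from-i, test-set-j) pairing via
swap/evaluate/swap-back; `domain_count_sweep` trains on every s-sized
domain subset containing a probe domain and averages the probe's metrics
over subsets.

## Synthetic benchmark

Four parametric shape families stand in for the four X-ray anatomies:
`ellipse_ring` (5 landmarks: axis endpoints + center), `digit_fan` (9: base,
4 finger tips, 4 midpoints), `twin_lobes` (5: lobe centers, outer extremes,
midpoint), `arch_pair` (6: arc endpoints + apexes). Landmarks are defined
*analytically on the geometry before rasterization* — ground truth is exact
and never derived from the rendered image. Each sample applies a similarity
jitter (scale ±10%, rotation ±10°, translation ±3 px), a random linear
illumination ramp (±0.08), and additive Gaussian intensity noise
(sd 0.05 on a [0, 1] scale); jitters that would put a landmark within 2σ
(6 px) of the border are re-drawn. Randomness is counter-based — sample
`k` of a domain is a pure function of (domain seed, k) — so benchmarks
regenerate bit-identically and out of order.

The default benchmark has three domains (5/9/5 landmarks) at 64×64 px with
200/20/40 train/val/test images each: the smallest configuration that keeps
σ = 3 heatmaps well resolved, exercises unequal per-domain heads *and*
contains an equal-count pair for the full parameter-exchange experiment,
while training in CPU-minutes. What passing on it shows — and does not
show: the generator produces exactly one bright figure per image with
moderate pose variation and homogeneous noise, so success demonstrates the
mechanics of multi-domain routing, shared-parameter learning and the
metric/codec pipeline, not robustness to the pathology variation, occlusion,
exposure differences and annotation noise of clinical radiographs. The
experiment scale used in the acceptance tests (reduced widths 16/32/64/128,
global width 40, 20 epochs, seed 7) was chosen as the smallest budget at
which held-out performance saturates well below the 3 px bar.

## Numerical choices

* float32 throughout; the loss and its gradient accumulate in float64.
* Bilinear resize is implemented as separable row/column interpolation
  matrices (half-pixel-center convention), so its adjoint (used in
  backprop through the global branch's down/upsampling) is the exact
  transpose. ×4 bilinear *sub*sampling uses 2-tap interpolation, i.e. it
  aliases like the common framework implementations rather than
  area-averaging.
* Batch norm: momentum 0.1, eps 1e−5, population variance in the batch
  statistics; evaluation always uses running statistics.
* Max-pool ties and argmax ties both resolve to the first position in scan
  order.
* Weight init: Kaiming-normal scaled by fan-in; biases zero; all from the
  config seed.
* The bandwidth-bound inner loops (depthwise 3×3, leaky ReLU, 2×2 pooling,
  fused batch norm) are numba-compiled with fixed sequential iteration
  order; GEMM-shaped work (1×1 convolutions, im2col 3×3) goes through
  BLAS.

## Known limitations

* CPU-oriented: practical for the synthetic benchmark and small studies;
  training on the full-resolution four-dataset X-ray corpus at 100 epochs
  is out of reach without a GPU framework backend.
* Landmarks are decoded at integer pixels (no sub-pixel refinement), so
  MRE has a floor of ≈ 0.38 px (mean rounding error) even for a perfect
  heatmap.
* One trunk requires all domains to share the input channel count (1 for
  radiographs).
* 2D only; no DICOM ingestion; unknown anatomies are rejected by design.
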