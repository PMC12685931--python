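# Methods

## Model

`icseg` implements a universal (in-context) segmentation model for 2-D
grayscale medical images. The unit of computation is an *episode*: one query
image plus `S` support pairs (image, binary mask) that define — by example —
what is to be segmented. Changing the support set changes the task without
retraining.

Four convolutional encoders share one blueprint (a simplified MSCAN): a
two-conv stem at output stride 2 followed by four stages at strides
4/8/16/32, each stage opened by a 3×3 stride-2 downsampler. The multi-scale
convolutional-attention branches of the original MSCAN are replaced by 1×1
pointwise mixers, and all FFN kernels are 1×1 except a single 3×3 depthwise
convolution in the first block of each stage. This fixes the theoretical
receptive field after stem/stages 1–4 at 7/19/43/91/187 px — 2.7%, 7.4%,
16.8%, 35.5% and 73.0% of a 256-px axis — *independently of depths and
widths*, because only the stem convs, the downsamplers and the one depthwise
conv per stage have spatial extent. The small field of view is intentional:
feature vectors describe their immediate neighbourhood, which keeps the
attention maps spatially specific and readable as explanations.

The encoders are:

- **Segmentation Encoder** — query image; skips at strides 2–32.
- **Support Set Encoder** — support image and mask concatenated channel-wise
  (shape `(S, 2, H, W)`); the *only* pathway by which mask information can
  reach the prediction.
- **Attention Mapper Encoder** — query image, strides 8/16/32.
- its **EMA twin** — support images only, updated per optimizer step as
  `shadow ← β·shadow + (1−β)·online` with β = 0.999; it receives no
  gradients. Using a slow-moving teacher on the support side prevents the
  attention from collapsing onto a single fixed key.

The **Cross Attention Mapper** relates the coarsest (stride-32) query and
support features through a one-head attention softmax

    A_i = softmax( x_iᵠ W_Q W_Kᵀ [Xˢ, tˢ]ᵀ / (δ·T) )[: S·H·W]

with δ = 0.1·d and a learnable temperature T. A handful of learnable
*registry tokens* tˢ (4 by default) are concatenated to the support keys and
their softmax mass is discarded, so a query location with no good match in
the support set can park probability "nowhere" — each retained row then sums
to ≤ 1. Masks never enter this computation, so a computed map can be reused
when re-targeting the same images to a different structure.

The **Attention Upsampler** doubles the resolution of an attention map
without recomputing attention (whose cost is quadratic in H·W): (1) per-row
attention mass; (2–3) separable interpolation of the support and query axes
with a learnable mix `c·nearest + (1−c)·bilinear`; (4) row renormalization
to the upsampled mass; (5) refinement of only the top-K support locations
per row by a small FFN on (attention value, query feature, support feature),
`A_ij ← A_ij · (1 + ELU(y))`; (6) renormalization again. K quadruples per
stage; the inference default of base K = 8 yields 32 refined locations at
stride 16 and 128 at stride 8. Non-top-K entries keep their interpolated
values — low-similarity pairs are unlikely to change ranking when the scale
doubles, which is what makes the sparse refinement safe.

The **decoder** has five residual stages plus a head: stage 1 fuses at
stride 32 with the coarse map; stages 2–3 upsample the attention map and
fuse at strides 16/8; stages 4–5 use query skips only; the skip-free head
restores full resolution and applies a 1×1 sigmoid projector. Support
features enter exclusively through Provided-Attention blocks
`x_iᵠ += (A_i·Xˢ)W_p + b_p`. Query features are upscaled between stages by
3×3 stride-2 transposed convolutions (implemented as zero-stuffing followed
by a 3×3 convolution, equivalent to output-padding-1 transposed
convolution).

## Numerical and initialization conventions

- All LayerNorms are plain z-scores over (channel, height, width) jointly,
  per sample, ε = 1e-6, without affine terms — every skip connection is
  therefore exactly normalized at emission.
- Identity-at-init: the last layer of every inner residual block, every
  Provided-Attention projection (W_p, b_p) and the refinement FFN's output
  layer are zero-initialized. A consequence worth knowing: at step 0 the
  attention pathway contributes nothing to the loss, so W_Q/W_K/tokens
  receive their first gradients at step 1, after W_p has moved off zero.
- Positivity by parametrization: T = exp(τ) (τ init 0 → T = 1);
  c = logistic(u) (u init 0 → c = 0.5, unbiased between nearest and
  bilinear).
- Top-K ties break toward the lower flattened support index (stable sort),
  for exact reproducibility. Flattening is row-major over (H, W) with
  support examples concatenated in order.
- Zero-mass attention rows are left exactly zero by every renormalization
  (no division); K is clamped (with a warning) when it exceeds the number
  of support locations.
- The backbone is plain NumPy differentiated by `autograd`; convolutions are
  im2col gather + matmul, interpolation is multiplication with precomputed
  1-D interpolation matrices (half-pixel convention), and the top-K
  refinement scatter is a custom primitive whose VJP is the corresponding
  gather.
- Images are min-max normalized to [0, 1] and resized bilinearly; masks are
  resized nearest-neighbour and binarized at 0.5. For multi-label ground
  truths, the binary task mask is `label == view_id`; masks under 10 px are
  rejected at load time.

## Presets and parameter budget

`tiny` (depths [1,1,1,1], widths [8,16,24,32]; ~146k parameters in the full
model) exists for CPU-scale training and tests at 64×64 geometry — all
stride arithmetic scales, the coarse grid is `size/32`. `full` (depths
[3,3,5,2], widths [52,104,208,416]) puts the full model at ≈25.5M
parameters; the depths are a free choice (the receptive field does not
depend on them) and the widths were tuned once to land near a 25M budget.
FFN expansion is 4, as in the MSCAN blueprint being simplified; narrowing
it to 2 measurably kills the support pathway (see below).

## Training

Loss = 1.0 · squared-denominator DICE (`1 − 2Σpt/(Σp² + Σt²)`) + 0.25 ·
pixel-mean BCE. AdamW (decoupled weight decay), one episode per step.
Full-scale defaults: 155k steps, base LR 1e-4 halved at 75k/100k, weight
decay 1e-3, S = 16, upsampler top-K 5 until step 125k then 24, validation
every 5k steps, early-stopping patience 5 rounds.

Augmentations (each firing independently, default p = 0.25 per episode):
h/v flips, rotation ±30° (bilinear image / nearest mask), contrast gamma in
[0.7, 1.4], intensity flip 1−x, Gaussian blur σ ∈ [0.5, 1.5] px, Gaussian
noise σ ∈ [0, 0.05], and mask-edge (all episode targets replaced by their
1-px inner boundary band, mask − erosion with a 3×3 element). Geometric
transforms use identical parameters across the whole episode so query and
support semantics stay aligned.

### Desk-scale recipe

The CPU-scale recipe used by the tests and examples
(`desk_train_config` / `desk_episode_stream`): tiny preset, 64×64, 2000
steps, base LR 3e-3 halved at 75%/92.5% of the run, weight decay 1e-4,
top-K 5 then 24 from 80% of the run, support size drawn from {4, 8, 16}
per episode, *no augmentation* (the augmentation set earns its keep over
long schedules; inside a 2k-step budget it slows convergence — a quarter
of episodes would train on boundary-band targets alone). These sizes are
the package's own desk-scale choices, not claims about the full-scale
configuration.

Two desk-scale findings shaped this recipe, both observed on trained runs:

- **Registry-token attention sink.** At 64×64 the coarse attention grid is
  2×2, so a handful of registry keys compete against only 4·S support keys.
  Whenever episodes that *require* reading the support set enter training,
  the optimizer prefers silencing the (initially noisy) support pathway by
  parking essentially all of the attention mass on the registry tokens,
  after which the pathway is dead and cannot recover. The
  desk recipe therefore trains with zero registry tokens (the count is a
  config knob; the default model keeps 4 and the full behaviour is
  unit-tested). At the reference 256-px geometry's 8×8 grid the sink has 16× more
  competition and long schedules to recover in; we have not trained the
  full-scale configuration, so this is reported as a desk-scale pathology.

- **Appearance shortcuts vs conjugate tasks.** If every task's appearance
  uniquely determines its target, a model can segment correctly while
  ignoring the support set entirely (replacing the whole support set then
  barely perturbs the output). The episode stream therefore
  mixes in *conjugate* tasks — the same scenes with target and decoy
  families swapped — after a 700-step warm-up: they are unsolvable without
  reading the support masks. Conjugates are restricted to visually distinct
  family pairs (disk↔blob-union is excluded as near-degenerate), and the
  warm-up is required (from step 0 they trigger the registry sink above).

## Synthetic episodes

A task couples a shape family (disk, rectangle, ring, blob-union,
thin-vessel) with an appearance model: background level U(0.15, 0.45),
signed foreground contrast ±U(0.2, 0.45), texture noise σ ∈ U(0.02, 0.06),
target size 10–22% of the image, a query-vs-support target offset budget of
up to 5–30% of the image (so attention must act globally), and 0–2 decoy
shapes from a *different* family rendered at the same foreground intensity.
The decoys are the point: intensity alone cannot identify the target, so
the model must read the support masks — the in-context premise. Every mask
covers ≥ 10 px (undersized draws are resampled). Held-out tasks are
generated disjointly from training tasks and never enter a training stream
(enforced).

What the generator does not emulate: real anatomy, imaging physics,
partial-volume effects, annotation noise, 3-D structure, or class imbalance
across organs. Passing desk-scale tests therefore demonstrates that the
architecture and training machinery work and that in-context conditioning
happens; it says nothing quantitative about performance on clinical data.

## Evaluation protocol

DICE = 2|P∩T|/(|P|+|T|) on masks binarized at 0.5; empty-vs-empty is
defined as 1, empty-vs-nonempty as 0. For every evaluation query a *fresh*
support set is resampled (no static-support bias). Aggregation is
two-level: queries → task mean → mean across tasks (and, as a second
aggregate, across shape families).

## Retrieval

The attention mapper doubles as a retrieval system. An index stores, for
every pool image and coarse-grid cell, the key-projected (W_K) EMA-encoder
feature; a query is embedded the same way at the cells containing points
sampled on the contour of a draft prediction (8 points by default).
Similarity is the normalized cross-correlation of the embeddings about the
index mean (centered cosine). Two failure modes dictate this choice, both
observed on trained models: raw dot products are won by a few large-norm
pool entries for *every* query, and the trained W_Q/W_K bilinear form —
tuned to rank keys within one episode's softmax — degenerates for
cross-image search, mapping nearly all queries onto the same few entries.
Centered correlation of same-projection embeddings restores well
above-chance cluster purity on two-appearance pools (the test suite checks
this). Pool images are ranked by match frequency,
ties by best similarity, padded by next-best similarity when fewer than S
distinct images are matched. The Monte-Carlo Δ-DICE experiment draws a labeled pool
(N) and queries (M) per task, fixes one random generic support set, and
measures the DICE increment per query from swapping to the retrieved,
query-personalized support set, averaged over queries, tasks and
repetitions (defaults N = 150, M = 100, 10 repetitions; the desk-scale
tests shrink all three). Contour points come from the *prediction* under
the generic support, not from ground truth — matching the intended use on
unlabeled queries.

## Known limitations

- CPU-only NumPy/autograd backbone: fine at the tiny/64×64 desk scale,
  roughly 0.2–0.3 s per training step; the full-scale configuration is
  expressible but not practical to train here.
- The receptive-field constants are fixed in *pixels* by the kernel layout,
  so at 64×64 they cover 11–100% of the image instead of 2.7–73%: the
  deliberately-local features the attention design relies on are much less
  local at desk scale, and the 2×2 coarse attention grid routes very
  coarsely. Desk-scale segmentation quality (mean held-out DICE around 0.7
  on the synthetic tasks, lower on families with same-intensity decoys or
  thin vessels) should be read with that distortion in mind.
- Single-head attention, no attention dropout, binary masks only, 2-D only.
- The `synth`-written PNG datasets quantize images to 8 bits; training
  streams generate episodes in memory at float precision instead.
- Empirical receptive fields are measured with normalization frozen, since
  LayerNorm statistics couple all positions with O(1/CHW) weights that a
  gradient-footprint test would otherwise pick up.
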