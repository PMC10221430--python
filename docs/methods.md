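# Methods

## Problem and overall design

`fundoseg` segments the optic disc (OD) and optic cup (OC) in fundus
photographs and derives the cup-to-disc ratio (CDR), the standard index of
glaucomatous cupping. The pipeline has five stages, each usable on its own:

1. **Label handling.** Ground truth arrives as a *combined* RGB mask:
   background black `[0,0,0]`, disc gray `[128,128,128]`, cup white
   `[255,255,255]`. A pixel is "object" when every channel is ≥ the
   corresponding threshold channel (default `[128,128,128]`); the
   channel-wise-AND reading makes the rule robust to anti-aliased labels.
   Splitting produces a **disc mask = gray ∪ white** (the cup sits on the
   disc, so white pixels are recolored gray) and a **cup mask = white
   only**. The alternative literal reading — recoloring gray pixels white
   for the cup — would make both masks identical and is rejected; cup ⊆
   disc is enforced as an invariant.
2. **Segmentation.** One binary U-Net per structure. Training cup and disc
   separately keeps the two targets from competing in a single softmax
   head and lets each model pick its own operating point.
3. **Evaluation.** Dice `2TP/(2TP+FP+FN)` and Jaccard `TP/(TP+FP+FN)` per
   image, averaged arithmetically over images (a pooled-pixel variant is
   available via a flag). The identity `DC = 2J/(1+J)` is asserted in
   tests to 1e-12. When both masks are empty both scores are defined as
   1.0 with a warning — agreement on absence — to keep NaNs out of means.
4. **Boundary visualization.** A staged Canny edge detector on each
   *predicted binary mask* (not the raw photograph), thickened by binary
   dilation and painted over the image (disc green, cup red; cup wins on
   overlap).
5. **CDR and staging.** Ratio of vertical diameters by default, with an
   area-based alternative `sqrt(|cup|/|disc|)`.

## Network and optimization

The U-Net is an encoder–decoder with skip connections: `depth` encoder
levels of two 3×3 same-padding convolutions + ReLU, channel width doubling
per level from `base_channels`, 2×2 max pooling between levels; a
double-convolution bottleneck; a mirrored decoder using 2×2 stride-2
transposed convolutions whose output is concatenated with the encoder
features of the same resolution; and a final 1×1 convolution + sigmoid to
one probability channel. Input sides must be divisible by `2^depth`.

The forward and backward passes are written directly in numpy (im2col
convolutions, exact-tiling transposed convolutions, argmax-routed pooling
gradients) with an Adam optimizer. This keeps CPU training bit-reproducible
for a fixed seed — there are no nondeterministic kernels — and the backward
pass is verified against central finite differences in the test suite.
`parameter_count` is a closed-form sum `k²·c_in·c_out + c_out` over all
(transposed) convolutions and is checked against brute-force enumeration of
the parameter arrays.

The loss is **soft Dice**, `1 − (2Σpt + ε)/(Σp + Σt + ε)` with `ε = 1e-6`,
computed per image and averaged over the batch; loss curves are plotted on
a log axis by convention. Reference optimization settings: Adam, learning
rate 1e-4, batch size 4, 300 epochs, with the best-validation-loss
parameter snapshot retained. He-normal weight initialization; no batch
normalization or dropout.

**Smoke profile.** All tests and the acceptance script use a scaled-down
profile chosen to keep a full run in CPU minutes: 120 scenes at 64×64, a
depth-2/base-8 network (29,465 parameters), batch 4, learning rate 1e-4,
with two seeded augmented copies of each training pair per the
augmentation protocol (more augmentation diversity measurably sharpens the
cup boundary at this scale). The cup model trains for 100 epochs; the disc
— a much easier, high-contrast target that converges early — for 50, which
keeps the full two-model run within CPU minutes. The architecture hyperparameters are configuration, not claims:
the default (depth 4, base 32, ≈1.9 M parameters) is one reasonable modified
U-Net; no specific published parameter total is targeted.

## Data handling

Images resize bilinearly, masks with nearest-neighbour (they must stay
binary); 8-bit images map affinely onto [−1, 1] (`x/127.5 − 1`) before
entering the network. Masks loaded from lossy formats are snapped to the
nearest canonical color within Chebyshev distance 16, anything farther is
an error naming the offending values.

The dataset split is a seeded shuffle followed by an 80-10-10 partition;
validation and test get `floor(0.1·n)` (at least 1) each and the remainder
goes to training, which favours the data-hungry stage and makes n=10 →
(8,1,1) and n=3 → (1,1,1).

Training augmentation applies crop and flips identically to image and
mask, and Gaussian blur to the image only (blurring a binary target would
corrupt it). The crop window side is drawn from a normal distribution —
mean 80 %, sd 10 % of the side, clamped to [50 %, 100 %] — then the crop is
resized back so batch shapes stay fixed; a degenerate window (≤ 8 px) is
re-drawn up to 10 times before falling back to no crop. The normal-window
parameters are exposed in `AugmentConfig` since no canonical values exist.

## Synthetic scenes

The generator renders the structure that matters for this pipeline: a
bright ellipse (disc) containing a brighter concentric ellipse (cup, with
vertical radius = `cdr_true` × disc vertical radius) on an orange
background, crossed by dark random-walk vessels, plus clipped additive
Gaussian pixel noise. Masks are rasterized from the same ellipses and are
noise-free, so the ground truth is exact by construction and the stored
`cdr_true` matches the mask-measured CDR to rasterization precision
(≤ 2/disc vertical diameter). Ellipses rather than circles are used so the
vertical-diameter CDR is genuinely distinct from an area ratio.

Randomness is counter-based: scene *i* derives from
`SeedSequence(dataset_seed, spawn_key=(·, i))`, so scene *i* is identical
whether 2 or 2000 scenes are generated.

What the generator does **not** model: photographic illumination and color
variation, camera blur, peripapillary atrophy, pathology other than cup
enlargement, and vessel-induced ambiguity of the true cup border. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
self-consistent, not that the smoke-scale network would reach the same
accuracy on clinical photographs.

## Edge detection

The five stages: (1) separable Gaussian blur, kernel truncated at 3σ
(default σ = 1.4); (2) 3×3 Sobel x/y gradients, magnitude and direction;
(3) non-maximum suppression against the two neighbours along the gradient
direction quantized to 4 bins, with **ties kept** (≥) so plateau ridges
survive; (4) double threshold at fractions of the maximum magnitude
(defaults 0.05 / 0.15) into strong and weak sets, with a small absolute
floor so float residue on constant images never fabricates edges; (5)
hysteresis as a full 8-connected flood fill — any weak pixel connected to a
strong pixel through weak/strong chains is promoted, independent of scan
order. σ and the thresholds have no canonical published values and are
exposed in `CannyParams`.

Dilation is binary dilation with a square structuring element (odd size,
default 3): each output pixel is the neighborhood maximum, so the output
always contains the input.

## CDR and staging

The vertical diameter of a mask is `max_row − min_row + 1` of its
foreground (0 when empty). The default CDR is cup/disc vertical diameter —
the clinical convention — with `area_sqrt` as an alternative; an empty disc
is an error, a cup not contained in the disc warns but still yields a
ratio. Staging: CDR < 0.4 → `normal`; 0.5 ≤ CDR ≤ 0.8 → `moderate`;
CDR > 0.8 → `severe`. The band [0.4, 0.5) is reported as `indeterminate`
rather than silently merged into a neighbour: clinically those eyes need
IOP or other tests, and the two published statements ("normal is < 0.5",
"< 0.4 indicates a normal disc") only coexist if the gap is kept explicit.

## Numerical choices and degenerate inputs

- Network arithmetic is float32; metric and loss reductions are float64.
- Max-pool gradients follow the argmax (first index on exact ties).
- One pipeline seed fans out to fixed-purpose sub-seeds (dataset, split,
  augmentation, disc model, cup model) through `SeedSequence` spawn keys,
  so runs are reproducible end to end and byte-identical on one CPU.
- Probabilities entering the loss are sigmoid outputs, strictly inside
  (0, 1), so no clipping is needed; ε guards empty-mask batches.
- `predict_mask` rejects inputs outside [−1, 1] (a common failure is
  passing raw 8-bit pixels).

## Known limitations

- CPU-only: no GPU path; the reference protocol (300 epochs, 128×128,
  depth 4/base 32) is hours on one CPU, which is why the smoke profile
  exists.
- Vertical-diameter CDR is sensitive to single-row prediction errors; at
  64×64 smoke resolution one pixel of cup boundary error moves the CDR by
  roughly 0.04, so prediction-based CDR accuracy is resolution-limited.
- No region-of-interest detection before segmentation and no polar
  transformation; the whole frame is segmented at model resolution.
- The empty-empty metric convention (score 1.0) is a choice; report means
  with care if a dataset contains images without the structure.
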