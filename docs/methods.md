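# Methods

This note records the modelling assumptions, parameter choices, and known
limitations behind `posekit`, in the order data flows through the pipeline.

## Coordinates and data model

Keypoint coordinates are (x = column, y = row), 0-based and continuous,
with the origin at the centre of the top-left pixel. Invisible keypoints
are stored as NaN mirrored by a boolean flag; this keeps arrays rectangular
and makes accidental use of a missing coordinate loud. The annotation
container is a single HDF5 file (`/images` uint8 N×H×W×C, `/keypoints`
float32 N×K×2 x-then-y, `/visible`, `/annotated`, skeleton CSV text as an
attribute), so a dataset is one portable file that carries its own skeleton.

A skeleton is a rooted tree: each keypoint names its parent (the root names
none or itself) and its bilateral mirror partner (itself if unpaired). The
swap relation must be an involution; the parent relation must be acyclic
with exactly one root. Both are validated at construction.

## Confidence-map encoding

Targets are Gaussians of amplitude 1 and scale σ (default 5 px in image
coordinates) rendered on a grid downsampled by the output stride s. The
map-grid ↔ image mapping is pure division by s — no half-pixel offset — so
encoding and subpixel decoding are exact inverses; this choice is what lets
the round-trip tests demand quarter-pixel agreement. σ = 5 px is a common
heatmap width for images in the 160–192 px range: wide enough to give the
loss a usable gradient basin, narrow enough to separate adjacent keypoints.
Amplitude is fixed at 1 to bound targets for MSE and make decoded map
values interpretable as confidences.

The posture graph draws each skeleton edge as a Gaussian-profile line (the
perpendicular profile has the same σ as the peaks) and stacks four levels:
edges, limbs, whole graph, whole graph plus peaks. Two details were left
open by the problem and decided here:

- **Combination is elementwise max, not sum.** Max keeps values in [0, 1]
  where limbs meet, so every level remains a well-normalised confidence
  map.
- **A limb is the set of edges sharing the same child-of-root ancestor**
  (a branch of the root). For typical animal trees rooted at the
  body centre this reproduces the intuitive groupings ("left leg",
  "head chain") and is deterministic for any tree.

Edges with an invisible endpoint contribute zero maps. Graph maps are
auxiliary supervision only and are dropped at inference.

## Subpixel decoding

The decoder cross-correlates each map with a Gaussian template of scale
σ/s (a matched filter against the drawn peak shape), centred at
((w−1)/2, (h−1)/2). The template is mean-subtracted first, which makes the
correlation argmax invariant to constant background offsets in predicted
maps. The coarse shift is the argmax of the circular FFT correlation
(wrapped indices beyond half the map size read as negative shifts); the
refinement evaluates the inverse transform of the correlation spectrum
directly on a ⌈1.5u⌉×⌈1.5u⌉ grid of spacing 1/u centred on the coarse
shift. The grid size is forced odd so the zero offset is always a
candidate; without this the decoder carries a constant 1/(2u) bias.
u = 16 (1/16 map pixel) costs little on the small refinement neighbourhood
and is finer than any error the models produce. Decoded peaks outside the
image are clipped to its bounds rather than raised, since badly trained
models legitimately peak at borders. The confidence score is the bilinear
interpolation of the map at the decoded peak, clipped to [0, 1] — a
spec-level choice, as is everything about confidence calibration.

A brute-force oracle decoder (analytic Gaussian scanned over a dense 1/u
grid in the spatial domain) shares no code with the FFT route and must
agree with it to 1/u on every tested map.

## Augmentation

Spatial parameters follow the distributions standard for egocentric
single-animal imagery: per-axis Bernoulli(0.5) flips, rotation uniform on
[−180°, 180°), scale uniform on [90%, 110%] (a [75%, 125%] range suits
datasets with larger size variation), and per-axis translation uniform on
[−5%, +5%] of image size. Flip, rotation/scale about the image centre, and
translation compose into a single affine applied in one bilinear pass with
reflective edge padding — one interpolation, not three. Keypoints receive
the same affine exactly; each flipped axis additionally permutes labels by
the skeleton's swap involution. Keypoints leaving the frame become
invisible rather than clipped — clipped coordinates would poison the drawn
targets. The load-bearing correctness property, tested directly: the peak
of a warped map and the map of warped keypoints agree to half a map pixel.

Noise magnitudes (additive amplitude, dropout fraction, blur/sharpen
strength, contrast range) have no canonical values; defaults are mild
(≤10/255 additive, ≤5% dropout, ≤1 px blur, contrast 0.8–1.2) and every
one is configurable. Noise never touches keypoints.

## Architectures and capacity

Both models first downsample to the output stride with a small
convolutional front end, then run `n_stacks` subnetworks, each emitting a
supervised (K+G)-channel output; subsequent subnetworks consume the
previous features concatenated with those output maps. Whether the front-end
features are re-injected at each stack, and whether gradients flow between
stacks, are open design points — both are flags (`reinject_input`,
`detach_between_stacks`), off by default.

The dense subnetworks use pre-activation BN→ReLU→conv ordering, dense
blocks of 3 layers, 2 pooling levels, and 0.5 compression in the
transitions. The exact capacity knobs are free parameters; the defaults
(growth rate 15, 40 front-end filters) were fixed so the canonical
two-stack stride-4 model for a 160×160×1 input with 9 keypoints lands at
1.50 M trainable parameters, the capacity regime this family of models is
designed for. The hourglass variant exposes its filter width
(`base_filters`, default 48) instead of hard-coding 256-filter blocks.

Inputs are normalised to [0, 1], matched to the amplitude-1 targets under
MSE. The compute backend (`posekit.nn`) is a compact numpy tape autodiff
with convolution evaluated as one GEMM per kernel tap; every operator's
gradient is verified against central finite differences in the test suite.

## Training protocol

Loss: mean over the supervised outputs of per-output MSE against one shared
target stack; validation loss uses the same full stack on unaugmented data.
Optimiser: Adam at its published moment defaults; only the learning rate is
scheduled. "Improvement" means the validation loss beats the best seen by
more than an absolute δ = 1e-3 — the natural reading of the plateau rule —
and the same δ governs early stopping for consistency; both thresholds,
patiences (10 and 50 epochs), and the factor (5) are configurable. The
schedule is a pure function of the validation-loss history, so any recorded
run can be replayed and checked exactly. Divergence (non-finite loss)
raises with the epoch index rather than producing a silent NaN checkpoint.
Checkpoints are `.npz` weight archives with the model config embedded as
JSON, so a checkpoint is self-describing.

## Curation

k-means frame sampling embeds images as flattened 32×32 grayscale vectors —
the cheapest embedding that separates gross posture differences — clusters
with k = 10 by default, and draws round-robin across clusters so every
posture mode is represented before any repeats. Egocentric alignment is
rigid (rotation + translation only, no scaling): the midpoint of the two
axis keypoints moves to the image centre and the axis points up.

## Bayesian error comparison

The Gamma mean-dispersion parameterisation (α = μ²/ϕ, β = μ/ϕ) makes
E[y] = μ and Var[y] = ϕ hold exactly per posterior draw, so "this model is
more accurate" (μ) and "this model is more consistent" (ϕ) are separate,
directly interpretable posterior statements. Observations are per-keypoint
errors (per-image means are an alternative the caller can aggregate to).
Zero errors are shifted by 1e-6 into the Gamma support. Priors are weakly
informative Normal(0, 10) on the link scale.

Sampling uses an affine-invariant ensemble MCMC (emcee) with
differential-evolution moves, which mix much faster than stretch moves on
this correlated 2G-dimensional posterior: 32 walkers × 3000 steps, first
1000 discarded, thinned by 5. The group likelihood reduces to sufficient
statistics (n, Σy, Σ log y), so sampling cost is independent of sample
size. Split-R̂ is computed per parameter treating walkers as chains; values
above 1.01 raise a warning and are attached to the result — reported, never
swallowed.

## Synthetic data

The generator emulates the structure of overhead single-animal footage: an
egocentrically centred creature (root at the image centre), forward
kinematics from per-joint rest angles with Gaussian angular jitter
accumulated along each chain (so limbs swing coherently), anti-aliased
bright limbs on a dark background, and additive Gaussian noise (default
σ = 5% of full scale). Presets mirror the shapes of three reference
datasets — fly192 (192×192, 32 keypoints), locust160 (160×160, 35),
zebra160 (160×160, 9) — with bilaterally symmetric tree skeletons.
`scaled_creature` shrinks a preset geometrically for fast pipeline runs.

What the generator does **not** emulate: appearance variation (texture,
lighting gradients, shadows), occlusion by other animals or objects,
self-occlusion, background clutter, motion blur, or label noise. Passing
tests on synthetic data therefore demonstrates the correctness of the
pipeline — encoding, optimisation, decoding, statistics — not performance
on real footage, which depends on annotation quality and image variance.

## Problem sizes in the test and acceptance runs

Everything runs on one CPU core. The overfit harness trains a one-stack
minimal model (growth 8, 16 front filters, stride 4) on ten 64×64 creatures
for up to 500 epochs with augmentation disabled and a fine-grained plateau
schedule (δ = 2e-6, factor 2) — the interpolation regime the harness is
meant to reach. The generalisation check trains the same family on 50
images of the zebra-skeleton creature scaled to 96×96 for 50 epochs.
Round-trip and oracle sweeps use 200 and 50 random keypoints; Gamma
coverage uses 50 replicates of two groups × 200 observations with
shortened chains (coverage needs many fits, not long ones). The full
model-comparison study sizes (hundreds of annotated frames at native
resolution, multi-hour training) are out of desk-scale scope.

## Known limitations

- Single centred individual only: no localisation, tracking, or multi-peak
  decoding; upstream detection must crop each animal first.
- The numpy backend is CPU-bound and single-threaded beyond BLAS; it is
  sized for small studies and tests, not production training throughput.
- Confidence scores are uncalibrated map values.
- BatchNorm uses running statistics for inference; very small batch
  training can make those statistics noisy.
- The Gamma model assumes exchangeable per-keypoint errors within a model
  group; it does not model per-keypoint or per-frame random effects.
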