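# Methods

## Architecture

The network is a symmetric 1-D temporal encoder–decoder over per-frame
feature vectors, with a self-attention block at the bottleneck.

**Dilated residual layers.** Both stacks consist of `L` layers (default
10); layer `l` applies an acausal dilated convolution (kernel 3, dilation
`s_l = 2^l`), ReLU, a 1×1 convolution, and a residual connection. The
convolution is zero-padded by `s_l` frames on each side, the only padding
that preserves the temporal length at every dilation rate; this also
makes each layer an exact identity map when its convolution branch is
zero, which the tests exploit. The stack's receptive field is
`1 + 2·Σ s_l = 2^{L+1} − 1` frames (2047 at `L = 10`); the package
measures it empirically by input perturbation rather than trusting the
closed form, probing with large ±deltas and several input draws so a
ReLU unit that happens to block one path cannot truncate the measurement.

**Pooling.** The encoder ends with a temporal max-pool of factor 4. When
`T` is not a multiple of the factor, the sequence is right-padded by
replicating the last frame before pooling and the decoder output is
cropped back to `T`, so the length contract `output rows = T` holds
exactly for every `T ≥ 1`. Unpooling is a parameter-free
nearest-neighbour repeat: max-unpooling switch indices would add state
for no demonstrated benefit, and repetition is the standard choice in
temporal segmentation decoders.

**Attention bottleneck.** Single-head scaled dot-product attention
(`d_k = d_v = 16`) with a learned output projection back to `f` channels
so the residual connection type-checks, a fixed sinusoidal positional
encoding applied at the bottleneck resolution (that is where order
information must be re-injected after pooling), and two residual +
layer-norm blocks wrapping the attention and the 512-wide position-wise
feed-forward layer. Q/K/V projections carry biases. A single head is
used throughout; multi-head attention is out of scope.

**Heads.** The gesture head is a per-frame affine map to 10 classes with
a row-wise softmax. The skill head averages the per-frame skill logits
over time before the softmax; because the head is affine this equals
applying it to the temporal mean feature, and it is invariant to frame
permutations — the simplest aggregation consistent with a single
video-level prediction. Feature-mean-first versus logit-mean-first is
therefore not a real fork for this head.

**Stage flags.** `use_encoder`, `use_decoder`, `use_attention`,
`use_pooling`, `use_skill_head` compose the forward pass, expressing the
ablation presets from `attention_only` through `multitask_full`. Pooling
wraps whatever sits at the bottleneck, so every variant preserves the
length contract.

## Optimization

Categorical cross-entropy for both tasks, combined as
`L = α·L_gesture + β·L_skill` (α = 0.9, β = 0.1 by default: skill
assessment is the auxiliary task). Losses are computed from logits via
log-sum-exp — algebraically identical to softmax + log but immune to
underflow. Frames outside any transcript segment carry the label `−1`
and are excluded from the gesture loss and all metrics; the skill loss
counts once per sequence per epoch. Training is Adam over one
full-length sequence per step with seeded epoch-level shuffling; batch
padding machinery would buy nothing at batch size 1 with variable `T`.
No dropout, learning-rate schedule or early stopping by default;
gradient clipping is exposed but off. Full-scale defaults are 30 epochs
at learning rate 0.01. For the reduced-scale synthetic experiments
(6 layers, 32 channels) the package uses 80 epochs at 0.002, which
converges cleanly where 0.01 oscillates for this smaller, shallower
configuration.

The whole network, its hand-derived backward pass and Adam are plain
NumPy in float64. Analytic gradients are verified against central finite
differences for every parameter array in the test suite; float64 keeps
those checks tight (relative agreement ~1e−6) and makes seeded runs
bit-reproducible. Argmax decoding breaks ties toward the lowest class
index. Non-finite activations or losses abort with the offending layer
or epoch/sequence identified.

## Metrics

* **Frame accuracy** — percentage of annotated frames correctly
  classified.
* **Edit score** — `100·(1 − D/max(m, n))`, clamped at 0, where `D` is
  the Levenshtein distance between the predicted and true segment class
  sequences (lengths `m`, `n`). Normalization by the *longer* sequence is
  the convention of the encoder–decoder TCN lineage this evaluation
  follows and keeps the score on the same 0–100 scale for either
  direction of fragmentation. Two empty lists score 100.
* **F1@k** — predictions are scanned in temporal order; each claims the
  unmatched same-class ground-truth segment of highest temporal IoU and
  counts as a true positive when that IoU strictly exceeds k/100. Greedy
  first-match is the field's standard; it is *not* always the optimal
  assignment — the tests carry a frozen counterexample where greedy finds
  2 true positives and exhaustive enumeration finds 3 (about 1 in 10⁴
  random pairs) — so the suite asserts the bound `greedy ≤ optimal`
  everywhere and exact agreement on a fixed random sample.
* A note on over-segmentation monotonicity: inserting segments into a
  prediction does **not** monotonically lower the edit score (an
  insertion can move a short prediction closer to a longer ground truth).
  The true penalty is the bound `score ≤ 100·min(m,n)/max(m,n)`, which
  the suite asserts, alongside the 1-Lipschitz property of the distance
  under single insertions.

Fold aggregation is the unweighted mean over folds (confusion matrices
are summed). LOUO holds out all trials of one subject per fold; LOSO
holds out repetition *i* of every subject.

## Synthetic trials

The generator emulates the structure of a JIGSAWS-like cohort: 8
subjects × 5 repetitions, 10 gesture classes, 128-dim features at a
nominal 10 FPS, with 2 expert / 2 intermediate / 4 novice subjects.

* **Grammar** — a Markov chain over gesture classes (zero diagonal;
  dominant forward flow with occasional skips) emits the segment order;
  12 base segments per trial.
* **Durations** — a shifted negative binomial per segment (mean 20
  frames ≈ 2 s, dispersion 4: heavy-tailed enough to create realistic
  over-segmentation pressure), scaled by a skill multiplier.
* **Skill effects** — novices take longer (duration multipliers 2.0 /
  1.5 / 1.0 for novice / intermediate / expert) and commit brief
  erroneous gestures (insertion probabilities 0.15 / 0.08 / 0.0, inserted
  segments ~6 frames before scaling). The skill signal lives *only* in
  these temporal dynamics, never in the feature centroids, so the skill
  task genuinely requires video-level temporal reasoning.
* **Features** — frame feature = class centroid + isotropic Gaussian
  noise, then a 5-frame moving average (adjacent video frames are
  correlated). Centroids are standard normal scaled by 0.15 with
  per-dimension noise sd 1.0: by the two-class Gaussian error formula
  this puts per-frame nearest-centroid error around 10–15 % before
  temporal context, so temporal smoothing and context genuinely matter,
  and boundary frames blur across segments.

What the generator does **not** emulate: visual/kinematic skill
correlates (tremor, path smoothness, idle time), subject-specific
appearance, annotation noise, and the long-range task-phase structure of
real surgery. Passing the synthetic recovery tests therefore shows the
pipeline can learn segment structure and duration statistics end to end;
it does not certify real-data performance.

Under these frozen conditions the cross-validated LOSO skill accuracy of
the small network plateaus near 60–65 %, while a linear discriminant
given the *ground-truth* per-trial duration statistics reaches 87.5 % —
the information is present but extracting near-oracle duration statistics
from 32 training videos through a β = 0.1 auxiliary loss is the hardest
part of the synthetic task. This is a known limitation of confining the
skill signal to durations at desk scale; on real data the published
architecture benefits from much richer skill correlates.

## Problem sizes

The test suite and the acceptance script run the synthetic study at a
reduced scale chosen as the package's own desk-scale condition: the
default cohort (40 trials, ~160–600 frames each), a 6-layer, 32-channel
pooled network for cross-validation, a 4-layer, 16-channel network for
the overfit check, and receptive-field measurement at the full 10 layers
(2047 frames). Full-size forward passes (10 layers, 128 channels,
T = 1000) are exercised for the architecture contracts.
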