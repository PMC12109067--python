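# Methods

`hcdm` implements a retina-inspired pipeline for pixel-level motion-direction
detection in pairs of RGB frames: a synthetic moving-object dataset, a
horizontal-cell (HC) On–Off feature frontend, and a sigma-pi dendritic
ganglion network trained by exact chain-rule gradients.  This note records
the model, its assumptions, and the numerical and design choices that were
genuinely open.

## Synthetic dataset

A sample is a pair of consecutive 32×32×3 8-bit frames.  A 4-connected
object of size s ∈ {1, 2, 4, 8, 16, 32, 64, 128} pixels is grown by uniform
random frontier expansion from a seed cell, placed uniformly among all
positions where both it and its translate fit, and shifted by exactly one
pixel step along one of the eight compass directions (diagonals move
(±1, ±1)).  Object pixels keep their colors between frames — motion is the
only object-level change.

Backgrounds and objects each follow one of three color regimes: `dark`
(zeros), `constant` (one scalar 1–255 shared by all pixels and channels),
`random` (i.i.d. uniform 1–255 per pixel and channel).  The 3×3 regime grid
minus the invisible dark-on-dark case gives the eight dataset groups.
`random` backgrounds are regenerated independently per frame, so background
memory is useless and object motion is the only temporally reliable cue;
`dark`/`constant` backgrounds are shared between frames.  In the
constant–constant group the object scalar is resampled until it differs from
the background scalar, since an equal pair would render the object invisible.

Noise is a test-time corruption applied independently to both frames:
salt-and-pepper sets exactly round(rate·H·W) pixel positions (sampled
without replacement; ties round half to even) to 0 or 255 in all three
channels, with the salt fraction drawn once per image from U(0, 1); Gaussian
noise adds zero-mean i.i.d. noise per pixel and channel, rounded and clipped
to [0, 255].

What the generator does *not* emulate: natural image statistics, textured
objects, multi-pixel or sub-pixel displacement, occlusion, and more than two
frames.  Results on this dataset therefore speak to pixel-level displacement
detection under controlled contrast regimes, not to natural video.

## Horizontal-cell On–Off frontend

For each interior pixel (a, b), each neighbor offset (y, z) ∈ {−1,0,1}²\{0},
and each channel c, the feature is

    H(a,b,y,z,c) = 1  if |frame_t[a,b,c] − frame_t1[a+y,b+z,c]| < θ_H
                   0  otherwise,        θ_H = 3.

θ_H is the smallest RGB difference treated as resolvable; a difference of
exactly θ_H counts as resolvable (feature 0).  Centers come only from frame
t and neighbors only from frame t+Δt, making the comparison temporally
asymmetric: at object pixels the neighbor along the motion offset matches
exactly, so the 24-vector per receptive field (8 neighbors × 3 channels,
channel-major order) carries a local direction cue.  Features are computed
only where the full 8-neighborhood exists (no invented padding), giving
(H−2)(W−2) = 900 receptive fields per 32×32 pair.

## Dendritic ganglion network

Per receptive field, with inputs x_i ∈ {0, 1}, i = 1..24, branch j = 1..J,
direction output m = 1..8:

    synapse   s_ijm = σ((w_ijm·x_i − q_ijm)/d)          d = 1 (fixed)
    branch    b_jm  = Π_i s_ijm
    membrane  u_m   = Σ_j v_jm·b_jm                      v_jm = 1/J (fixed)
    soma      o_m   = σ(λ_m(u_m − θ_m))                  λ = 10, θ = 0.5

One parameter set is shared by all receptive fields; the per-field soma
outputs are sum-pooled into the global response vector Ō (length 8), and the
predicted direction is argmax_m Ō_m (ties to the lowest code).

Fixed constants: d is redundant with w and q and never learned.  v = 1/J
keeps u ∈ (0, 1) for every branch count, so the soma threshold default is
meaningful across J (v = 1 is available via configuration).  λ = 10 and
θ = 0.5 place the soma switch at "half the branches fully active"; both are
configurable.

Under binary inputs each synapse realizes one of four regimes — excitatory
(s rises with x across 0.5), inhibitory (s falls across 0.5), constant-1
(pass-through), constant-0 (pruned: it silences its branch) — classified
from s0 = σ(−q/d) and s1 = σ((w−q)/d).

Numerics: binary inputs mean each synapse takes only the two values s0, s1,
so log b = Σ_i log s0 + Σ_i x_i(log s1 − log s0) turns the branch products
of a whole image into one matrix product; products are evaluated in log
space and the logistic is overflow-guarded.  A general per-field path
handles real-valued inputs and doubles as a cross-check; both paths agree
with a dependency-free scalar loop to 1e−10.

## Output normalization and loss

The pooled vector Ō sums sigmoids over 900 fields and is not a probability
distribution.  The default map is sum-normalization, p_m = Ō_m / Σ_k Ō_k —
the literal reading of "Ō represents the probability distribution over
directions" — with cross-entropy E = −Σ_m T_m log p_m (natural log, floor
1e−12 on the target probability).  A softmax over Ō/τ with τ = the number of
receptive fields is provided as an alternative.

Sum-normalization is also the better-behaved training signal: its gradient
∂E/∂Ō_m = 1/ΣŌ − T_m/Ō_m pulls with magnitude 1/Ō_target, i.e. hardest on
images whose true-direction response is still weak (small objects, sparse
cues), whereas the field-count softmax pulls with the constant (p−T)/τ ≈
1e−4 and, empirically, leaves training on a long plateau.

## Training

Plain mini-batch SGD on w and q only (batch 128, seeded shuffle per epoch,
bitwise-reproducible): Ω ← Ω − η·∂E/∂Ω, Q ← Q − η·∂E/∂Q, with gradients the
exact derivatives of the composed forward pass, validated against central
finite differences (relative error < 1e−5).  The per-branch structure of the
printed per-layer derivative chain is resolved by differentiating the
composition exactly, summing over receptive fields and branches.

Initialization is permissive and output-symmetric: w ~ U(−1, 1) and
q ~ U(−4, −2) drawn once per (input, branch) and shared across the eight
outputs.  Two measured failure modes motivate this:

* mid-range biases (q ~ U(−1, 1)) collapse the 24-factor branch products to
  ~1e−8 and all gradients to ~1e−10 — the network is born silent and cannot
  leave its initial state at any learning rate;
* independent per-output draws give the eight outputs large random pooled
  offsets (std ≈ 20 out of ~115), and SGD spends its entire budget
  equalizing them before any class signal can accumulate.

The permissive start (every synapse near constant-1) is also the natural
developmental reading: learning prunes and specializes an initially
all-pass dendritic tree.  The untrained symmetric network responds
identically to all eight directions and therefore starts exactly at the
uniform predictor.

Learning rate: the default is η = 30 (stable range ≈ 10–100 under
sum-normalization).  The absolute scale of the gradient is set by the choice
of output normalization, which the model family leaves open, so η is
loss-scale plumbing rather than a physical constant; the value 0.001 often
quoted for cross-model comparisons presumes a different (unspecified)
normalization and, under either normalization implemented here, cannot move
this architecture off the uniform predictor in any feasible epoch budget.

Convergence is declared when, over a trailing window of 10 epochs, every
training accuracy lies within 0.05 percentage points of the window mean and
the window standard deviation is at most 0.1 points (both inclusive).  A
stable plateau at ≤ 2× chance accuracy is treated as the pre-learning phase
of the symmetric start, not convergence.  Divergence (NaN loss) aborts with
a diagnostic.

## Evaluation protocols

* **Branch sweep** — train J ∈ {1, 5, 10, 20} on a mixed eight-group 75/25
  split; report train/test accuracy (mean ± sample std over repeats) and
  CNLE.
* **Cross-validation** — train on a single group; report accuracy on that
  group's held-out pairs and *cross-accuracy* on a balanced mixture of all
  eight groups.
* **Noise immunity** — evaluate a clean-trained model on test pairs with
  salt-and-pepper rates {1, 2, 5, 10}% or Gaussian std {1, 5, 10, 20}
  applied to both frames at test time (noise is a test-time robustness
  probe; models are never trained on noise).

CNLE (compute-normalized learning efficiency) is L = batch_size·ΔE·α/(R·P)
with α = 100, ΔE the cross-entropy reduction from the start of training, R
wall-clock training seconds and P processor utilization in percent.  It is
hardware-dependent and reported for information only, never asserted in
tests.

## Problem sizes

The package's experiment defaults are desk-scale: 2,000 mixed pairs (1,500
train / 500 test) rather than 10,000, 1,200 single-group training pairs,
2 training repeats plus 3 noise seeds per reported mean, and epoch budgets
of 160–250 with convergence stopping (η = 100 for J=5 runs, η = 30 for J=1
and constant-background runs, which oscillate at the larger step).  At this
scale a J=5 mixed run trains in ~2–3 CPU minutes and reaches ≳95% held-out
accuracy; larger runs reproduce the same qualitative picture with higher
accuracy.  All sample counts are parameters of the relevant functions.

## Known limitations

* Single-pixel displacement only; the frontend's 3×3 receptive field cannot
  represent larger shifts.
* The learning dynamics pass through a plateau at chance before selectivity
  bootstraps; convergence detection must (and does) ignore that plateau.
* CNLE values depend on the host machine and are not comparable across
  environments.
* The constant-background groups train more slowly than random-background
  groups because all-match background fields saturate every direction's
  pooled response equally, shrinking relative gradients.
* Cross-regime transfer is asymmetric in this implementation: models trained
  on random (flickering) backgrounds keep improving their transfer to the
  other regimes the longer they train, because their branches sharpen into
  background-independent edge gates, whereas models trained only on static
  constant backgrounds acquire branch patterns that assume neighboring
  pixels usually match and degrade on flickering backgrounds.  Transfer
  from single-group training also varies substantially across initialization
  seeds.
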