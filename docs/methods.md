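# Methods

This note documents the models, numerical choices, and the synthetic
benchmark behind `eedcl`, in the spirit of a model-documentation page: what
is computed, under which assumptions, and what the self-tests do and do not
establish.

## The model

`eedcl` implements an EEG classification architecture built from four parts,
plus a contrastive pretraining stage.

### Shallow feature encoder

Two interchangeable encoders map a window `X ∈ R^{C×T}` (C electrodes, T
samples) to a token sequence:

* **Depthwise-separable encoder** (`DscSfe`): per-electrode depthwise
  temporal filters (m per electrode, kernel k_t) → BatchNorm + ELU → mean
  pooling (factor P along time) → pointwise mixing of the m maps to F →
  depthwise spatial kernel spanning all C electrodes (one weight vector per
  map, 'valid', which collapses the electrode axis) → pointwise expansion
  F → e·F → BatchNorm + ELU after every convolution → patch-embedding
  tokenizer (non-overlapping length-p patches, linear map to d).
* **Dense baseline** (`BaselineSfe`): standard temporal convolution
  (1×k_t, depth 1→F) → spatial convolution (C×1, depth F→e·F) → max pooling
  (factor P) → the same tokenizer.

Conventions: cross-correlation (no kernel flip), 'same' padding along time,
'valid' along electrodes. All encoder convolutions are bias-free and the
encoder BatchNorms carry no affine pair — both are redundant under the
normalization that immediately follows, and the parameter counts then
reflect exactly the filter banks being compared.

At the reference configuration (C=32, T=512, k_t=45, m=2, F=64, k_s=32,
P=4, p=8, d=64, e=2), the analytic counts are

|            | parameters | forward MACs |
|------------|-----------:|-------------:|
| dense SFE  | 265,024    | 181,403,648  |
| DSC-SFE    | 13,248     | 3,309,568    |
| ratio      | 20.005     | 54.8         |

`count_params`/`count_macs` compute these from declarative layer lists
(conv params = depth_in/groups · depth_out · k; MACs = per-position
multiplies × output positions). The comparison covers the convolutional
stacks; the tokenizer is identical in both encoders and excluded. The final
pointwise stage expands F → 2F: with it, both encoders reproduce the
published fold-reduction bounds (≥20× parameters, ≥36× MACs); without it
the parameter ratio cannot reach 20 under any consistent reading of the
two stage lists.

### Hierarchical coarse/medium/fine layers

Each of L layers (default 3) halves the token count through three parallel
branches whose outputs are summed:

* **Coarse**: multiscale gated linear attention (MG-LA). Queries, keys and
  values are average-pooled over windows of 1, 2, 4 tokens per scale;
  each scale computes φ(Q)(φ(K)ᵀV) with φ(x) = ELU(x)+1, right-to-left, so
  the cost is linear in sequence length; results are nearest-neighbour
  upsampled and combined through per-scale, per-feature sigmoid gates
  (logits initialized to 0, i.e. neutral weight 1/2). Heads are folded into
  the feature dimension (block-diagonal over d/d_k heads, d_k = 16): the
  per-scale cost is O(n·d·d_k), which is what makes linear attention
  cheaper than softmax attention from a few dozen tokens — full-width
  d×d state would not be. The MG-LA output is linearly projected,
  max-pooled (kernel 2, stride 2), added to the max-pooled input
  (the residual path), layer-normalized, and passed through a 2-layer ELU
  feed-forward block (hidden 2d). Pooling the attention output before the
  residual sum is the minimal reconciliation of an un-pooled attention
  formula with a pooled residual: the sum requires equal lengths.
* **Medium**: dropout 0.25 → kernel-7 temporal convolution over tokens
  (feature dim as depth) → BatchNorm + ELU → average pool (2, stride 2).
* **Fine**: dropout 0.10 → kernel-3 convolution → BatchNorm + ELU →
  stride-1 max pool (kernel 2, 'same') → stride-2 subsample. The subsample
  after the stride-1 pool is what makes the three branch shapes equal so
  they can be summed.

### Dense purification (per layer)

The medium and fine maps of every layer are refined before fusion:
log-power (square → centred moving average of width w tokens, edges
replicated, → log(·+ε), ε = 1e-8) keeps the token axis — a global temporal
mean would collapse the sequence and leave nothing for attention to attend
over; w defaults to 8 and clamps to the sequence length. Single-head scaled
dot-product self-attention over the power map is blended with the raw power
map through a per-feature sigmoid gate (a convex combination, gate logits
initialized to 0), and the refined medium and fine maps are combined by a
learnable weighted sum α·medium + β·fine with α = β = 1 at initialization
(the plain sum, as printed). Parameters are per-layer, unshared. The
`dip` mode (used by the `no_adip` ablation) is the global-mean log-power
with no attention (w = full length).

### Head

The final integrated map and each layer's fusion map (average-pooled to the
final token count) are concatenated along the token axis in fixed order
(integrated, then layers first→last), passed through a pre-LN transformer
encoder (2 layers, 4 heads, no positional encoding — token order is already
hierarchical by construction), mean-pooled, and classified by a 2-layer MLP
(hidden 2d, ELU, dropout 0.5, softmax). A separate projection head
(mean-pool → d → d_z = 128 → L2 normalization) produces the unit-norm
embeddings used only during contrastive pretraining and discarded
afterwards.

### Losses and optimization

* **InfoNCE**: −log[exp(s⁺/τ) / (exp(s⁺/τ) + Σ_j exp(s_j⁻/τ))] over cosine
  similarities, τ = 0.1; negatives are in-batch (every candidate that
  violates the positive criterion), and positives are either two augmented
  views of one window (`self_supervised`) or an augmented same-subject,
  same-class window (`class_conditioned`, the default).
* **Weighted cross-entropy**: −w_y log p_y with inverse-frequency default
  weights N/(K·N_c), weight-normalized over the batch so uniform weights
  reduce to the plain cross-entropy; probabilities clamped at 1e-12.
* **AdamW** throughout (β = 0.9/0.999, decoupled weight decay 0.01);
  published protocol defaults: lr 1e-4, batch 64. Fine-tuning keeps
  pretrained representations with either a frozen encoder or a 10× reduced
  encoder learning rate (the default).

All of this runs on a small tape-based reverse-mode automatic
differentiation engine over NumPy (`eedcl.nn`), written for this package:
grouped stride-1 convolution via im2col with the column matrix reused for
the weight gradient and the input gradient computed by the flipped-kernel
correlation identity; fused moment normalization serving BatchNorm and
LayerNorm; gradients verified against central finite differences in the
test suite.

## Synthetic benchmark

The generator emulates the statistical structure this architecture is
designed to exploit, not raw-EEG realism:

* band-limited sources — two per canonical band (theta 4–8, alpha 8–13,
  beta 13–30 Hz), unit-RMS sinusoids with random frequency and phase and a
  **phase-diffusion** random walk (coherence time 1 s by default): cortical
  rhythms do not hold phase over a whole trial, and phase-locked sources
  would make cross-channel interference a trial-level constant that inflates
  window-to-window correlation;
* a per-subject C×S mixing matrix, per-subject channel gains in [0.5, 2]
  and ±25 % band-amplitude jitter (inter-subject variability);
* 1/f-power background noise (spectrally shaped white noise), unit RMS
  per channel at the default noise level 1.0;
* class identity multiplies the theta and alpha source amplitudes, factors
  geometrically spaced so the extreme classes differ by `class_effect`
  (default 2.0).

A no-learning oracle (alpha-band Welch power, median-midpoint threshold)
separates the extreme classes with ≥90 % accuracy at the default settings —
the self-tests assert this before any learning test is trusted. What the
generator does **not** model: ocular/EMG artifact morphology, volume
conduction, non-stationary class effects, realistic channel covariance.
Passing the learning tests therefore shows the pipeline recovers planted
band-power structure under subject variability and 1/f noise; it does not
certify performance on recorded EEG.

Default geometry is DEAP-like (32 channels, 128 Hz, 60 s trials); the desk
bench (`eedcl.bench`) scales this to 8 channels, 64 Hz, 12 s trials — five
4-s windows at 50 % overlap per trial — so that the full training protocols
run in minutes on one CPU. At 64 Hz the preprocessing band is 4–28 Hz
(the usual 4–47 Hz upper edge would cross Nyquist/attenuation margins).

## Desk-scale training protocol

Choices made once for the CPU bench, and why:

* **Reduced model**: k_t=25, m=4, F=24, P=16, p=2, d=32, one final-encoder
  layer, L=3. Pooling factor 16 (250 ms at 64 Hz) exceeds the slowest
  planted period (theta, 167 ms), so the post-ELU mean pool is an envelope
  and per-electrode band power exists immediately after the depthwise
  temporal stage. m=4 gives each electrode one filter per band centre
  (theta, alpha, low and high beta) — beta coverage is what normalizes the
  class-scaled theta/alpha power after z-scoring.
* **Band-pass filter-bank initialization**: the depthwise temporal filters
  start as unit-norm windowed cosines cycling through the canonical band
  centres (±10 % jitter, random phase). Random flat-spectrum filters make
  every downstream power feature band-unselective at initialization;
  seeding oscillatory atoms is the EEG analogue of wavelet initialization
  and markedly shortens training on band-power tasks.
* **Augmented fine-tuning**: every batch is re-drawn through the full
  augmentation suite — window shift (30–50 % overlap with the anchor),
  ±10 % time warp, σ = 0.2 Gaussian noise. Without it the network memorizes
  trial-specific source frequencies and interference patterns instead of
  band power. lr 5e-3, batch 64, 35 epochs.
* **Trial-level scoring**: predictions average the per-window softmax
  vectors of a trial's five sliding windows (argmax ties resolve to the
  lowest class index) — the same postprocessing used at inference.

Under these conditions the end-to-end check (3 subjects, 2 classes,
class-effect 2, 40 trials per class, 5-fold CV grouped by trial, 3 training
seeds) reaches ≥90 % mean trial accuracy; the label-efficiency check (5
subjects, class-effect 1.6, 25 % of trial labels, self-supervised
pretraining for 8 epochs at lr 1e-3) scores at least as high with
pretraining as without it, seed-averaged. Both are computed fresh at test
time; no measured value is stored.

## Evaluation machinery

* **Cross-validation**: 5-fold grouped by trial (no trial contributes
  windows to both sides of a split) and leave-one-subject-out; folds
  shuffled deterministically from the seed.
* **Paired t-test**: two-sided, via the standard t statistic on the paired
  differences. Degenerate cases are policy, not errors: all differences
  zero → p = 1; constant non-zero differences → p = 0 (the limit of a
  deterministic difference).
* **Effective attention width (EAW)**: no published formula exists, so the
  package defines it as the mean linearly-interpolated full width at half
  maximum of each attention row over key positions, times the per-token
  hop in milliseconds. A delta row has width 1 token, a uniform row width
  n; a Gaussian profile of width σ tokens gives ≈2.355 σ. Every EAW result
  carries a provenance flag marking the definition as package-specific.
* **Analytic compute**: per-sample GFLOPs (2 FLOPs per MAC) summed over the
  encoder stack and the per-layer attention cores; the MG-LA core is
  O(n·d·d_k) per scale, the softmax core O(n²·d), so the softmax variant is
  costlier from a few dozen tokens and the gap grows with sequence length.

## Numerical notes and limitations

* float32 parameters and activations; float64 in tests where finite
  differences require it. Determinism holds for fixed seeds under
  single-threaded BLAS; bitwise stability across BLAS builds is not
  guaranteed (tolerances of 1e-6 are used instead).
* BatchNorm uses batch statistics in training and running averages
  (momentum 0.1) at inference; z-scoring leaves constant channels at zero
  with a warning (or raises, configurable).
* Segmentation drops remainder samples after the last full hop; windows
  are 0-based, half-open.
* The EDF writer emits 16-bit, one-second data records with per-channel
  symmetric physical ranges; round trips through the independent mne
  reader agree to one quantization step. Integer sampling rates and whole
  seconds only — sufficient for the generator's output.
* The stacked-autoencoder artifact-removal stage of the original
  preprocessing pipeline is out of scope; `preprocess_recording` is the
  hook where it would sit.
* Known limitation: the desk bench's accuracy margins are modest (a few
  points above the 90 % bar); slower hardware does not change them, but
  changes to the training recipe would require re-validation.
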