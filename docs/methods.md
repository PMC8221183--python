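# Methods

This note records the modeling conventions, parameter choices and numerical
decisions behind the package, and what the synthetic experiments do and do
not establish.

## Feature extraction

Band power is computed per channel with non-overlapped 1-s Hanning windows
zero-padded to a 512-point FFT; a band's power is the sum of periodogram
values over FFT bins with lo ≤ f ≤ hi, normalized by the window energy
Σw². Frame count is therefore ⌊duration/1 s⌋. Differential entropy uses
the Gaussian closed form DE = ½·ln(2πe·(P + ε)) with natural logarithm and
ε = 1e−12 guarding the log at zero power; band power plays the role of the
variance estimate. Consequence worth remembering: doubling a signal's
amplitude quadruples P and raises DE by ½·ln 4 = ln 2.

Variable-length trials are zero-padded at the tail to a common frame count
(265 for the 3-class layout, 64 for the 4-class layout, 40 for the tiny
preset). Padded frames are excluded from all statistics and re-zeroed after
normalization; zeros entering the mean/std would bias short trials.

Per-subject normalization standardizes each subject's valid frames to mean
0, std 1 per electrode-band. The default applies this to *every* subject
independently — including the held-out subject of a LOSO fold — which is
the convention of the benchmark datasets this pipeline mirrors. A
`normalize="train-only"` mode in `run_loso` uses pooled training-subject
statistics only, for experiments on normalization leakage; results in this
package's tests use the default.

## Graph construction

The self-organized adjacency is A = row-softmax(tanh(VW)·tanh(VW)ᵀ). The
softmax is applied **row-wise** (for fixed row i, normalize over j), the
attention convention: each row holds one electrode's outgoing weights and
sums to 1. Top-k sparsification keeps each row's k largest weights at their
values (ties break toward the lower column index for determinism); its
gradient is a straight-through mask — retained entries pass gradients,
zeroed entries block them — so it behaves like a modified max-pooling
layer during backpropagation.

Row-softmax plus top-k yields an asymmetric matrix, but spectral filtering
needs a real symmetric eigensystem, so the Laplacian is built from
A_sym = (A + Aᵀ)/2. Softmax rows guarantee strictly positive degrees;
for baseline graphs (covariance/absolute-correlation), a configurable
unit self-loop handles isolated nodes.

The spectral filter is an order-K Chebyshev polynomial (default K = 2) of
the rescaled Laplacian L̃ = 2L/λ_max − I with λ_max fixed at 2 (the upper
bound of the normalized-Laplacian spectrum), evaluated in the vertex
domain by the three-term recurrence with a learnable (K+1) × C_in × C_out
coefficient tensor. An explicit U·Θ(Λ)·Uᵀ eigendecomposition path exists
solely as the independent reference; tests require agreement within 1e−5
relative on random graphs (measured agreement is ~1e−15).

## Architecture

Three conv-pool blocks (kernels 5×5, 1×5, 1×5; maps 32/64/128; pooling
1×4 for 265-frame inputs, 1×2 for 64-frame inputs) act on each electrode's
band × time map independently. The first kernel consumes the whole band
axis, enforced at construction. The same pool size is applied in all three
blocks — the block naming implies pooling in each, and no other guidance
exists — giving temporal chains 265→261→65→61→15→11→2 and 64→60→30→26→13→9→4.
ReLU follows every convolution and every graph convolution. Dropout
(rate 0.1) is applied to each block output and to the concatenated feature
vector during training. The classifier head is one hidden fully connected
layer (width 128, configurable) followed by the softmax output layer.

The training loss is the summed per-class binary cross-entropy applied to
the softmax outputs, −Σᵢ Σ_c [y·ln p + (1−y)·ln(1−p)], with probabilities
clamped to [1e−7, 1−1e−7] so both logarithms stay finite; plain categorical
cross-entropy is available behind `loss_kind="categorical"` for ablation.
Weights use uniform Glorot initialization from a configurable seed.

Shape propagation is computed symbolically from the configuration and
validated at construction; any temporal underflow fails before training
starts.

## Training and evaluation protocol

Defaults: Adam with learning rate 1e−5, weight decay 1e−4 (added to the
gradient), batch size 16, dropout 0.1. After every epoch the macro
one-vs-rest AUC is computed on the full training set in eval mode;
training stops at the first epoch reaching 0.99, with a max_epochs cap of
500 so non-converging runs terminate (flagged by `epochs_trained` in the
log). LOSO trains a fresh model per fold with seed = global seed + fold
index; the early-stopped parameters are used directly — no
validation-based checkpointing, which would leak the held-out subject.
Metrics: argmax accuracy, per-class and macro F1, macro one-vs-rest AUC
(classes absent from a validation set are excluded from the macro with a
warning), and full confusion counts. Macro metrics are averaged per fold,
then across folds. Model comparison uses the two-sided Wilcoxon
signed-rank test on paired per-subject accuracies (zero differences
dropped, exact null for n ≤ 25); the reported statistic is signed,
W₊ − W₋, so swapping the models flips its sign.

## Synthetic data

The generator emulates the *structure* of the 62-channel film-clip emotion
benchmarks: 15 subjects, balanced classes (45 trials/subject, 3 classes;
or 72 trials/subject, 4 classes), trial lengths uniform in [185, 265] or
[12, 64] frames, 200 Hz raw signals or DE-shaped tensors. Planted signal,
defaults chosen once as a plausible desk-scale stand-in:

* **Band signatures** — each class multiplies the power of one
  characteristic band (α, β, γ, θ in class order) by 2.5 in the informative
  electrodes, i.e. a DE shift of ln 2.5 ≈ 0.92 against unit noise.
* **Class-dependent coupling** — designated electrode pairs (8 for the
  full layouts, 5 for tiny) share a frame-wise latent source with
  class-specific correlation (0.9/0.55/0.2 for three classes), so the
  discriminative information is partly relational.
* **Subject shifts** — per-subject additive offsets on each electrode-band
  (sd 0.3) plus per-subject channel-gain jitter (sd 0.05); this is what
  makes LOSO genuinely harder than a random split.

Raw-signal generation colors each channel in the frequency domain
(complex-Gaussian content with a 1/√f envelope per band) so all five bands
carry non-degenerate power. All randomness flows from one seed through a
subject → trial splitting scheme.

What passing tests show: the architecture can learn planted cross-subject
band and coupling structure well above chance, and its learned adjacencies
rank the planted pairs above background. What they do not show: performance
on real EEG — the generator has no artifacts, no nonstationarity, no
volume-conduction correlation structure, and its class effects are far
cleaner than real emotion correlates.

## Problem sizes and study settings

The synthetic study runs on the tiny preset: 6 subjects × 12 trials,
16 electrodes, frames padded to 40, reduced conv maps 16/32/64 and 1×2
pooling (temporal chain 40→36→18→14→7→3→1). Study training uses learning
rate 1e−3 with a 15-epoch cap — a desk-scale choice for the small, clean
synthetic task; the package default TrainConfig keeps the protocol values
(1e−5, cap 500). The top-k comparison (k = 10 vs k = N) averages LOSO mean
accuracy over 3 training seeds per setting, because a single seed's
fold-level noise is comparable to the quoted 5-point band.

## Known limitations

* The autodiff core is single-threaded numpy; full-montage (62-electrode)
  training is functional but slow, and desk-scale experiments use the tiny
  preset.
* MAT import supports pre-v7.3 files only and requires a JSON manifest for
  labels; trial variables are detected by array shape.
* λ_max is fixed at 2 rather than computed per sample; for Laplacians with
  smaller spectral radius the Chebyshev basis is mildly non-orthogonal,
  which the learnable coefficients absorb.
* The dense per-sample softmax adjacency is O(N²) in memory; no sparse
  kernels are used after top-k.
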