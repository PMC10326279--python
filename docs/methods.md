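# Methods

## Problem and model

Overnight polysomnography (PSG) is scored in 30-second epochs into five
stages — W, N1, N2, N3, REM. Stage N1 is the low-resource class: it is
rare (~3–5 % of epochs in adult cohorts), has almost no characteristic
grapho-elements, and human scorers decide it largely from the
surrounding epochs. Naive class rebalancing (oversampling or weighted
losses) raises N1 recall at a disproportionate cost to every other
stage. This package implements a two-branch network plus a scheduled
("transitive") loss that trades those two failure modes off explicitly,
and a synthetic PSG generator that reproduces the phenomenon so the
trade-off is testable without any restricted clinical dataset.

### Feature extractor

Input is one 30-s, five-channel epoch (C3, C4, left/right EOG, chin
EMG) at 125 Hz: a 5 × 3750 tensor in μV. A stem BatchNorm standardises
the raw μV scale (stage-dependent RMS spans roughly 3–80 μV; without
the stem layer the residual projection path carries that scale past
every internal normalisation and saturates the softmax heads). Three
cascaded 1-d attention residual blocks follow. Each block is

    Conv(k=7, stride s) → BN → ReLU → Conv(k=7) → BN  →  F (C × T)
    F ⊙ M_C ⊙ M_T  + skip(1×1 conv)  → ReLU

with two parameter-light attention maps computed from F:

* channel attention `M_C = softmax(MLP(avgpool_t F) + MLP(maxpool_t F))`,
  one shared squeeze-and-excitation MLP (bottleneck C → C/r → C,
  r = 16) for both pooled descriptors, softmax over channels — so M_C
  lies on the simplex;
* temporal attention `M_T = 1 + softmax_t(maxpool_c F)`, parameter-free;
  the cascaded softmax bounds the per-step gain strictly inside (1, 2)
  and the excess mass Σ(M_T − 1) is exactly 1.

Each block downsamples time by stride 4 on its first convolution
(3750 → 938 → 235 → 59); a global average pool yields the epoch feature
vector, 256-dimensional at full scale (block widths 64/128/256).

### Two-branch classifier

* **ELB** (epoch learning branch): fully connected 256 → 128 → 5 on the
  centre epoch's features; learns universal single-epoch patterns.
* **SLB** (sequential learning branch): fully connected
  1280 → 512 → 128 → 5 on the concatenated features of the
  2N+1-epoch context window (N = 2); learns contextual decisions.

At test time the stage is `argmax[ α·p_ep + (1−α)·p_seq ]` with
α = 0.5 by default; ties resolve to the first stage in W, N1, N2, N3,
REM order. α < 0.5 favours contextual (transition-heavy) scoring,
α ≥ 0.5 favours macroscopic structure.

### Transitive training

The loss on a batch is

    L = α·L_ep + (1−α)·L_seq,      α = 1 − (T / T_max)²

where T indexes training epochs (blocks of `epochs_per_train_epoch`
iterations; 3 500 at full scale) and T_max is their total. L_ep is the
unweighted cross-entropy of the ELB; L_seq is the class-weighted
cross-entropy of the SLB with weights `w_c ∝ 1/n_c` over training-set
counts, normalised to mean 1 so the mixture stays a meaningful convex
combination. The weighted mean divides by the batch's weight sum
(unbiased under imbalanced batches). Probabilities are clamped at
1e-12 before the log.

Two structural rules make the schedule work:

* **Gradient gating.** The SLB consumes *detached* feature vectors, so
  L_seq backpropagates only into the SLB; feature-extractor gradients
  equal α·∂L_ep/∂θ exactly. The extractor therefore learns the
  majority-class patterns first and is never dragged by the rebalanced
  loss.
* **Eval-mode context features.** Because the detached features carry
  no gradients, they are computed with running BatchNorm statistics.
  The SLB then trains on exactly the feature distribution it sees at
  inference; with batch statistics instead, the branch suffers a
  train/eval shift the ELB does not, and in scaled-down runs it ended
  up contributing nothing to the mixture.

Optimisation is Adam (lr 1e-3 at full scale, ×0.1 step decay after 70 %
of iterations, mini-batch 200, 140 000 iterations). Validation runs at
every training-epoch boundary; the checkpoint with the highest
validation macro-F1 is kept (ties: later epoch). Batches are plain
shuffled samples — no class-balanced sampling, since avoiding
resampling is the point of the method.

### Ablation regimes

`run_rebalancing_comparison` trains three objectives on byte-identical
data and batch streams: **none** (ELB removed, unweighted sequence
loss), **weighted** (ELB removed, class-weighted sequence loss) and
**transitive** (the full method). In the SLB-only regimes the sequence
loss trains the CNN directly (there is no other gradient source), and
prediction uses the sequence branch alone.

## Synthetic PSG generator

The generator defines the study conditions for every experiment here.

**Hypnograms** are sampled from a five-state Markov chain. The default
transition matrix is built by detailed balance from symmetric
stage-pair flows (W↔N1 strong, N1↔N2, W↔N2, N2↔N3, N2↔REM, small
W↔REM, N3↔W and N1↔REM), with per-stage self-flows absorbing the rest,
so its stationary distribution equals the target overnight proportions
*exactly*: W 28.7 %, N1 3.7 %, N2 41.0 %, N3 12.6 %, REM 14.0 %
(typical of a large adult cohort). The flow sizes give N1 a mean bout
length of two epochs (a brief gateway between W and N2) and stage
persistence probabilities of 0.90–0.93 elsewhere. Reversibility is a
simplification — real sleep cycles are directional — but marginal
proportions and short-range transition structure are what the methods
under test consume.

**Signals** are sums of FFT-shaped band-limited Gaussian noise per
channel and stage (alpha-dominant W, theta-dominant N1, delta-dominant
N3, mixed-frequency REM), plus scheduled transients: 13 Hz spindle
bursts and biphasic K-complex-like waves in N2, slow eye movements in
N1 and rapid eye movements in REM (mirrored across the two EOGs), and a
chin-EMG tone ordered W > N1 > N2 > N3 > REM. Amplitudes (RMS μV) are
in the physiological range and everything stays within ±500 μV.

**The ambiguity dial λ ∈ [0, 1]** makes N1 context-dependent: each N1
epoch's synthesis parameters are blended `(1−λ)·N1 + λ·disguise`, where
the disguise is the nearest non-N1 neighbour stage in {W, N2} (coin
flip if none). At λ = 1 a single-epoch linear probe on band powers
cannot tell N1 from its disguise classes, while a probe that also sees
the ±2 neighbouring epochs stays well above chance — exactly the
mechanism the two-branch method must exploit. Experiments here use
λ = 0.8.

What the generator does *not* emulate: 1/f background spectra, real
spindle/K-complex morphology and density statistics, artifacts,
arousals, apnea events, inter-subject variability, or directional sleep
cycles. Passing tests therefore demonstrate that the training machinery
produces the predicted *qualitative* trade-off under controlled
class-imbalance and context-dependence — not clinical-grade staging
accuracy on real PSG.

Datasets for training are synthesised directly at the 125 Hz analysis
rate. The EDF export path synthesises at 250 Hz instead so that the
full preprocessing chain (filter → clip → resample) is exercised
end-to-end.

## Preprocessing

EEG/EOG are band-pass filtered 0.3–35 Hz and EMG high-pass filtered at
10 Hz; samples are saturated at ±500 μV; channels are resampled to
125 Hz (polyphase, exact for the rational rate ratios common in EDF).
Nothing else — no normalisation, artifact rejection or re-referencing.

Filtering uses MNE's windowed-FIR design (zero phase, delay
compensated) rather than forward-backward IIR. At a 0.3 Hz cutoff the
backward IIR pass excites a pole transient (time constant ≈ 1.4 s) at
the pad/data junction that contaminates the record tail with artifacts
comparable to the signal amplitude; the FIR response is compactly
supported and its interior attenuation matches the kernel's magnitude
response to better than 0.1 %. Edge transients still exist for any
finite-record filter — they span about half the kernel (~5 s at 0.3 Hz)
at each end — so steady-state attenuation is measured on the interior
of a record. The ±500 μV saturation is re-applied after resampling
because interpolation overshoots hard-clipped plateaus (about 4 % was
observed next to saturated spikes).

Epoch i covers samples [i·3750, (i+1)·3750). UNSCORED epochs are
dropped from training and evaluation but remain as raw temporal context
for their neighbours; context windows replicate the edge epoch beyond
record boundaries (zero epochs would be out-of-distribution for the
CNN).

## Evaluation

Confusion matrices store counts with human labels on rows, in fixed
W/N1/N2/N3/REM order; row-normalised percentages are a rendering.
Accuracy, Cohen's κ = (p_o − p_e)/(1 − p_e), per-stage recall and
macro-F1 (the model-selection criterion) follow the standard closed
forms; both κ and MF1 are cross-checked against scikit-learn on random
matrices to 1e-10. An epoch is *stable* when both within-record
neighbours share its label, otherwise *transitional*; first and last
epochs count as transitional so the two sets partition each record.
By-record reporting omits (rather than zeroes) stages absent from a
record's human scoring and averages MF1 over the present stages.

## Numerical substrate

The network and training loop run on a small reverse-mode autodiff
engine over numpy arrays (`somnoscore.autodiff`): exactly the operator
set the model needs, with convolutions lowered to im2col matrix
products. Gradients follow the forward dtype, so the test suite
verifies every operator against float64 central differences while
training runs in float32. Argmax tie-breaks, probability clamping
(1e-12) and the BatchNorm epsilon (1e-5, momentum 0.1) are fixed; with
a fixed seed the whole pipeline — simulation, batching, optimisation —
is bit-reproducible on a given platform.

## Scaled experiment sizes

Full-scale training (140 000 iterations, batch 200, block widths
64/128/256) is out of desk scope. The package's experiments use block
widths 8/16/32, batch 32 and 300 iterations per regime over
12 records × 240 epochs (7 train / 2 val / 3 test, λ = 0.8, three
seeds), with α updated every 30 iterations (T_max = 10). These sizes
were fixed from per-iteration cost measurements on one CPU; the test
split holds three records so that N1 recall is estimated from ~30
rather than ~5 epochs. Smoke and unit tests use still smaller
configurations. The directional claims under test (weighting raises N1
recall; the transitive schedule recalls more N1 than no rebalancing
while keeping higher overall accuracy than full weighting) are
evaluated as seed-majority checks, not as point estimates: at this
scale the sequence branch receives only ~85 effective gradient steps
(the α-schedule discounts early ones), so its contribution to the
α = 0.5 mixture is near its detection threshold and individual seeds
can fall either way.

## Known limitations

* The simulator's λ-mechanism makes N1 ambiguous against W/N2 only;
  real N1 also blends into REM.
* Reversible transition dynamics; no ultradian cycle structure.
* The attention-map strict bounds (M_C > 0, 1 < M_T < 2) hold in exact
  arithmetic; in float32 at long temporal lengths softmax entries can
  round to 0 or 1, touching the closed interval.
* Scaled runs select checkpoints after as few as ten validation points;
  at full scale model selection sees 40 training epochs.
* EDF support is intentionally minimal: uniform-rate voltage channels,
  no annotations, no EDF+ discontinuities.
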