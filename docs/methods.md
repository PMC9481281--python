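# Methods

`anobeat` detects abnormal heartbeats by *one-class* (outlier) detection:
an adversarial autoencoder built from temporal-convolutional residual
blocks is trained only on normal beats, and a beat is flagged abnormal
when its anomaly score exceeds a threshold fitted on the training scores.
This note records the model, its assumptions, the defaults and why, and
what the synthetic data generator does and does not establish.

## Problem setting and model

The unit of analysis is a single-lead ECG beat: 250 samples at 360 Hz,
100 samples before and 150 after the R peak, min-max normalized to
[−1, 1]. Training data contain only normal sinus (N) beats; at test time
the detector must separate N from the four arrhythmic classes A (atrial
premature), L (left bundle branch block), R (right bundle branch block)
and V (ventricular premature) it has never seen.

Three subnetworks operate on beats `x ∈ [−1,1]^250`:

* **Encoder** `z = E(x) ∈ ℝ^8`: three TCN residual blocks with 32, 16
  and 8 filters, each followed by max-pooling ×5 (250 → 50 → 10 → 2),
  then flatten (16) and a ReLU dense layer to the 8-dimensional latent
  code.
* **Decoder** `x' = D(z)`: dense to 16, reshape to 2×8, three rounds of
  nearest-neighbour upsampling ×5 followed by TCN blocks (8→8, 8→16,
  16→32), and a final kernel-9 causal convolution to one channel with
  tanh output. Upsampling repeats the time axis only; channel changes are
  carried by the TCN blocks (an upsampling layer cannot change channel
  count). The tanh head, rather than ReLU, is used because normalized
  beats are signed; a ReLU head is available via
  `ModelSpec(decoder_output_activation="relu")`.
* **Discriminator** `D_adv(x) ∈ (0,1)`: the encoder trunk plus dense(8,
  ReLU) → dense(1, sigmoid), trained to tell original beats from
  reconstructions.

Each TCN block is `ReLU(skip(x) + F(x))` with `F` = two weight-normalized
dilated causal convolutions (kernel 9), each followed by ReLU and dropout
(rate 0.05, disabled at inference). The skip path is the identity, or a
kernel-1 convolution when the channel count changes. Dilations grow 1, 2,
4 across the three blocks of a stack, giving a receptive field of
`1 + Σ 2·(k−1)·d = 113` samples (~0.31 s at 360 Hz) — enough to span a
QRS complex and its neighbourhood. "Causal" means output `t` depends only
on inputs `≤ t`, enforced by left zero-padding of `(k−1)·d`.

### Training objective

Per batch of normal beats, two alternating Adam updates:

1. **Discriminator**: descend the binary cross-entropy
   `−[log D_adv(x) + log(1 − D_adv(x'))]` on originals vs
   reconstructions.
2. **Autoencoder**: descend `MSE(x, x') + γ·(−log D_adv(x'))`. The
   generator term is the non-saturating form (the literal
   `log(1 − D_adv)` of the minimax objective has vanishing gradients when
   the discriminator wins early).

MSE is the *mean* squared error per sample, so losses are comparable
across beat lengths. The adversarial weight γ (default 0.05) is small so
reconstruction dominates; γ = 0 recovers a plain autoencoder exactly —
the autoencoder's random streams (initialization, shuffling, dropout) are
separated from the discriminator's so the reduction is bit-exact.

Defaults: Adam lr 1e-3 (AE) and 2e-4 (D), β = (0.5, 0.999), batch 64, up
to 100 epochs with early stopping (patience 10 on the reconstruction-loss
plateau). Because adversarial updates make late epochs oscillate, the
returned model is the *best-reconstruction* checkpoint
(`restore_best=True`), the usual keep-best practice. Epoch reconstruction
losses in the history are end-of-epoch evaluations over the full training
set with dropout off, so they can be reproduced exactly from the saved
parameters; discriminator/adversarial entries are online batch means.

### Scoring and decision rule

For a test beat: reconstruction score `R(x) = MSE(x, D(E(x)))`,
discrimination score `D_adv(x)`, and anomaly score

    a(x) = (1 − λ)·R(x) + λ / max(D_adv(x), 1e-7)

The reciprocal enters because the discriminator assigns *lower*
probabilities to beats it cannot mistake for training-set
reconstructions, so 1/D rises on anomalies. λ defaults to 0
(reconstruction error alone), which makes the detector independent of
the discriminator at inference; the discriminator then acts purely as a
training-time regularizer. The threshold is `T = mean + 1·sd` (sample
sd, n−1) of the training-set anomaly scores; beats with `a(x) > T`
(strictly) are called abnormal. Ties at exactly `T` are normal.

Evaluation treats abnormal as the positive class: ACC, Pre, Rec, F1 from
the confusion counts, and AUC as the Mann–Whitney rank statistic on the
continuous scores (ties ½), which is threshold-free and invariant to
monotone rescaling. Undefined ratios (zero denominators) are reported as
missing, never silently 0.

## Synthetic data generator

No public ECG corpus ships with the package, so every experiment runs on
synthetic beats. A beat is a sum of Gaussian bumps for P, Q, R, S, T on
the 250-sample grid, R anchored at index 100; the normal template has a
P–R interval ≈ 0.16 s and QRS ≈ 0.08 s. Abnormal classes are morphology
caricatures: V drops the P wave, doubles the QRS width and inverts the T;
L has a notched two-lobed broad R; R adds a deep S and a secondary R′
deflection; A advances the P wave by 40 ms at half amplitude. Per-beat
variability is multiplicative amplitude jitter (sd 5%) and width jitter
(sd 3%) per wave, plus additive white noise (sd 0.03 of the unit R
amplitude). Records place beats at a configurable heart rate (default
70 bpm) and add a single-tone baseline wander (0.1 a.u. at 0.3 Hz). One
integer seed drives all randomness through a single generator.

What this establishes — and what it does not: the generator produces
classes that are separable *in morphology space*, with realistic interval
structure, noise and drift, so it exercises every pipeline stage
(resampling from 560 Hz, denoising, segmentation, normalization,
training, scoring). It does not reproduce the within-class diversity,
inter-patient variability, electrode artefacts or rhythm-level context of
clinical recordings, so passing results bound what the implementation
does, not what the method would score on hospital data.

## Preprocessing choices

* **Resampling** (e.g. 560 → 360 Hz): polyphase FIR resampling with the
  rational rate ratio; R-peak indices are rescaled and re-snapped to the
  local |signal| maximum within ±3 samples so the anchor survives the
  grid change. Output length is `round(n·target/fs)`.
* **Denoising**: db6 DWT, default depth 8 at 360 Hz. The deepest
  approximation band (< 0.71 Hz) is flattened to its mean — removing
  baseline wander while keeping any legitimate DC offset (depth 9 was
  rejected: its 0.35 Hz band edge bisects typical wander frequencies and
  left ~24% of a 0.3 Hz tone's power behind). Detail bands are
  thresholded at the universal level `σ·√(2 ln n)`, `σ =
  median(|d1|)/0.6745`, with *hard* thresholding by default: soft
  shrinkage biases the large QRS coefficients enough to worsen the
  reconstruction error of a clean beat at realistic noise levels.
  Wavelet, depth and mode are all arguments. The requested depth is
  capped at `pywt.dwt_max_level` for short signals.
* **Segmentation**: half-open windows `[r−100, r+150)`, 0-based; peaks
  without full context are skipped and counted, never silently dropped.
* **Normalization** is per beat, `2(x−min)/(max−min) − 1`; constant
  (degenerate) beats map to the zero vector so a corrupt lead cannot
  abort a batch run.

## Numerical choices

The networks are implemented directly on numpy (forward passes as
per-tap GEMMs over shifted views; hand-written backward passes verified
against central finite differences in the test suite). Working precision
is float32 for single-core throughput; gradient-check tests and the
convolution oracle run in float64 via a context switch. Weight
initialization is Glorot-uniform from the model seed; weight-normalized
kernels start with `g = ‖v‖` so the initial effective kernel equals its
direction. Probabilities are clamped to `[1e-7, 1 − 1e-7]` before logs;
the discriminator score is floored at `1e-7` before the reciprocal in
`a(x)`. Max-pooling breaks ties by first occurrence (argmax). Runs are
bit-reproducible for a fixed seed on a fixed BLAS backend.

## Scaled experiment

The packaged experiment trains on 2,000 synthetic normal beats and tests
on 500 normal + 500 abnormal beats (uniformly mixed A/L/R/V), with 20
training epochs — a problem size chosen so a full run takes a few
minutes on one CPU core while leaving the separation pattern intact:
mean reconstruction error on held-out normal beats sits near the
training level, abnormal beats score an order of magnitude higher, and
AUC is well above 0.9 across seeds. `scripts/acceptance.py` reruns this
end to end and reports ACC/Pre/Rec/F1/AUC, the fitted threshold and the
per-class mean reconstruction errors.

## Known limitations

* Synthetic morphology is a five-class caricature; no dynamical-system
  ECG model, no multi-lead synthesis, no rhythm-level arrhythmias.
* The adversarial game is kept mild (small γ, slow discriminator); the
  implementation makes no claim about GAN stability at other settings.
* WFDB interop (`read_wfdb_record`) needs the optional `wfdb` package;
  without it, records travel through the package's plain-text format.
* Scores are per-beat; the multi-beat clinical decision rules that a
  monitoring system would layer on top are out of scope.
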