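# Methods

## Problem

Remote photoplethysmography (rPPG) estimates the blood-volume pulse — and
from it the heart rate — from the tiny periodic color fluctuations that
cardiac perfusion induces in skin observed by an ordinary RGB camera. The
package implements a compact 3-D convolutional encoder-decoder that maps a
clip `x ∈ R^{3×T×H×W}` to a waveform `ŷ ∈ R^T`, trained against a contact
PPG reference resampled to the frame rate, plus the surrounding toolkit:
spectral deep supervision, STFT heart-rate evaluation, a channel-width
cost-function optimizer, layer visualization, and a synthetic pulse-video
generator that makes all of it testable without human video.

## Network

Twelve convolutional layers in the PhysNet encoder-decoder lineage:

| stage | layers | kernel | output (T, spatial) |
|---|---|---|---|
| stem | 1 conv + BN + ReLU + maxpool (1,2,2) | (1,5,5) | T, H/2 |
| encoder1 | 2 convs + maxpool (2,2,2) | (3,3,3) | T/2, H/4 |
| encoder2 | 4 convs + maxpool (2,2,2) | (3,3,3) | T/4, H/8 |
| encoder3 | 2 convs + maxpool (1,2,2) | (3,3,3) | T/4, H/16 |
| decoder1, decoder2 | transposed conv + BN + ELU each | (4,1,1), stride (2,1,1) | T/2 then T, H/16 |
| head | spatial mean + 1×1×1 conv | (1,1,1) | T |

All convolutions are stride-1 with 'same' padding and carry bias plus affine
batch normalization. Channel widths are the tunable architecture
hyperparameters: `baseline` = stem 32, encoders 64/64/64, decoders 64/64
(866,689 parameters); `dse` = 16/16/16/16, decoders 2/2 (57,087 parameters);
the intermediate `encoder16` preset (77,857 ≈ 78 k) marks the encoder sweep's
stopping point. These three counts are the anchors that pin the
reconstruction; the printed activation size of one encoder layer (56×56 from
a 128×128 input) cannot be met simultaneously with the fixed layer counts
under any uniform padding rule, so same-padding (giving H/2 = 64) was chosen
and the parameter anchors kept.

Weight initialization is fan-in-scaled Gaussian with a recorded seed.
Everything — forward, backward, Adam — is implemented on numpy in float32;
every backward pass is pinned by float64 finite-difference tests (worst
relative error observed ≈ 3e-10).

## Spectral maximum cross-correlation loss

For mean-centered reference `y` and prediction `ŷ` of length N at rate fs:

    MCC = c_pr · max_k r[k] / (N σ_y σ_ŷ)

where `r` is the cross-correlation of the band-limited signals and
`c_pr = (in-band power of y) / (total non-DC power of y)` is a constant with
respect to the prediction. Numerical pipeline:

1. mean-center both signals; σ are their (population) standard deviations;
2. band-limit each signal by exact frequency-bin masking on its native
   N-point grid, keeping |f| ∈ [40, 180] bpm — on the native grid an
   in-band tone passes untouched, so a perfect match scores exactly
   c_pr = 1;
3. zero-pad to the next power of two ≥ 2N and compute the cross-correlation
   by FFT, so the lag scan is linear, not circular;
4. take the maximum over all lags, normalize, scale by c_pr.

Two consequences worth stating plainly. First, a k-sample delay loses the
non-overlapping k/N fraction of correlation mass under linear correlation —
that loss is irreducible for any non-circular implementation; what the lag
max removes is the *phase* penalty (a half-period delay would otherwise
score −1, the failure mode the loss exists to avoid). Second, masking on
the native grid rather than the padded grid is what makes the statistic
agree with a direct time-domain lag-scan oracle to 1e-6 and keeps tones
exact; masking the padded grid instead would leak ~1.5% of a tone's energy
out of band.

Degenerate (constant) inputs raise rather than return 0, to surface label
bugs early. The losses return analytic gradients with respect to the
prediction (the max's winning lag treated as locally constant); gradients
are finite-difference checked. Comparison losses: MSE, negative Pearson
correlation, and both signs of MCC, selectable by the strings
`mse | negpcc | mcc | negmcc`.

## Deep supervision

Each of the six block outputs (stem, three encoders, two decoders) is
spatially averaged into a (C, T_l) matrix — a pure reduction, so supervision
adds zero trainable parameters (asserted against the parameter counter).
The channel-mean trace is compared by NegMCC against the label linearly
interpolated down to T_l (the in-band spectral peak lands at the same
physical frequency at the layer's effective rate fs·T_l/T). Each auxiliary
term carries weight 0.1 relative to the primary loss. Alternatives exposed:
`channel_mode="per_channel"` averages per-channel losses instead of
channels; the tap set is configurable. Zero-variance traces (routine in the
first batches) are skipped per batch with a logged warning — a constant
trace has no defined direction under a correlation loss. Note that conv
biases immediately followed by batch normalization receive exactly zero
gradient (the BN mean subtraction absorbs them); the gradient-flow test
therefore checks weights and BN affine parameters.

## Training

Adam with learning rate 1e-4, weight-decay coefficient 0.1 (added to the
gradient), batch size 6, default 100 epochs, all seeded. Validation runs
every epoch: predictions and references go through the same preprocessing
and STFT estimator, and the history records per-epoch losses and validation
heart-rate RMSE, from which epochs-to-threshold statistics are derived.

## Heart-rate evaluation

Signals are bandpassed to 40–180 bpm by frequency-bin masking (the same
filter family as the loss), standardized, then analyzed with a sliding
short-time Fourier transform: 5 s Hann window, 0.1 s step, each window
zero-padded to ≥ 2048 samples so the frequency grid is finer than 1 bpm at
typical frame rates; the window's heart rate is the in-band magnitude peak.
Metrics are RMSE, MAE and Pearson correlation over aligned window grids,
pooled over clips; identical constant series report PCC 1 with an explicit
`pcc_defined=False` flag. Repeated-run comparisons use mean ± sd over runs
and Welch's two-sided t-test at α = 0.05, because run-to-run retraining
variability exceeds typical architecture effects.

## Channel-width optimization

A sweep trains the network at widths α ∈ {1, 2, 4, …, 64} and records mean
heart-rate RMSE ε(α) and exact parameter count P(α). The selected width
minimizes ε(α) + λP(α) with λ = σ_ε/σ_P (standard deviations across the
sweep), the normalization that gives both addends equal spread. Cost ties
break toward fewer parameters. The protocol is sequential: encoder axis
(stem + all encoder blocks jointly) with the decoder at baseline width,
then the decoder axis (both layers jointly) at the selected encoder width.

## Synthetic data

A clip is an elliptical "skin" patch in a textured frame whose color is
modulated by a PPG-shaped waveform: fundamental at 45–170 bpm, second
harmonic at 0.3 relative amplitude, 0.1 Hz baseline wander of amplitude 0.1,
additive waveform noise (sd 0.05), all standardized. The rendering adds
green-dominant modulation (R:G:B ≈ 0.5:1:0.4, green amplitude 0.02 of a
~0.45 base level, mimicking hemoglobin absorption ordering), a per-subject
static texture (sd 0.02), shared per-frame illumination fluctuation
(sd 0.005), per-pixel sensor noise (sd 0.01), a smooth bounded random walk
of the patch position (default 1 px), and optional 8-bit quantization.
Subjects (one base color + texture identity) are disjoint across
train/val/test splits. A handcrafted oracle — mean green intensity over the
skin ellipse, bandpass, STFT — achieves < 2 bpm RMSE at default noise,
establishing that the dataset is solvable before any learning; oracle error
grows with weaker modulation and with motion.

What the generator deliberately omits: face geometry, expressions, specular
and shadow lighting, compression artifacts, and heteroscedastic sensor
models. Passing tests therefore demonstrate that the learning machinery —
architecture, losses, supervision, evaluation — works end to end on data
with the assumed statistical structure, not performance on real faces.

## Study conditions for the end-to-end tests

Single-CPU numpy training budgets the geometry: 16×16 pixels, 128 frames at
25 Hz (5.12 s, exactly one 5-s evaluation window), 50 clips (30/10/10
subject-exclusive), the `dse` configuration, MSE primary + deeply
supervised NegMCC, 15 epochs of the published optimizer recipe. Under these
conditions the trained network reaches ~1 bpm test RMSE (threshold 5 bpm).
The convergence comparison follows the repeated-run averaging protocol:
validation-RMSE curves are averaged over 5 seeds per arm and the
epochs-to-10-bpm of the averaged curve compared between deep supervision
and no supervision. At this easily learnable desk scale both arms converge
within a few epochs and the supervised arm is no slower (a tie in the
current conditions); the large absolute acceleration reported on real data
should not be expected from a synthetic task this easy.

## Known limitations

- No GPU path; benchmark-scale inputs (128×128×256) forward fine but training
  at that scale on one CPU is impractical.
- The MCC gradient treats the winning lag as constant (subgradient of max),
  standard but locally non-smooth when two lags tie.
- BatchNorm statistics make the loss batch-composition dependent during
  training (inference uses running statistics and is deterministic).
- The HR estimator reports the in-band argmax only; no harmonic
  disambiguation (the 40–180 bpm band plus the generator's harmonic ratio
  keep this unambiguous in practice).
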