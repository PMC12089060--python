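# Methods

This note records the models, the synthetic-data design, the numerical
choices and the known limitations of `eegadvdenoise`. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing
is quoted from external measurements.

## Problem setting

The target signal is multichannel scalp EEG sampled at 128 Hz, restricted
to the 8–30 Hz band covering the alpha (8–12 Hz) and beta (13–30 Hz)
rhythms that dominate motor-imagery work. Contamination is modeled as
additive: slow ocular drift, bursty 20–60 Hz muscle activity, mains
interference, and 1/f or white sensor noise. A denoiser maps a noisy epoch
(a fixed-length window, default 512 samples = 4 s) to an estimate of its
clean counterpart.

Because a genuinely clean EEG recording of the *same* brain activity does
not exist, supervised training and honest scoring both rely on
**semi-synthetic pairing**: segments that pass a low-artifact screen serve
as clean references, and noise of a chosen kind is added at an exact
target SNR. The pair `(clean, noisy)` is then ground truth by
construction.

## Preprocessing

- **Band-pass** 8–30 Hz: windowed-sinc FIR designed and applied
  forward–backward (via MNE), i.e. zero-phase. Phase linearity matters
  here because two of the eight evaluation metrics (CC, DTW) measure
  temporal alignment; an IIR filter's group delay would bias them.
  Transition width 2 Hz per edge (configurable); the filter is ~211 taps
  at 128 Hz, so inputs must be longer than that.
- **Min–max normalization** per channel onto [0, 1], matching the
  sigmoid-headed generators' output range. The per-channel extrema are
  retained, so the transform is exactly invertible. A constant channel has
  no range and maps to 0.5 with a warning — flat fixtures should flow, not
  crash. Filtering runs before normalization by default (filtering after
  would push values outside [0, 1]); both orders are possible by calling
  the steps directly.
- **Epoching**: non-overlapping 512-sample windows by default. 512 is
  4 s at 128 Hz and divisible by 16, the temporal downsampling factor of
  the full discriminator.
- **Shape enforcement** pads by edge replication, never zeros — a zero
  step at the boundary would ring through any subsequent filter.

## Synthetic data

`simulate_clean_eeg` builds each channel as
`a·alpha + b·beta + 0.3·background` where alpha and beta are unit-RMS
band-limited Gaussian noise (spectral bumps at 10 Hz with σ = 1 Hz and
20 Hz with σ = 1.5 Hz) and the background is unit-RMS 1/f noise;
amplitudes a ~ U(1, 2) and b ~ U(0.7, 1.5) are drawn per channel. Band
components are filtered noise rather than pure tones so that correlation
and DTW between different epochs behave like real data rather than like
phase-shifted copies of one sinusoid.

Artifact models (all seeded, all scaled analytically to the target SNR so
that `10·log10(P_clean/P_noise)` is exact):

| kind | construction | spectral signature |
|---|---|---|
| white | Gaussian i.i.d. | flat |
| pink | 1/√f spectral shaping | 1/f power |
| ocular | low-passed random walk + Gaussian blink pulses (~0.1 s, 3–6× amplitude) | > 80 % of power below 5 Hz |
| muscle | 20–60 Hz Gaussian noise under a smoothed on/off envelope (floor 0.2) | > 80 % of power above 20 Hz |
| line | fixed 50 Hz sinusoid, random phase per channel | single spectral line |

The low-artifact screen replaces manual inspection with a deterministic
rule: a non-overlapping window survives if every sample of every channel
stays within `z_threshold` (default 3) standard deviations of its
channel's mean. The default SNR grid is {−5, 0, 5, 10} dB. Pair
construction draws one child seed per pair from the master seed, so any
single pair can be regenerated in isolation.

What the generator does **not** emulate: volume conduction and
inter-channel correlation (channels are independent), non-stationarity of
rhythms over minutes, event-related structure, and real artifact
waveshapes (e.g. true EOG templates). Passing tests therefore demonstrate
algorithmic correctness and relative method behavior under controlled
contamination — not clinical performance on recorded EEG.

## Architectures

All networks operate on [0, 1]-normalized epochs and are built on the
package's own reverse-mode autodiff engine (float64, CPU). Every VJP in
the engine is expressed through the engine's own ops, so gradients are
differentiable graph nodes and the second-order term required by the
gradient penalty (gradient of a gradient norm with respect to weights)
falls out naturally.

- **LSTM generator**: single recurrent layer (default hidden size 64,
  h₀ = c₀ = 0) with forget/input/output gates and a candidate cell state,
  followed by a per-timestep linear map and a sigmoid (tanh and identity
  heads selectable). Channels enter as per-timestep features, so output
  length always equals input length.
- **Residual generator**: stride-2 initial conv (64 filters, kernel 3) →
  16 residual blocks (two conv+batch-norm pairs each, skip connection,
  ReLU) → stride-2 transposed conv restoring the length → output conv +
  sigmoid. The down/up stride-2 pair is what lets the transposed
  convolution double the length while the network as a whole preserves it;
  epoch lengths must be even.
- **Discriminator/critic**: eight conv layers, kernel 3, strides
  alternating 1 and 2, filters 64, 64, 128, 128, 256, 256, 512, 512
  (doubling every two layers), batch norm on all but the first layer,
  LeakyReLU slope 0.2; a projection conv widens to 1024 features before
  flattening, making the flattened width 1024·L/16; one dense unit ends in
  a sigmoid (probability) or stays linear (Wasserstein critic). Epoch
  lengths must be divisible by the downsampling factor (16 at full depth).
  Batch norm is retained in the critic as the architecture's default even
  though layer norm is more customary under a gradient penalty;
  `norm ∈ {batch, layer, none}` is configurable. During the penalty's
  forward pass the running statistics are snapshotted and restored —
  interpolates are auxiliary points, not data.

Zero-initialized networks have exact fixed points (sigmoid heads 0.5,
linear heads 0) that the test suite uses to pin the wiring; parameter
counts are asserted against closed-form expressions to catch silent
architecture drift.

## Training

Three regimes share one loop skeleton, all optimized with Adam
(β = (0.5, 0.999)):

- **lsgan** — one discriminator update (squared-error labels y_real = 1,
  y_fake = 0, halved sum) and one generator update (adversarial
  least-squares term, weight 1.0 by default, plus MSE content term) per
  minibatch. Defaults: lr_g = 2e-5, lr_d = 2e-3 (the 100× asymmetry is
  kept as configured defaults), batch 32, 15 epochs.
- **wgan_gp** — critic loss E[D(fake)] − E[D(real)] + gp, minimized; the
  printed Wasserstein objective is a maximization, so the implementation
  negates it to drive a standard minimizer. gp = λ·E[(‖∇ₓD(x̃)‖₂ − 1)²] at
  x̃ = ε·real + (1−ε)·fake, ε ~ U(0,1), λ = 10. Five critic steps per
  generator step; generator loss −E[D(fake)]. Defaults: lr 2e-5 both,
  batch 64, 25 epochs.
- **wgan_nogp** — identical schedule with the penalty removed (no weight
  clipping either).

Seeding: the config seed spawns three named child streams — parameter
init, batch shuffling, ε draws — so runs are bit-reproducible and the ε
stream cannot perturb the shuffle stream. A consequence the tests exploit:
`wgan_gp` with λ = 0 walks the *exact* parameter trajectory of
`wgan_nogp`, a strong continuity check on the penalty's implementation.

Early stopping (off by default) monitors content loss on a 90/10 held-out
split with configurable patience. Any non-finite loss aborts with the
partial trace attached.

## Evaluation

Eight metrics, each computed per (channel, epoch), averaged over epochs to
one value per channel, then summarized across channels as mean ± SD:

- SNR = 10·log10(Σref²/Σ(est−ref)²) dB; PSNR = 10·log10(peak²/MSE) dB with
  peak = 1 on normalized signals (hence PSNR ≥ SNR whenever
  mean(ref²) ≤ 1). Perfect reconstruction yields +∞, serialized as the
  explicit token `"Infinity"`, never as a large float.
- RRMSE = RMS(est−ref)/RMS(ref); MAE; SD = population standard deviation
  of the residual (an `sd_mode="signal"` alternative reports the SD of the
  estimate instead, since either reading is defensible).
- MI: joint histogram over 64 equal-width bins per signal (clamped to the
  epoch length), in bits. Constant signals collapse to one bin (MI = 0).
  The estimator is cross-checked in tests against an independent
  contingency-table implementation.
- CC: Pearson correlation (errors on constant input).
- DTW: classic O(n·m) dynamic program, |a_i − b_j| local cost, steps
  (1,0), (0,1), (1,1), endpoints matched, no window, no path-length
  normalization; numba-accelerated with a pure-Python fallback, and
  verified against exhaustive warping-path enumeration for short
  sequences.

## Baselines

- **Wavelet thresholding**: sym8, 4 levels (clamped to the maximum
  meaningful depth for short epochs), soft universal threshold
  σ·√(2·ln N). σ is the MAD/0.6745 estimate from the *finest* detail band
  — the standard white-noise estimator. Estimating σ per band was tried
  and rejected: coarser bands carry the 8–30 Hz rhythms themselves, so
  per-band thresholds shrink the signal away with the noise. sym8 was
  chosen over shorter Daubechies filters for its lower leakage of ~20 Hz
  content into the finest band, which otherwise inflates σ.
- **Wiener filtering**: short-time spectral filter, Hann window (default
  256 samples) at 50 % overlap, per-bin gain max(0, 1 − P_n/P_x),
  overlap-add synthesis. The input is reflect-padded by half a window so
  every sample has full frame coverage (without this the synthesis
  normalization vanishes at the edges and the division amplifies modified
  edge frames). The noise spectrum comes from the known injected noise
  power when clean references are available (the estimator's `fit`
  measures it from X − y), otherwise from the median periodogram of the
  top quarter of the spectrum.

## The reduced (smoke) profile

Desk-scale CPU runs use a deliberately scaled-down configuration: one
simulated channel, 100 s of signal, 64-sample epochs, white noise at 0 dB,
~180 pairs with an 80/20 train/test split, a reduced discriminator
(4 layers, 8 base filters, 32-feature projection), LSTM hidden size 32,
8 training epochs, and learning rates raised to 5e-3/1e-3 (lsgan) and
1e-3/1e-3 (wgan) — at a few dozen Adam steps the full-scale 2e-5 rates
would leave the networks indistinguishable from their initialization. The
Wiener window shrinks to 32 samples to fit the epoch.

On this profile (computed by `scripts/acceptance.py`) all five methods
improve mean SNR over the 0 dB noisy input by roughly 5–12 dB. Two honest
caveats. First, on [0, 1]-normalized signals the SNR reference power
includes the DC offset, so even a flat 0.5 output scores well above the
noisy input; SNR gains on normalized data overstate waveform recovery,
which is why RRMSE/CC/DTW are reported alongside. Second, at this training
scale the adversarial models capture the coarse signal structure but not
fine waveform tracking — their CC on held-out pairs is near zero — so the
smoke profile demonstrates that the training machinery works and is
reproducible, not that a few dozen updates yield a production denoiser.

## Known limitations

- Training is CPU/float64 and desk-scale; the full 8-layer discriminator
  with 512-sample epochs is exercised in forward passes and shape/zero
  contracts, not trained to convergence in the test suite.
- Channels are denoised jointly only through the generator's channel
  dimension; no spatial (montage-aware) modeling.
- The LSGAN generator's adversarial-vs-content weight (default 1.0) is a
  free parameter; no scheme for tuning it is provided.
- MI binning (64 equal-width bins) and DTW without a warping window are
  conventions, not optimized choices; both are configurable or easily
  replaced.
- `wgan_nogp` omits both the penalty and weight clipping, so its critic is
  unconstrained; it exists as an ablation, not a recommended method.
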