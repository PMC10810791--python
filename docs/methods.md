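# Methods

## The problem and the approach

Raman scattering is weak (far fewer than one in 10^6 photons), so Raman and
related hyperspectral measurements (TERS nanoscopy, fluorescence and
photoluminescence line-scan imaging) trade signal-to-noise ratio against
acquisition time, laser power and resolution.  Supervised denoisers trained
on matched low/high-SNR spectra of a particular sample generalize poorly to
other samples: they are *sample-dependent*.

This package implements the *noise-learning* (NL) alternative: the quantity
the network learns is the **instrument's additive noise**, not the sample's
signal.  Training data are assembled from two independent sources:

1. **Measured (or simulated) instrument noise.**  Noise-only spectra are
   acquired on a Raman-inactive reference; a smooth Au film on a real
   instrument, the synthetic bank simulator here (`noise.simulate_noise_bank`).
   Each acquisition still contains a large smooth background (photo-
   luminescence plus reflected light).  Arranging the n spectra as the
   columns of an m x n matrix S and taking its SVD separates the two:
   `Noise = S - sum_{j in J} sigma_j u_j v_j^T`, with J the set of background
   components, by default {1} — the first component carries almost all of
   the smooth background.  An automatic surrogate for manually inspecting
   singular vectors is provided: components whose right-singular vectors are
   smooth along the acquisition order (lag-1 autocorrelation above 0.8) are
   flagged as background.

2. **Generated ground-truth spectra.**  Raman line shapes are pseudo-Voigt
   profiles `V = rho*G + (1-rho)*L` — a Gaussian/Lorentzian mixture sharing
   one FWHM, with Gaussian weight rho = 0.6785.  A spectrum is a random
   superposition `R = sum_i A_i V(x; mu_i, w_i)` with the peak count uniform
   on [1, 10], FWHM uniform on [5, 200] cm^-1 and positions uniform on
   [1, 1600] cm^-1 (the confocal-microscope preset); the baseline uses the
   same construction with 1-3 very broad components (FWHM 300-2000 cm^-1).

A noisy spectrum is the plain sum `clean + noise` (the instrumental noise is
treated as purely additive — the dominant terms, photon shot noise on the
background, detector readout and dark current, do not depend on the weak
Raman signal itself).  Because the discrete cosine transform is linear,
`DCT(clean + noise) = DCT(clean) + DCT(noise)` holds exactly, so the pair
(DCT(noisy), DCT(noise)) is a perfectly labelled training example.  The
network maps noisy-spectrum DCT coefficients to noise coefficients; at
inference the predicted noise is inverse-transformed and subtracted:

    denoised = raw - IDCT( AUnet( DCT(raw/s) ) ) * s,   s = max |raw|.

The DCT pair is the *orthonormal* type-II/type-III convention, so the
round trip is exact to machine precision and energy is preserved
(a printed uniform-sqrt(2/N) convention without the 1/sqrt(2) DC factor is
not self-inverse; only round-trip-exact conventions are admissible here).

## Network

A 1-D U-net with channel and spatial attention ("AUnet"):

- encoder: `depth` levels of [conv(k=3) - ReLU - conv(k=3) - ReLU -
  channel attention - spatial attention], followed by factor-2 max pooling;
  channels double per level from `base_channels` (default 32), capped at
  `max_channels` (default 128) to keep the deepest levels affordable;
- bottleneck block of the same shape;
- decoder: factor-2 transposed convolution, concatenation with the matching
  encoder skip, then the same attention conv block; final 1x1 convolution to
  one channel.
- channel attention: global average pool -> bottleneck MLP (reduction 8)
  -> sigmoid, one scale per channel; spatial attention: channel mean and max
  maps -> 7-tap convolution -> sigmoid, one scale per position.  Both gates
  produce factors strictly inside (0, 1), so attention can only attenuate;
  disabling attention yields a plain 1-D U-net with identical contracts.

A global residual connection (on by default) adds the input coefficients to
the network output, so the convolutional stack predicts a *correction*: in
the DCT domain the noise equals the input wherever the smooth signal has no
energy, which makes the identity the natural starting point and speeds up
training considerably at scale.  (For very small smoke models trained for a
handful of epochs the plain mapping converges from the safer "subtract
nothing" side; the flag covers both.)

Inputs of length not divisible by 2^depth are zero-padded symmetrically in
coefficient space and cropped on output; padding touches only coefficients
beyond the measured band.  Inputs and targets are normalized per spectrum by
the maximum absolute intensity of the noisy spectrum (the scale is stored
and undone), making the model amplitude-robust.

The network is implemented directly in NumPy, in (batch, channel, length)
float32 layout, with analytically derived backward passes; convolutions are
lowered to BLAS matrix multiplications (im2col).  Gradient correctness is
verified against central finite differences (in float64) in the test suite.

## Training

- Loss: mean squared error on coefficient vectors (shared with the
  evaluation module's `mse` — the identical implementation is used).
- Optimizer: SGD with momentum 0.9; the initial learning rate is annealed
  to zero by a cosine schedule over the run.  (Momentum, batch size and the
  initial rate are not dictated by the method; the defaults were selected by
  validation loss on the synthetic task and live in `TrainConfig`.  The
  reference configuration uses an initial rate of 0.25 with batch 16 —
  smaller rates underfit noticeably at desk-scale budgets.)
- The noise bank is split 80/20 into train/validation pools *before* any
  pairing, so no noise spectrum leaks across the split.  Training pairs use
  a freshly generated ground-truth spectrum at every step; validation
  ground truths are frozen at run start so validation losses are comparable
  across epochs.  The returned checkpoint is the best-validation-loss one.
- Ground-truth amplitudes are drawn log-uniform on [0.1, 1] relative units
  and then rescaled per pair so the composed spectrum's SNR
  (10 log10(sum x^2 / sum n^2)) hits a target drawn uniformly from
  `target_snr_db` (default [-5, 5] dB) — the noise always stays at
  instrument scale, as it would when pairing measured noise with generated
  spectra.
- The *training* distribution is deliberately broader than the evaluation
  distribution in two respects.  SNR targets are drawn from U(-5, 15) dB: a
  model that never sees strong signals learns to treat tall coherent peaks
  as noise and subtracts them, which shows up as a heavy error tail on
  high-SNR test spectra.  Peak widths use the `mixed` law (each FWHM drawn
  from the uniform or the log-uniform law over [5, 200] cm^-1 with equal
  probability): narrow peaks are the hardest case — their DCT signatures
  are extended oscillation packets that resemble noise locally — and the
  plain uniform law under-represents them.  Both choices concern only what
  the network is shown during training; evaluations use the plain preset
  (uniform widths, SNR U(-5, 5) dB).
- CSL mode (`train_csl`) runs the same loop on a fixed list of matched
  (low, high) spectra with target DCT(low - high); it exists for the
  NL-vs-CSL generalization comparison on synthetic data and is not part of
  the NL pipeline.

Full-scale runs in the original setting use thousands of epochs on a GPU.
The package's reference configuration — used by `scripts/acceptance.py` and
the end-to-end tests — is a desk-scale CPU run: a 1024-channel bank of
2,500 simulated noise spectra, depth-4/base-32 model, batch 16 with
32 steps per epoch for 50 epochs (25,600 training pairs seen).  These sizes
are the package's chosen trade-off between fidelity and turnaround; the
same code scales to larger runs by changing `TrainConfig`.

## Synthetic noise bank

`simulate_noise_bank` emulates a noise measurement on a Raman-inactive
reference: per column, `bg(t) + [Poisson(bg(t) + dark*t) - mean] +
N(0, sigma_r)`, where `bg(t) = background_level * t * shape(x)` and
`shape` is a fixed smooth photoluminescence-like curve.  Defaults:
background 1000 counts/s at the curve maximum, readout sigma 3 counts,
dark rate 10 counts/s, integration times 0.1-0.5 s with 500 spectra each
(2,500 total).  What it does **not** model: multiplicative/heteroscedastic
gain noise, EMCCD gain-register cascades, cosmic-ray spikes, wavelength-
dependent detector response, or correlated readout artifacts.  Tests passing
on this bank therefore demonstrate the pipeline's algebra and learning
behaviour under additive instrument noise, not performance on any particular
real detector.

## Evaluation metrics

- `mse(x, y) = (1/m) sum |y_i - x_i|^2`;
- `snr_db(x, y) = 10 log10(sum x^2 / sum (y - x)^2)` — powers are channel
  sums; the ratio is identical for sums or means so long as both are treated
  alike.  Identical inputs are flagged (warning + infinity), never silent.
- `psnr = 10 log10(1 / mean((Y - X)^2))` with both images first normalized
  by the joint maximum of the pair, making the unit-peak formula
  well-defined;
- `ssim`: mean local structural similarity; local statistics use a Gaussian
  window (width 11, sigma 1.5) with unbiased (co)variance normalization and
  constants c1 = 0.01^2, c2 = 0.03^2 for unit dynamic range.  A `global`
  window mode applies the formula once over the whole image.  The
  implementation is cross-checked against scikit-image in the tests.

## Spatial-resolution estimation

An edge profile across a material boundary is fitted with the logistic step
`y = I2 + (I1 - I2)/(1 + exp(-a(x - b)))`; the FWHM of its first derivative,
`2 ln(3 + 2 sqrt(2)) / |a|` (~3.53/|a|), estimates the imaging resolution.
Initialization: plateau levels from the 10th/90th percentiles, inflection at
the half-crossing, steepness from the central finite-difference slope; both
rising and falling edges converge from this start.  Non-convergence returns
a flagged failure carrying residual diagnostics rather than an exception;
`resolution_over_lines` averages per-line FWHMs (mean +/- sample sd),
skipping failed lines.  Intensity decay along the scan order (probe or
focus drift) is quantified by an ordinary least-squares line `y = Kx + b`.

## Classical baselines

- Savitzky-Golay: local least-squares polynomial, order 2 / window 15,
  mirror padding at the edges.
- Wavelet "BlockJS": sym4 multilevel decomposition (level 3), block
  James-Stein shrinkage of detail coefficients — blocks of length
  floor(log n), shrink factor `(1 - lambda* L sigma^2 / ||block||^2)_+`
  with lambda* = 4.50524, sigma from the median absolute deviation of the
  finest detail band.  The named rule is a published block-thresholding
  scheme whose dialect (wavelet family, block length, constant) is pinned
  here for reproducibility; all three are configurable.

Neither baseline clamps negative values, and neither does the NL pipeline:
noise-subtracted counts may legitimately go negative.

## Numerical and design choices

- Default axis: 1024 channels over 0-1600 cm^-1 (~1.56 cm^-1/px).  A
  power-of-two length avoids padding in the default model; the sampling
  density is configurable to match an instrument (e.g. 1.2 cm^-1/px).
- Spectra are columns of the noise matrix (m = channels); on disk banks are
  stored one spectrum per row with a transposing loader.
- No mean-centering before the SVD: the first singular component is allowed
  to absorb the mean background, which is exactly what removing it exploits.
- Seed fan-out: a run seed is mapped to per-component sub-seeds by hashing
  the component name (`io.derive_seed`), so adding a component never shifts
  the random streams of existing ones; every artifact records its seed and
  config hash.
- Degenerate inputs: zero spectra normalize with scale 1 (no 0/0); a zero
  residual in SNR, or identical images in PSNR, yield a warned infinity;
  an all-zero wavelet noise estimate (sigma = 0) returns the input
  unchanged.

## Known limitations

- The noise model is additive and signal-independent; strong-signal shot
  noise on the Raman peaks themselves is outside the model (and outside the
  method's stated approximation).
- Each trained model is specific to one instrument/noise bank; there is no
  transfer across instruments by design.
- The desk-scale training configuration trades a few dB of achievable SNR
  gain for CPU turnaround; the published-scale gains require longer
  training on the same code path.
- Real-data reproductions (specific materials, cells, TERS maps) require
  instrument data not bundled here; the synthetic generator and property
  tests substitute for them.
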