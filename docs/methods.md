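# Methods

`vecspeckle` is a simulation-plus-learning pipeline for imaging through
anisotropic, dynamically varying scattering media with polarized (vector)
light. It has three layers: a physical forward model that produces speckle
datasets, a hybrid convolutional/self-attention restoration network, and an
evaluation/experiment harness. This note records the models, the defaults and
why they were chosen, the numerical choices, and what the simulated results
do and do not say about laboratory data.

## 1. Forward model

### 1.1 Fields and phase encoding

A monochromatic paraxial field is a Jones field: two complex amplitude maps
`(ex, ey)` on an H x W pixel grid; camera intensity is `|ex|^2 + |ey|^2`
(no analyzer in front of the camera). Phase targets are grayscale glyphs
`g in [0,1]` mapped to phases `delta = phase_scale * g`, with
`phase_scale = pi` by default: pi gives maximal interferometric contrast for
stroke-like binary glyphs while avoiding the `2*pi == 0` wrap that would make
a binary glyph invisible. Vector illumination places `exp(i*delta1)` and
`exp(i*delta2)` on two orthogonal basis vectors (horizontal/vertical linear,
or left/right circular, converted to the x/y frame); scalar illumination
carries `exp(i*delta1)` on a single component. Total input power is `H*W` in
every mode.

The glyph generator emulates preprocessed handwritten-digit targets with
procedural stroke glyphs: 2-4 random quadratic Bezier strokes rasterized at
28 x 28 logical resolution, Gaussian-blurred, upsampled to the working grid.
Support (pixels > 0.1) is guaranteed in 5-40 % of the grid by redrawing from
derived sub-seeds. `blobs` and `rings` styles provide non-stroke controls.
Real digit images can be substituted through the grayscale-image loader; the
pipeline does not depend on any external dataset.

### 1.2 Hologram encoding and demodulation

Two phase maps are written on one real transmittance using two orthogonal
carriers at spatial frequency `f0` (cycles per grid width):

    t(x,y) = 1 + (gamma/2) cos(2 pi f0 x + delta1) + (gamma/2) cos(2 pi f0 y + delta2)

with modulation depth `gamma` (default 1.0 — the value is otherwise free and
only rescales the diffraction orders). Encoding refuses carriers below the
target's measured spectral bandwidth (99 %-energy radius of `exp(i*delta)`),
because the diffraction orders would then overlap irrecoverably.

Demodulation models an ideal dual-aperture 4f spatial filter: mix the +1
order of one carrier to baseband and keep it with a *half-band* mask — a
Gaussian-edged half-plane, hard-zeroed before the contaminating orders, all
of which sit at parallel frequency <= -f0 after mixing — then take the
argument of the analytic signal. Pure spectral filtering leaves a small bias
(the cosine nonlinearity spreads each order's tails into its neighbors), so
by default six Gauss-Newton refinement passes follow: they fit the full
transmittance model, updating each phase map with spectrally capped
(0.55 f0) corrections. On targets bandlimited below `f0/2` the round-trip
error is ~0.02 rad RMS; `refine=0` reproduces the pure spatial-filter model.
Recovered phases are defined up to one global constant per carrier, as in
any off-axis holographic method.

Targets whose phase maps carry substantial energy beyond `f0/2` cannot be
recovered to that accuracy by *any* single-sideband method — the out-of-band
phase content is itself the error floor. The round-trip contract therefore
applies to bandlimited targets only.

### 1.3 Scattering media

Two interchangeable linear-operator representations:

**Dense vector transmission matrix.** Four complex `N x N` blocks
(`N = H*W`) act on the flattened polarization components:
`E_out,x = T11 E_in,x + T12 E_in,y`, `E_out,y = T21 E_in,x + T22 E_in,y`.
Entries are i.i.d. circular complex Gaussians with variances set by three
parameters: transmissivity `eta` (ensemble-mean power throughput), ballistic
fraction `beta` (an unscattered `sqrt(eta*beta) * I` term on the
co-polarized blocks), and anisotropy coupling `kappa` — the fraction of
diffuse power routed through the cross-polarized blocks. `kappa = 0` is the
isotropic (ground-glass) limit with `T12 = T21 = 0` exactly; biological
tissue is modeled with `kappa = 0.5` by default. Dense mode is exact but
memory-bound, so it is capped at 48 x 48 grids (a 256 x 256 grid would need
~17 GB per block).

**Layered Jones-screen medium.** For large grids the same contract is
realized physically: L per-pixel unitary screens (random birefringent
retarders: fast axis `pi * z_axis`, retardance `kappa * (pi/2) * z_ret`,
scalar phase `1.0 * z_phase`, where the `z` textures are unit-variance
Gaussian fields with 3 px correlation length) separated by unitary
angular-spectrum propagation (default gap 8 px). The per-layer phase std of
1.0 rad makes image degradation accumulate gradually over layers, so depth
acts as a thickness proxy rather than destroying the field in one step. The
simulation wavelength defaults to 1.4 px, below which every discrete spatial
frequency propagates and the free-space step is exactly unitary; choosing a
larger wavelength activates evanescent clipping. `effective_vtm` rebuilds
the explicit dense operator of a layered medium column-by-column on small
grids, which is the oracle tying the two representations together.

**Thickness ladder.** Tissue thickness is emulated qualitatively, not by
radiative transfer: the four levels tagged 0.5/1.0/1.5/2.0 mm map to
decreasing ballistic fraction (0.45/0.30/0.12/0.04), decreasing
transmissivity (0.90/0.75/0.55/0.40), increasing depth in layered mode
(2/4/6/8 layers), and increasing camera grain averaging (0/0.7/1.4/2.1 px,
see the camera model below). The grain term carries the information loss: a linear scattering
operator is equally invertible by a learned restorer at any ballistic
fraction (we measured indistinguishable restoration quality across the
ballistic range in a noise-free camera), whereas averaging unresolved
speckle grain — the analogue of recording a fine-grained diffuse halo on
finite-size camera pixels and resizing the frame — destroys detail
irreversibly and scales with thickness. Only the monotone degradation trend
is meaningful; the published absorption/scattering coefficient ranges
motivate the ordering but are not used quantitatively.

**Temporal drift.** Tissue deformation/drying is a stationary autoregressive
process: each random component is replaced by
`sqrt(1-eps) * old + sqrt(eps) * fresh` per step (dense: the Gaussian
blocks; layered: an Ornstein-Uhlenbeck step on each screen's underlying
textures). `eps = 0` is the identity, `eps = 1` a fresh independent medium,
and repeated steps compound speckle decorrelation monotonically in
expectation. This is the simplest one-knob stationary decorrelation model;
the real decorrelation time of tissue is not characterized here, so the rate
is surfaced in configuration (datasets default to `eps = 0.3` per
acquisition session when drift is enabled).

### 1.4 Camera

Total intensity (both polarizations summed), then optionally, in physical
order: grain averaging (`speckle_blur`, Gaussian std in px, applied to the
raw intensity — speckle grain finer than the effective pixel is averaged
incoherently, reducing contrast irreversibly, as happens when a large raw
frame of a fine-grained diffuse halo is resized to the working resolution);
Poisson shot noise at a configurable photon budget (`noise` = expected
photons at unit raw intensity); additive Gaussian read noise (std in
photons); ADC quantization (default 8 bit); and finally per-image
max-normalization to [0, 1] — the standard normalization for learning
pipelines when no radiometric calibration exists. Because noise and grain
act on the *raw* intensity, media with lower transmitted power produce
noisier normalized frames.

### 1.5 Seeds

One root seed; every medium, glyph, camera-noise draw and shuffle derives a
child generator via `SeedSequence(root, spawn_key=hash(path))` with a
symbolic path ("medium", ("glyph", i), ...). Any single sample is
reproducible in isolation, and identical configurations produce
byte-identical HDF5 containers (datasets are written with
`track_times=False`).

## 2. Restoration network

Two parallel encoders, fused, one decoder:

* **Convolutional path**: four stages of two 3 x 3 convolutions (ReLU) and
  2 x 2 max pooling, channels doubling from `cnn_base_channels`; skip
  connections feed the decoder.
* **Attention path**: the input is cut into `P x P` patches, each linearly
  projected to a K-dimensional token plus a learned positional embedding
  (`X_embed = X * W_proj + pos_emb`); pre-norm Transformer blocks
  (multi-head self-attention + GELU feed-forward, width 2K) model global
  structure. Tokens are projected to the bottleneck channel count and
  reshaped to a spatial map, average-pooled or upsampled to the bottleneck
  grid.
* **Fusion**: `concat(f_cnn, f_attn, f_cnn * f_attn)` mixed by a 1 x 1
  convolution. "Multiplication and concatenation" admits several readings;
  this one keeps both originals and their elementwise interaction and is the
  package's documented interpretation. Fusion happens at the bottleneck;
  decoder skips come from the convolutional path only.
* **Decoder**: four stages of nearest-neighbor 2x upsampling, skip
  concatenation, two 3 x 3 convolutions; a 1 x 1 head with sigmoid yields 1
  channel (single-phase restoration, SPIR) or 2 independent channels
  (dual-phase, DPIR). Output spatial size always equals input size.

The `cnn_baseline` variant removes the attention path and fusion and is
otherwise identical, so the trans-vs-baseline comparison isolates the global
self-attention contribution under identical data and training configs.

Because no GPU tensor framework is assumed, the network runs on a compact
in-repo reverse-mode autograd engine (`vecspeckle.nn`, numpy throughout);
every primitive's gradient is verified against central finite differences in
the test suite.

Defaults (unstated in the source description, chosen as the smallest
configuration that trains in minutes on one CPU while preserving the
architecture): full scale 256 px, P=16, K=256, 4 attention layers, 8 heads,
32 base channels; desk scale 32 px, P=8, K=64, 2 attention layers, 4 heads,
8 base channels.

## 3. Training and evaluation

Pixelwise L2 loss (L1 available) between the sigmoid output and the
normalized glyph labels — the labels are the glyphs, not the phase maps, the
two being proportional through `phase_scale`. Adam at 1e-3, batch 32 at desk
scale, 8:2 train/test split drawn by seed before training and stratified
across drift epochs so every acquisition session appears in both splits.
Divergence (non-finite loss) aborts with diagnostics.

Metrics: Pearson correlation over flattened pixels (degenerate constant
images score 0 with a warning); SSIM with the standard Gaussian 11 x 11
window, sigma 1.5, K1=0.01, K2=0.03 (scikit-image backend; images smaller
than the window fall back to global statistics, flagged); PSNR
`10 log10(MAX^2/MSE)` with zero-MSE capped at 100 dB so table aggregation
stays finite.

Experiment presets (`dynamic`, `scalar_vs_vector`, `thickness`,
`dual_phase`) generate their datasets, train the configured models and emit
tables shaped like the corresponding study designs. Desk scale uses 32 x 32
grids, a dense medium, 1500 samples and 12 epochs; the `dynamic` preset
trains one model jointly across the four drift sessions (matching the
generalization claim; per-session training is the documented alternative).

### Problem sizes used by the test suite and acceptance script

Simulated studies are sized to minutes of CPU: the single-phase restoration
check trains on 1,500 samples (1,200/300 split) for 10 epochs; the
qualitative trend checks compare seed-averaged means over three seeds each —
hybrid-vs-baseline and cross-session stability on 320-sample datasets for 6
epochs, vector-vs-scalar likewise (on the layered medium, see section 4),
the thickness ladder on 576-sample datasets for 9 epochs, and dual-phase
recovery on 480-sample datasets for 8 epochs. Monte-Carlo physics checks
use 16-64 px grids with 10-200 medium draws as noted per test.

A caution that shaped these sizes: stroke glyphs share enough structure that
a restorer trained on *uninformative* inputs already reaches test PCC ~0.62
by reproducing glyph statistics. Comparisons are therefore run at sample
counts whose restoration quality sits clearly above that prior floor, where
differences reflect the physics of the input rather than label statistics.

## 4. What the simulation does and does not show

The synthetic media reproduce the *structural* properties that matter for
the method: linear vector transmission, polarization coupling, ballistic
attenuation with thickness, fully developed speckle statistics, and
stationary temporal decorrelation. They do not model real tissue quantitatively:
no radiative transfer or absorption spectroscopy, no spatial inhomogeneity
of the coupling, no memory-effect correlations, and drift is a single-rate
stationary process rather than monotone drying. Published metric values from
laboratory tissue datasets are therefore not reproduction targets; what is
reproducible — and asserted by the tests — is the direction of every
comparison (hybrid over baseline, vector over scalar, degradation with
thickness, stability across drift sessions) plus the internal physics
contracts. On this simulator, single-phase restoration through a moderately
scattering static medium reaches test PCC ~0.87 at desk scale.

One structural finding deserves emphasis. In the dense Gaussian matrix
model, scalar and vector illumination of a *single-phase* target produce
camera-intensity ensembles with identical first and second moments: the
glyph-bearing interference variance and the diffuse beat noise are equal
however the diffuse power is split between co- and cross-polarized blocks,
so the scalar-vs-vector comparison is degenerate there (paired runs tie to
within ±0.006 PCC). The layered Jones-screen medium has no such symmetry —
its four effective blocks share the same physical screens and are mutually
correlated — and there vector illumination consistently outperforms scalar.
The vector-over-scalar comparison is therefore run on the layered medium,
which is also the physically structured, tissue-like realization. Similarly,
thickness-driven degradation does not exist in a noise-free camera (a dense
random linear map is equally learnable at any ballistic fraction); it enters
through the camera's grain averaging, which is why the ladder carries that
term.

## 5. Known limitations

* Dense mode is exact but capped by memory; layered mode scales but its
  effective operator statistics are induced by the screen model rather than
  prescribed (kappa controls retardance spread, not the exact cross-block
  variance).
* The autograd engine is single-threaded numpy; full-scale (256 px, 10k
  samples) training is hours of CPU, desk scale is the tested regime.
* L1 training loss uses a constant-sign subgradient at zero.
* Demodulation assumes integer-aligned, orthogonal carriers and global
  phase offsets remain undetermined (inherent to off-axis holography).
* Glyph support guarantees use redraws, so extreme style parameters could in
  principle exhaust the 64 redraw attempts (an explicit error, never a
  silent fallback).
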