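# vecspeckle

Imaging through biological tissue with coherent light is frustrated by
scattering: the image-bearing wavefront is scrambled into a speckle pattern,
and soft tissue is both *anisotropic* (it couples the two orthogonal
polarization components of the field) and *dynamic* (it drifts as the sample
dries and deforms). `vecspeckle` is a self-contained pipeline for studying
learned restoration of phase images carried by polarized light through such
media:

* a **vector transmission matrix (VTM) simulator** — the medium is the
  2 x 2-block linear operator

  ```
  [E_out,x]   [T11 T12] [E_in,x]
  [E_out,y] = [T21 T22] [E_in,y]
  ```

  acting on the two polarization components, with tunable anisotropy
  coupling (T12, T21 vanish for ground glass, not for tissue), ballistic
  fraction, transmissivity and an autoregressive temporal drift. A dense,
  exact matrix form serves small grids; a layered random-birefringent-screen
  form with angular-spectrum propagation realizes the same linear contract
  at 256 x 256, and the two are cross-checked against each other.

* a **two-carrier hologram codec** — one or two phase maps delta1, delta2
  ride orthogonal spatial carriers of one real transmittance
  `t = 1 + (g/2)cos(2 pi f0 x + delta1) + (g/2)cos(2 pi f0 y + delta2)`,
  and an idealized 4f spatial-filter demodulator (plus optional Gauss-Newton
  refinement) recovers them.

* a **hybrid restoration network** — a four-stage convolutional U-shaped
  path (local texture) in parallel with a patch-embedding Transformer path
  (`X_embed = X W_proj + pos_emb`, self-attention for the global structure
  that speckle demands), fused multiplicatively at the bottleneck and
  decoded to one (SPIR) or two (DPIR) phase-image channels. A
  convolution-only baseline isolates the attention contribution. The
  networks run on a small in-repo numpy autograd engine — no GPU framework
  required.

* **metrics and experiment presets** — per-image PCC / SSIM / PSNR, 8:2
  stratified splits, and end-to-end presets (`dynamic`, `scalar_vs_vector`,
  `thickness`, `dual_phase`) that emit the corresponding report tables.

## Worked example

Simulate a dataset through a moderately scattering anisotropic medium
(coupling 0.5, ballistic fraction 0.3), train the hybrid network at desk
scale, and score it:

```sh
vecspeckle simulate --n-samples 300 --out runs/demo.h5 \
    --set simulation.grid=32
vecspeckle train --dataset runs/demo.h5 --out runs/demo \
    --set model.input_size=32 --set model.patch_size=8 \
    --set model.embed_dim=64 --set model.n_attention_layers=2 \
    --set model.n_heads=4 --set model.cnn_base_channels=8 \
    --set training.epochs=10 --set training.batch_size=32
```

which prints the per-epoch progress (this exact run, seeds all default):

```
model parameters: 224449
epoch   0  loss 0.17492  test PCC 0.1758  SSIM 0.0618  PSNR 9.24 dB
epoch   1  loss 0.10204  test PCC 0.5557  SSIM 0.1274  PSNR 10.76 dB
...
epoch   9  loss 0.07154  test PCC 0.6359  SSIM 0.1324  PSNR 11.44 dB
```

i.e. after ten epochs on 240 training speckles the network restores held-out
glyphs with pixel correlation ~0.64 — mostly glyph statistics at this tiny
sample count; 1,500 samples and 10 epochs reach test PCC ~0.87 (see the
acceptance script below). `runs/demo/` then contains the checkpoint,
CSV/JSON metric reports and a speckle/truth/restoration montage PNG. The
hologram round trip is a one-liner:

```sh
vecspeckle demo --size 64 --f0 12
```

```
round-trip RMS phase error: 0.0499 / 0.0527 rad
```

(the demo's stroke glyphs are only lightly smoothed, so they sit at the edge
of the carrier's band; smoother targets round-trip at ~0.02 rad RMS).

Experiment presets reproduce whole study designs
(`vecspeckle experiment thickness --scale desk`), writing one table row per
thickness level.

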