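# hexademosaic

Demosaicing for **hexachromatic color/near-infrared image sensors** — the
single-chip imagers used in fluorescence image-guided surgery that pair
vertically stacked photodiodes (three spectral measurements per pixel) with a
pixelated filter array alternating visible-pass (400–700 nm) and NIR-pass
(700–1000 nm) filters in a checkerboard. Each pixel records either a visible
(R, G, B) or a NIR (NIR1, NIR2, NIR3) triplet, so both spectral streams are
sampled at half the sensor's spatial resolution, offset by one pixel
horizontally. This package reconstructs the full-resolution six-channel image
from the raw mosaic.

It is intended for researchers building or evaluating color–NIR imaging
pipelines: it simulates the sensor, implements two demosaicers, trains the
learned one, and scores reconstructions with a four-metric protocol.

## Method

Two reconstruction routes are provided:

1. **1D bilinear baseline.** Every missing pixel of a stream has measured
   horizontal neighbours under the checkerboard; it is filled with their mean
   (single-neighbour replication at borders). Cheap, but it produces zipper
   artifacts along high-contrast edges.

2. **Residual CNN.** A deep convolutional network is trained to predict the
   *high-frequency residual* between the bilinear estimate and the ground
   truth, following the residual-learning strategy used in super-resolution:

   - layers `n = 1 … N−1`:  `F_n(Y) = selu(F_{n−1}(Y) * W_n + B_n)` — 64
     filters of 3×3 with one-pixel padding, each convolution followed by batch
     normalization and a SELU activation,
     `selu(x) = λx (x>0), λα(eˣ−1) (x≤0)`;
   - final layer: `F(Y) = F_{N−1}(Y) * W_N + B_N` — a plain 3-filter
     convolution, no activation;
   - output: `X̂ = F(Y; Θ) + Ŷ`, the interpolation plus the predicted
     residual, trained with the loss
     `L(Θ) = (1/n) Σᵢ ‖(F(Yᵢ; Θ) + Ŷᵢ) − Xᵢ‖²`
     (Adam, constant learning rate, MSRA/He initialization, 50×50 training
     patches with the 8 dihedral augmentations).

   Because half of the interpolated image's pixels are exact measurements,
   the low frequencies are already right and the network only learns the
   high-frequency correction. The visible and NIR streams share one
   architecture; by default a color-trained model is applied to both streams.

   The network (convolutions, batch norm, SELU, backpropagation, Adam) is
   implemented directly on numpy, so the package has no deep-learning
   framework dependency and runs anywhere numpy does.

Evaluation: per-channel **PSNR** and **MSE**, the **95th percentile of
DSSIM** = (1 − SSIM)/2 (tail, not mean — localized artifacts matter), the
**95th percentile of ΔE** (channel-space Euclidean distance as a percentage
of the maximum √3·peak, applicable to visible and NIR triplets alike), and an
**FFT analysis** comparing vertical-frequency line profiles of the
reconstruction and the ground truth in dB.

A synthetic-scene generator produces six-channel ground truth with the
structure that makes demosaicing hard — sharp step edges, thin bright
vessel-like curves a few pixels wide in one NIR channel, smooth gradients,
partially correlated visible/NIR content — so the whole pipeline is testable
without external datasets.

## Worked example

```python
import numpy as np
from hexademosaic import (SceneSpec, generate_scene, make_masks, mosaic,
                          demosaic_bilinear, evaluate)

scene = generate_scene(SceneSpec(seed=3))          # 96x96x6 ground truth
frame = mosaic(scene, make_masks(96, 96, phase=0)) # raw sensor readout
recon = demosaic_bilinear(frame)                   # baseline reconstruction
report = evaluate(recon, scene)
print({k: round(v, 2) for k, v in report.psnr.items()})
print(round(report.p95_dssim_vis, 4), round(report.p95_delta_e_vis, 3))
```

prints

```
{'vis_r': 29.68, 'vis_g': 31.05, 'vis_b': 29.94, 'nir_1': 29.57, 'nir_2': 36.68, 'nir_3': 36.83}
0.1372 8.149
```

i.e. the bilinear baseline reconstructs this synthetic scene at ~30–37 dB per
channel, with a 95th-percentile visible DSSIM of 0.137 and a 95th-percentile
visible ΔE of 8.1% — the numbers the residual CNN is trained to improve.

The same pipeline is available from the shell:

```bash
hexademosaic synth --n 8 --seed 1 --out scenes/
hexademosaic mosaic --input scenes/scene_000.tif --phase 0 --out frame.tif
hexademosaic train --config train.yaml --out model.npz
hexademosaic demosaic --input frame.tif --method cnn --checkpoint model.npz --out recon.tif
hexademosaic eval --recon recon.tif --truth scenes/scene_000.tif --out report.json
```

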