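# cellrestore

Task-driven restoration of degraded 2D microscopy images, built around a
flow-field instance-segmentation network.

## The problem

Microscopy images are often degraded by shot noise (low illumination),
Gaussian-like blur (open apertures, scattering in thick tissue) or
undersampling (photon/time budgets).  Instance-segmentation models trained
on clean images lose much of their accuracy on such data.  Classical
denoisers fix *pixels*; but a restoration optimized for mean squared error
happily blurs away the thin boundaries between touching cells — exactly
the detail segmentation needs.

`cellrestore` trains restoration networks for the *downstream task*
instead: a restoration U-net is optimized so that its output is well
segmented by a **frozen** segmentation network, with the training error
back-propagating through the frozen segmenter into the restorer,

```
L = w_rec · ‖x̂ − x‖² / N                                   (reconstruction)
  + w_seg · [ 5 · MSE(flows(S(x̂)), flows_gt) + BCE(prob(S(x̂)), prob_gt) ]
  + w_per · mean_b  ‖C_b(x̂) − C_b(x)‖² / (N_b · sd(C_b(x)))  (perceptual)
```

where `S` is the frozen flow-field segmenter, `flows_gt`/`prob_gt` are the
ground-truth flow field and cell-probability map derived from the masks,
and `C_b` is the Pearson channel–channel correlation matrix of the
segmenter's activations at encoder level *b*.  The perceptual term keeps
the restored images visually faithful; the segmentation term is what
recovers instance accuracy.

Everything needed to study this mechanism at desk scale ships in the
package: a seeded synthetic cell/nucleus image generator, parameterized
degradations (gamma-distributed Poisson photon scales, diameter-scaled
blur, decimation) with test-time calibration to a target AP ratio, the
masks↔flows instance representation, AP/IoU evaluation, training
orchestration, and a small CLI.  The neural networks run on a built-in
numpy autodiff engine — no GPU or deep-learning framework required.

## Worked example

```bash
python examples/04_train_and_restore.py
```

trains a toy segmenter on 12 synthetic cytoplasm images (64×64, ~18 px
objects), calibrates per-image Poisson noise to halve its AP@0.5, trains a
restoration network through the frozen segmenter, and prints, e.g.:

```
clean AP@0.5            : 1.000
degraded AP@0.5         : 0.688  (calibrated ratio 0.50, target 0.5)
restored (task loss)    : 1.000
restored (pixel loss)   : 0.969
```

Reading: calibration found, per image, the photon scale at which the
segmenter loses about half its accuracy; restoring those images with the
task-loss network recovers most of the lost AP, and does not trail the
pixel-reconstruction network.  Smaller examples cover the generator
(`01`), the degradation protocols and the shot-noise law (`02`), and the
flow round-trip (`03`).

The same pipeline is scriptable from the shell:

```bash
cellrestore simulate --n-images 8 --diameter 20 --size 128 --seed 7 --out data/
cellrestore degrade  --mode denoise --seed 1 --in data/ --out noisy/
cellrestore train    --task segment --epochs 50 --in data/ --out ckpt/seg.npz
cellrestore segment  --checkpoint ckpt/seg.npz --diameter 20 \
                     --in noisy/deg_000.tif --out masks/pred_000.tif
cellrestore eval     --pred masks/ --gt gt_masks/ --out scores/
```

Every command writes a JSON run manifest next to its outputs.

## Scope

2D single/dual-channel images only; synthetic degradations (no real PSF
or structured-noise models); the object diameter is a required user input
for restoration and segmentation.  See `docs/methods.md` for the model,
parameter and design details.
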