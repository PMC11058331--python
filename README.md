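# mfnet

Frequency-space amplitude mixing plus a two-task meta-learning objective
for domain-generalizable 2D lesion segmentation, exercised end-to-end on
a synthetic two-domain multi-modal phantom.

The idea: the amplitude spectrum of an image carries its low-level
"style" while the phase spectrum carries anatomy. Blending the amplitude
spectra of two co-registered modalities of the same case (keeping the
source phase, and hence the source mask) manufactures new appearance
variants. Training couples a plain Dice-loss task on original images
with a meta task: take one inner gradient step on the original batch,
then evaluate the mixed batch at the adapted parameters, and optimize
`alpha * L_init + beta * L_mix` with SGD under a polynomial LR schedule.
`beta = 0` reduces exactly to the plain (ERM) baseline.

Everything runs on CPU: the network stack (U-Net, SGD, first- and
second-order meta-gradients) is implemented on numpy with a small
reverse-mode autodiff engine included in the package.

## Layout

- `mfnet.spectral_mix` — amplitude/phase decomposition, convex amplitude
  mixing, reconstruction, λ sampling
- `mfnet.losses_metrics` — soft Dice loss; Dice / IoU metrics with
  foreground and two-class mean-IoU modes
- `mfnet.seg_model` — U-Net (batch norm, bilinear upsampling, sigmoid head)
- `mfnet.meta_trainer` — inner update, meta objective, SGD loop,
  polynomial LR schedule, multi-seed training, evaluation
- `mfnet.synthetic_phantom` — two-domain, three-modality phantom
  generator with tumour masks
- `mfnet.data_io` — manifests, PNG/JPEG loading, case-level splits,
  original/mixed data streams
- `mfnet.cli` — `mfnet` command-line entry point
- `mfnet.autodiff` / `mfnet.layers` — numpy autodiff engine and layers

## CLI

```sh
# generate a two-domain phantom dataset (domain A = train, B = unseen test)
mfnet make-phantom --out data/ --n-train 40 --n-test 20 --size 96 --seed 0

# write amplitude-mixed augmentations for inspection
mfnet augment --input data/manifest.csv --output aug/ --lam uniform --seed 0

# train (YAML config optional; --beta 0 gives the ERM baseline)
mfnet train --data data/manifest.csv --out run/ --size 96 --epochs 30

# evaluate a checkpoint
mfnet evaluate --checkpoint run/model_seed0.npz --data data/manifest.csv --out eval/
```

Every run writes a frozen `run_config.yaml` next to its outputs.

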