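# echoaug

Mask-preserving generative augmentation for sector-scan cardiac ultrasound.

An unconditionally trained denoising diffusion model is combined with
mask-guided RePaint inpainting and five sector-geometry transforms (depth
increase, tilt, width adjustment, translation, and their random combination)
to enlarge the acquisition variety of a labeled dataset while leaving every
labeled pixel bit-identical to the source image.  The package also ships the
downstream evaluation stack: Dice / Hausdorff segmentation metrics,
Simpson-biplane volumes and ejection fraction, Bland–Altman agreement,
SSIM-based retrieval, and the survey statistics (Wilcoxon signed-rank with
Bonferroni correction, exact binomial tests, Cohen's kappa).

No external data is required: a synthetic phantom module generates speckled
sector images with LV/MYO masks — and cine sequences with a prescribed EF —
so every stage is testable offline.

## Layout

| module                  | contents |
|-------------------------|----------|
| `echoaug.schedule`      | cosine noise schedule, respacing for fast sampling |
| `echoaug.ddpm`          | forward process, closed-form posterior, learned-variance reverse sampling, hybrid loss, importance-sampled timesteps, training, generation, checkpoints |
| `echoaug.repaint`       | jump schedules and mask-guided inpainting |
| `echoaug.geometry`      | sector geometry rendering and detection |
| `echoaug.transforms`    | the five augmentations, keep-mask bookkeeping, DDPM-training preprocessing, the full augment protocol |
| `echoaug.phantom`       | speckled sector phantoms and cine sequences with exact ground truth |
| `echoaug.metrics` / `simpson` / `stats` | Dice, Hausdorff (mm), SSIM retrieval, method-of-discs volumes/EF, Bland–Altman, Wilcoxon+Bonferroni, kappa, binomial tests |
| `echoaug.io` / `stages` / `config` / `cli` | PNG/MetaImage/NIfTI readers and writers, manifests, nnU-Net-style export, YAML pipeline runner, CLI |

The diffusion model is a small fully-connected denoiser written in pure
numpy (with explicit backprop, Adam, EMA weights); it trains in seconds on
the toy and phantom problems used by the tests.  Latents live in [-1, 1],
public images in [0, 1].

## CLI

```sh
echoaug phantom --preset hunt4like --n 100 --out data --seed 1
echoaug train-ddpm --config cfg.yaml --data data --out ckpt.npz --seed 1
echoaug repaint --ckpt ckpt.npz --image in.png --mask keep.png --out out.png --seed 1
echoaug augment --data data --ckpt ckpt.npz --out aug --n-aug 5 --seed 1
echoaug augment --data data --out blackout --n-aug 5 --seed 1 --no-repaint
echoaug evaluate-seg --pred predDir --ref refDir --label lv --out metrics.csv
echoaug ef --a2c a2cDir --a4c a4cDir --out ef.csv
echoaug survey-stats --responses responses.csv
echoaug run pipeline.yaml
```

Datasets are directories of PNG image/mask pairs plus a `manifest.json`
carrying spacing (mm/px), view/cycle metadata and optional sector geometry;
`--layout nnunet` exports `imagesTr`/`labelsTr` naming with a
`dataset.json`.  Mask label 3 (left atrium) is remapped to background on
read.  All randomness flows from a single master seed through
`numpy.random.SeedSequence` spawn keys.

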