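"""Pipeline stages shared by the CLI and the YAML config runner.

Every stage takes a seed and is bit-reproducible for a fixed seed.  Child
seeds for per-sample randomness are derived with
``numpy.random.SeedSequence(entropy=seed, spawn_key=...)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ddpm, io, metrics, phantom, repaint as repaint_mod, simpson, stats
from .errors import InvalidArgumentError, PipelineFailureError
from .schedule import respace_schedule
from .transforms import AugmentationConfig, augment_dataset, blackout_baseline

__all__ = [
    "stage_phantom",
    "stage_train_ddpm",
    "stage_repaint",
    "stage_augment",
    "stage_evaluate_seg",
    "stage_ef",
    "stage_survey_stats",
]


def stage_phantom(
    out,
    n: int,
    preset: str = "hunt4like",
    seed: int = 0,
    image_size: int = 256,
    anatomy_scale: float = 1.0,
):
    """Generate ``n`` phantom samples into ``out`` (native layout)."""
    if preset not in phantom.PRESETS:
        raise InvalidArgumentError(f"unknown preset {preset!r}")
    cfg = phantom.PRESETS[preset](image_size=image_size, anatomy_scale=anatomy_scale)
    samples = []
    for i in range(int(n)):
        child = np.random.SeedSequence(entropy=int(seed), spawn_key=(i,))
        s, _ = phantom.generate_sample(cfg, int(child.generate_state(1)[0]))
        samples.append(s)
    return io.write_augmented_dataset(samples, out, layout="native", force=True)


def stage_train_ddpm(data, out, seed: int = 0, config: dict | None = None):
    """Train a DDPM on the images of a native-layout dataset directory."""
    cfg_kwargs = dict(config or {})
    cfg_kwargs.setdefault("seed", int(seed))
    cfg = ddpm.TrainingConfig(**cfg_kwargs)
    dataset = io.load_dataset(data)
    latents = np.stack([2.0 * s.image - 1.0 for s in dataset])
    predictor = ddpm.train(latents, cfg)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    ddpm.save_checkpoint(out, predictor, predictor.schedule, cfg)
    log_path = out.with_suffix(".log.csv")
    pd.DataFrame(predictor.training_log, columns=["step", "loss", "vlb"]).to_csv(
        log_path, index=False
    )
    return out


def stage_repaint(
    ckpt,
    image,
    mask,
    out,
    seed: int = 0,
    jump_length: int = 10,
    n_resample: int = 10,
    sampling_steps: int | None = None,
):
    """Repaint one image: keep pixels where the mask is set."""
    predictor, schedule, _ = ddpm.load_checkpoint(ckpt)
    if sampling_steps is not None:
        schedule = respace_schedule(schedule, sampling_steps)
    img_raw, _ = io._read_any(image)
    img = io._to_unit_image(img_raw)
    mask_raw, _ = io._read_any(mask)
    keep = (np.asarray(mask_raw) > 127).astype(np.uint8)
    result = repaint_mod.repaint(
        predictor,
        schedule,
        img,
        keep,
        seed=int(seed),
        jump_length=jump_length,
        n_resample=n_resample,
    )
    io.write_png_image(out, result)
    return Path(out)


def stage_augment(
    data,
    ckpt,
    out,
    n_aug: int = 5,
    seed: int = 0,
    no_repaint: bool = False,
    layout: str = "native",
    sampling_steps: int | None = None,
    jump_length: int = 10,
    n_resample: int = 10,
):
    """Original + ``n_aug`` generative (or blackout) augmentations per sample."""
    samples = io.load_dataset(data)
    config = AugmentationConfig(
        n_augment_per_image=int(n_aug), jump_length=jump_length, n_resample=n_resample
    )
    if no_repaint:
        augmented = []
        for i, s in enumerate(samples):
            augmented.append(s)
            for k in range(config.n_augment_per_image):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=int(seed), spawn_key=(i, k))
                )
                augmented.append(blackout_baseline(s, config, rng))
    else:
        predictor, schedule, _ = ddpm.load_checkpoint(ckpt)
        if sampling_steps is not None:
            schedule = respace_schedule(schedule, sampling_steps)
        augmented = augment_dataset(samples, predictor, schedule, config, int(seed))
    return io.write_augmented_dataset(augmented, out, layout=layout, force=True)


_LABEL_IDS = {"lv": 1, "myo": 2}


def stage_evaluate_seg(pred, ref, label: str = "lv", out="metrics.csv", hd_percentile=None):
    """Per-sample Dice and Hausdorff (mm) between two native-layout datasets."""
    label_id = _LABEL_IDS.get(str(label).lower())
    if label_id is None:
        raise InvalidArgumentError(f"label must be one of {sorted(_LABEL_IDS)}")
    pred_recs = io.load_manifest(Path(pred) / "manifest.json")
    ref_recs = io.load_manifest(Path(ref) / "manifest.json")
    if len(pred_recs) != len(ref_recs):
        raise InvalidArgumentError("prediction and reference datasets differ in size")
    rows = []
    for pr, rr in zip(pred_recs, ref_recs):
        ps = io.read_sample(pr["image"], pr["mask"], pr)
        rs = io.read_sample(rr["image"], rr["mask"], rr)
        d = metrics.dice(ps.mask, rs.mask, label_id)
        try:
            hd = metrics.hausdorff_mm(
                ps.mask, rs.mask, label_id, rs.spacing, percentile=hd_percentile
            )
        except Exception:
            hd = float("nan")
        rows.append({"case": Path(pr["image"]).name, "dice": d, "hausdorff_mm": hd})
    df = pd.DataFrame(rows, columns=["case", "dice", "hausdorff_mm"])
    df.to_csv(out, index=False)
    return Path(out)


def _cycles_from_dir(directory):
    """Group a view directory's manifest into per-cycle (ED, ES) mask pairs."""
    recs = io.load_manifest(Path(directory) / "manifest.json")
    cycles = {}
    spacing = None
    for r in recs:
        role = str(r.get("frame_role", "other")).upper()
        if role not in ("ED", "ES"):
            continue
        s = io.read_sample(r["image"], r["mask"], r)
        spacing = s.spacing
        cycles.setdefault(r.get("cycle", 0), {})[role] = s.mask
    pairs = [
        (c["ED"], c["ES"]) for _, c in sorted(cycles.items()) if "ED" in c and "ES" in c
    ]
    if not pairs:
        raise PipelineFailureError(f"no complete ED/ES cycles in {directory}")
    return pairs, spacing


def stage_ef(a2c, a4c, out="ef.csv", n_discs: int = 20):
    """Biplane EF from the ED/ES cycles of two view directories."""
    a2c_cycles, sp2 = _cycles_from_dir(a2c)
    a4c_cycles, sp4 = _cycles_from_dir(a4c)
    value = simpson.biplane_ef_from_masks(a2c_cycles, a4c_cycles, sp2, sp4, n_discs)
    df = pd.DataFrame(
        [
            {
                "ef_percent": 100.0 * value,
                "n_a2c_cycles": len(a2c_cycles),
                "n_a4c_cycles": len(a4c_cycles),
            }
        ]
    )
    df.to_csv(out, index=False)
    return Path(out)


def stage_survey_stats(responses, out=None, p0: float = 0.5):
    """Per-group accuracy with binomial p-values and Cohen's kappa matrix.

    ``responses`` is a CSV with columns: pair_id, rater, group, answer
    (the selected image id) and truth (the synthetic image id).  Rows whose
    truth is empty (both images real) are excluded from accuracy but kept
    for agreement.
    """
    df = pd.read_csv(responses)
    required = {"pair_id", "rater", "group", "answer", "truth"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"responses CSV missing columns {sorted(missing)}")
    scored = df[df["truth"].notna()]
    result = {"groups": {}, "kappa": {}}
    for group, sub in scored.groupby("group"):
        k = int((sub["answer"] == sub["truth"]).sum())
        n = int(len(sub))
        result["groups"][group] = {
            "k": k,
            "n": n,
            "accuracy_percent": 100.0 * k / n if n else float("nan"),
            "binomial_p_one_sided": stats.binomial_test(k, n, p0, "greater"),
        }
    # answers aligned on pair_id per rater for agreement
    wide = df.pivot_table(index="pair_id", columns="rater", values="answer", aggfunc="first")
    rater_group = df.groupby("rater")["group"].first()
    groups = sorted(rater_group.unique())
    for ga in groups:
        for gb in groups:
            ra = [wide[r].to_numpy() for r in wide.columns if rater_group[r] == ga]
            rb = [wide[r].to_numpy() for r in wide.columns if rater_group[r] == gb]
            if ga == gb:
                if len(ra) < 2:
                    continue
                value = stats.average_pairwise_kappa(ra)
            else:
                value = stats.average_pairwise_kappa(ra, rb)
            result["kappa"][f"{ga}|{gb}"] = value
    if out is not None:
        Path(out).write_text(json.dumps(result, indent=1, sort_keys=True))
    return result
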