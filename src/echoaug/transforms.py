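"""Sector-geometry transforms on image+mask pairs.

Each transform returns a new :class:`LabeledSample` together with a boolean
``keep_mask`` marking the output pixels that still carry original image
content.  The complement of the keep mask is the region a generative model
may repaint; by construction it never intersects labeled pixels, which is
the central guarantee of the augmentation scheme.

Conventions: images bilinear, masks and keep masks nearest-neighbour;
coordinates 0-based (row, col) with row 0 at top; translation angles in
degrees counterclockwise from image-right, so a shift of length L at angle
phi moves content by ``(d_row, d_col) = (round(-L sin phi), round(L cos phi))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import (
    ContractError,
    GenerationError,
    InvalidArgumentError,
)
from .geometry import SectorGeometry, detect_sector, sector_support

__all__ = [
    "LabeledSample",
    "AugmentationConfig",
    "depth_increase",
    "tilt",
    "width_adjust",
    "translate",
    "combine",
    "blackout_baseline",
    "narrow_width_pretrain",
    "subsample_every_nth",
    "augment_dataset",
]

LABELS = (0, 1, 2)
LV, MYO = 1, 2


@dataclass
class LabeledSample:
    """A sector image with labels, geometry and physical pixel spacing."""

    image: np.ndarray  # H x W floats in [0, 1]
    mask: np.ndarray  # H x W ints in {0 bg, 1 LV, 2 MYO}
    geometry: SectorGeometry | None = None
    spacing: tuple = (1.0, 1.0)  # (row, col) mm per pixel
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise InvalidArgumentError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ"
            )
        if not np.isin(self.mask, LABELS).all():
            raise InvalidArgumentError(
                f"mask labels must be within {LABELS}, got {np.unique(self.mask)}"
            )
        self.mask = self.mask.astype(np.uint8)
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise InvalidArgumentError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.image.shape

    def support(self) -> np.ndarray:
        """Sector support: rendered from geometry when known, else the
        non-black image footprint."""
        if self.geometry is not None:
            return sector_support(self.geometry, self.shape)
        return self.image > 0

    def replace(self, **kwargs) -> "LabeledSample":
        base = dict(
            image=self.image,
            mask=self.mask,
            geometry=self.geometry,
            spacing=self.spacing,
            provenance=list(self.provenance),
        )
        base.update(kwargs)
        return LabeledSample(**base)


@dataclass
class AugmentationConfig:
    """Ranges and probabilities for the five generative augmentations."""

    depth_lambda_range: tuple = (0.0, 150.0)  # px
    tilt_range: tuple = (-30.0, 30.0)  # degrees
    width_factor_range: tuple = (0.5, 1.5)
    translation_length_range: tuple = (0.0, 50.0)  # px
    combination_probability: float = 0.5
    n_augment_per_image: int = 5
    out_size: int = 256
    min_lv_retention: float = 0.8  # redraw when cropping removes more LV
    jump_length: int = 10
    n_resample: int = 10

    def __post_init__(self):
        for name in (
            "depth_lambda_range",
            "tilt_range",
            "width_factor_range",
            "translation_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidArgumentError(f"{name} must be ordered, got {(lo, hi)}")
        if not 0.0 <= self.combination_probability <= 1.0:
            raise InvalidArgumentError("combination_probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _resize(arr, shape, order):
    return _sk_resize(
        arr.astype(np.float64),
        shape,
        order=order,
        mode="constant",
        cval=0.0,
        anti_aliasing=False,
        preserve_range=True,
    )


def _resize_mask(mask, shape):
    return _resize(mask, shape, order=0).astype(mask.dtype)


def _resize_bool(arr, shape):
    return _resize(arr.astype(np.uint8), shape, order=0).astype(bool)


def _affine(arr, matrix, offset, order):
    out = ndimage.affine_transform(
        arr.astype(np.float64), matrix, offset=offset, order=order, mode="constant", cval=0.0
    )
    return out


def _keep_or_support(sample, keep):
    if keep is not None:
        return keep.astype(bool)
    return sample.support()


# ---------------------------------------------------------------------------
# the five transforms
# ---------------------------------------------------------------------------

def depth_increase(sample: LabeledSample, lambda_px: float, keep=None):
    """Simulate a deeper acquisition: pad black rows below (and columns
    laterally to keep the aspect), then resize back to the original frame.

    Spacing scales by ``(H + lambda) / H`` per axis; the keep mask is the
    resized original support.
    """
    lam = float(lambda_px)
    if not 0.0 <= lam <= 150.0:
        raise InvalidArgumentError(f"lambda_px must be in [0, 150], got {lam}")
    keep0 = _keep_or_support(sample, keep)
    prov = {"transform": "depth_increase", "lambda_px": lam}
    if lam == 0:
        out = sample.replace(provenance=sample.provenance + [prov])
        return out, keep0
    lam_i = int(round(lam))
    H, W = sample.shape
    pad_l = lam_i // 2
    pad_r = lam_i - pad_l

    def pad(arr, cval=0):
        return np.pad(arr, ((0, lam_i), (pad_l, pad_r)), constant_values=cval)

    image = _resize(pad(sample.image), (H, W), order=1)
    mask = _resize_mask(pad(sample.mask), (H, W))
    keep_new = _resize_bool(pad(keep0.astype(np.uint8)), (H, W))
    s_r = H / (H + lam_i)
    s_c = W / (W + lam_i)
    spacing = (sample.spacing[0] * (H + lam_i) / H, sample.spacing[1] * (W + lam_i) / W)
    geom = sample.geometry
    if geom is not None:
        geom = geom.with_(
            apex=(geom.apex[0] * s_r, (geom.apex[1] + pad_l) * s_c),
            radius=geom.radius * s_r,
        )
    out = sample.replace(
        image=np.clip(image, 0.0, 1.0),
        mask=mask,
        spacing=spacing,
        geometry=geom,
        provenance=sample.provenance + [prov],
    )
    return out, keep_new


def _rotation(theta_deg):
    th = math.radians(theta_deg)
    return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])


def tilt(sample: LabeledSample, theta_deg: float, keep=None):
    """Rotate image and mask by ``theta_deg`` about the sector apex.

    Positive angles swing the sector toward increasing columns; content
    leaving the frame is cropped.
    """
    th = float(theta_deg)
    if not -30.0 <= th <= 30.0:
        raise InvalidArgumentError(f"theta must be in (-30, 30), got {th}")
    if sample.geometry is None:
        raise ContractError("tilt requires sector geometry")
    keep0 = _keep_or_support(sample, keep)
    prov = {"transform": "tilt", "theta_deg": th}
    if th == 0:
        return sample.replace(provenance=sample.provenance + [prov]), keep0
    apex = np.asarray(sample.geometry.apex, dtype=np.float64)
    M = _rotation(-th)  # inverse map: output -> input
    offset = apex - M @ apex
    image = _affine(sample.image, M, offset, order=1)
    mask = _affine(sample.mask, M, offset, order=0).astype(np.uint8)
    keep_new = _affine(keep0.astype(np.uint8), M, offset, order=0).astype(bool)
    geom = sample.geometry.with_(axis_angle=sample.geometry.axis_angle + th)
    out = sample.replace(
        image=np.clip(image, 0.0, 1.0),
        mask=mask,
        geometry=geom,
        provenance=sample.provenance + [prov],
    )
    return out, keep_new


def width_adjust(sample: LabeledSample, factor: float, keep=None):
    """Scale columns about the apex column by ``factor``.

    ``factor > 1`` stretches the sector laterally (implicitly cropped by the
    frame); ``factor < 1`` squeezes it toward the apex column, leaving black
    gaps.  Column spacing is divided by ``factor`` — the induced anisotropy
    is tracked, not corrected.
    """
    f = float(factor)
    if not 0.5 <= f <= 1.5:
        raise InvalidArgumentError(f"factor must be in (0.5, 1.5), got {f}")
    keep0 = _keep_or_support(sample, keep)
    prov = {"transform": "width_adjust", "factor": f}
    if f == 1.0:
        return sample.replace(provenance=sample.provenance + [prov]), keep0
    if sample.geometry is not None:
        apex_c = sample.geometry.apex[1]
    else:
        apex_c = (sample.shape[1] - 1) / 2.0
    M = np.array([[1.0, 0.0], [0.0, 1.0 / f]])
    offset = np.array([0.0, apex_c * (1.0 - 1.0 / f)])
    image = _affine(sample.image, M, offset, order=1)
    mask = _affine(sample.mask, M, offset, order=0).astype(np.uint8)
    keep_new = _affine(keep0.astype(np.uint8), M, offset, order=0).astype(bool)
    geom = sample.geometry
    if geom is not None:
        half = math.radians(geom.opening_angle / 2.0)
        new_half = math.degrees(math.atan(f * math.tan(half)))
        axis = math.degrees(math.atan(f * math.tan(math.radians(geom.axis_angle))))
        geom = geom.with_(opening_angle=2.0 * new_half, axis_angle=axis)
    out = sample.replace(
        image=np.clip(image, 0.0, 1.0),
        mask=mask,
        geometry=geom,
        spacing=(sample.spacing[0], sample.spacing[1] / f),
        provenance=sample.provenance + [prov],
    )
    return out, keep_new


def translation_shift(angle_deg: float, length_px: float):
    """Integer pixel shift for a translation of ``length_px`` at
    ``angle_deg`` counterclockwise from image-right."""
    phi = math.radians(angle_deg)
    return (
        int(round(-length_px * math.sin(phi))),
        int(round(length_px * math.cos(phi))),
    )


def _shift2d(arr, dr, dc, cval=0):
    out = np.full_like(arr, cval)
    H, W = arr.shape
    r0d, r1d = max(0, dr), min(H, H + dr)
    c0d, c1d = max(0, dc), min(W, W + dc)
    if r0d >= r1d or c0d >= c1d:
        return out
    out[r0d:r1d, c0d:c1d] = arr[r0d - dr : r1d - dr, c0d - dc : c1d - dc]
    return out


def translate(sample: LabeledSample, angle_deg: float, length_px: float, keep=None):
    """Shift the frame by an integer-rounded vector; exposed pixels are black
    and content leaving the frame is cropped."""
    L = float(length_px)
    if not 0.0 <= L <= 50.0:
        raise InvalidArgumentError(f"length must be in (0, 50), got {L}")
    keep0 = _keep_or_support(sample, keep)
    dr, dc = translation_shift(angle_deg, L)
    prov = {
        "transform": "translate",
        "angle_deg": float(angle_deg),
        "length_px": L,
        "shift": (dr, dc),
    }
    if dr == 0 and dc == 0:
        return sample.replace(provenance=sample.provenance + [prov]), keep0
    image = _shift2d(sample.image, dr, dc)
    mask = _shift2d(sample.mask, dr, dc)
    keep_new = _shift2d(keep0.astype(np.uint8), dr, dc).astype(bool)
    geom = sample.geometry
    if geom is not None:
        geom = geom.with_(apex=(geom.apex[0] + dr, geom.apex[1] + dc))
    out = sample.replace(
        image=image, mask=mask, geometry=geom, provenance=sample.provenance + [prov]
    )
    return out, keep_new


# ---------------------------------------------------------------------------
# combination and baseline
# ---------------------------------------------------------------------------

def _draw_combination(config: AugmentationConfig, rng):
    p = config.combination_probability
    flags = {
        "depth": bool(rng.random() < p),
        "tilt": bool(rng.random() < p),
        "width": bool(rng.random() < p),
        "translate": bool(rng.random() < p),
    }
    params = {}
    if flags["depth"]:
        params["lambda_px"] = float(rng.uniform(*config.depth_lambda_range))
    if flags["tilt"]:
        params["theta_deg"] = float(rng.uniform(*config.tilt_range))
    if flags["width"]:
        params["factor"] = float(rng.uniform(*config.width_factor_range))
    if flags["translate"]:
        params["trans_angle_deg"] = float(rng.uniform(0.0, 360.0))
        params["trans_length_px"] = float(rng.uniform(*config.translation_length_range))
    return flags, params


def apply_combination(sample: LabeledSample, flags: dict, params: dict):
    """Apply the recorded transforms in the fixed order
    depth -> tilt -> width -> translate, chaining the keep mask."""
    out, keep = sample, sample.support()
    if flags.get("depth"):
        out, keep = depth_increase(out, params["lambda_px"], keep)
    if flags.get("tilt"):
        out, keep = tilt(out, params["theta_deg"], keep)
    if flags.get("width"):
        out, keep = width_adjust(out, params["factor"], keep)
    if flags.get("translate"):
        out, keep = translate(
            out, params["trans_angle_deg"], params["trans_length_px"], keep
        )
    return out, keep


def combine(sample: LabeledSample, config: AugmentationConfig, rng, max_redraws: int = 20):
    """Independently apply each transform with the configured probability.

    Draws are redrawn (up to ``max_redraws``) when cropping removes more than
    the configured fraction of LV pixels.  Returns
    ``(sample, keep_mask, provenance)`` where provenance records the drawn
    flags and parameters.
    """
    lv_before = int((sample.mask == LV).sum())
    for _ in range(max_redraws):
        flags, params = _draw_combination(config, rng)
        out, keep = apply_combination(sample, flags, params)
        lv_after = int((out.mask == LV).sum())
        if lv_before == 0 or lv_after >= config.min_lv_retention * lv_before:
            prov = {"transform": "combine", "flags": flags, "params": params}
            out = out.replace(provenance=out.provenance + [prov])
            return out, keep, prov
    raise GenerationError(
        f"no combination retained {config.min_lv_retention:.0%} of LV pixels "
        f"after {max_redraws} redraws"
    )


def blackout_baseline(sample: LabeledSample, config: AugmentationConfig, rng):
    """Same transform chain as :func:`combine` but the repaint region is left
    black instead of being synthesized."""
    out, keep, prov = combine(sample, config, rng)
    image = np.where(keep, out.image, 0.0)
    return out.replace(
        image=image, provenance=out.provenance + [{"transform": "blackout"}]
    )


# ---------------------------------------------------------------------------
# DDPM-training preprocessing
# ---------------------------------------------------------------------------

def narrow_width_pretrain(frame, delta_deg=None, geometry: SectorGeometry | None = None, rng=None):
    """Narrow the sector opening by ``delta_deg`` (removing peripheral scan
    lines symmetrically) and stretch the cut sector horizontally back to full
    frame width.  Used only to diversify DDPM training data.

    When ``delta_deg`` is None it is drawn uniformly from [0, 20].
    """
    frame = np.asarray(frame, dtype=np.float64)
    if delta_deg is None:
        if rng is None:
            raise InvalidArgumentError("either delta_deg or rng must be given")
        delta_deg = float(rng.uniform(0.0, 20.0))
    delta = float(delta_deg)
    if not 0.0 <= delta <= 20.0:
        raise InvalidArgumentError(f"delta must be in [0, 20], got {delta}")
    if geometry is None:
        geometry, _ = detect_sector(frame)
    half = geometry.opening_angle / 2.0
    new_half = half - delta / 2.0
    if new_half <= 0:
        raise InvalidArgumentError(
            f"delta {delta} would close the {geometry.opening_angle} degree sector"
        )
    if delta == 0:
        return frame.copy()
    cut_geom = geometry.with_(opening_angle=2.0 * new_half)
    cut = frame * sector_support(cut_geom, frame.shape)
    f = math.tan(math.radians(half)) / math.tan(math.radians(new_half))
    apex_c = geometry.apex[1]
    M = np.array([[1.0, 0.0], [0.0, 1.0 / f]])
    offset = np.array([0.0, apex_c * (1.0 - 1.0 / f)])
    return np.clip(_affine(cut, M, offset, order=1), 0.0, 1.0)


def subsample_every_nth(frames, rng, stride_range=(8, 12)):
    """Keep a frame, then skip a freshly drawn N-1 frames, N uniform in the
    stride range; repeats until the sequence is exhausted."""
    n = len(frames)
    if n == 0:
        raise InvalidArgumentError("frame sequence must be non-empty")
    lo, hi = int(stride_range[0]), int(stride_range[1])
    if lo < 1 or lo > hi:
        raise InvalidArgumentError(f"invalid stride range {stride_range}")
    kept = [0]
    idx = 0
    while True:
        idx += int(rng.integers(lo, hi + 1))
        if idx >= n:
            break
        kept.append(idx)
    return [frames[i] for i in kept]


# ---------------------------------------------------------------------------
# full augmentation protocol
# ---------------------------------------------------------------------------

def augment_dataset(samples, predictor, schedule, config: AugmentationConfig, seed: int):
    """Original + ``n_augment_per_image`` combine->repaint samples per input.

    Labeled pixels of every emitted sample are bit-identical to the
    transformed (pre-repaint) image; repaint failures are logged into the
    provenance and redrawn up to 3 times.
    """
    from .repaint import repaint  # local import to avoid a cycle

    if len(samples) == 0:
        raise InvalidArgumentError("input set must be non-empty")
    out = []
    for i, sample in enumerate(samples):
        out.append(sample)
        for k in range(config.n_augment_per_image):
            last_exc = None
            for retry in range(3):
                ss = np.random.SeedSequence(entropy=seed, spawn_key=(i, k, retry))
                rng = np.random.default_rng(ss)
                ts, keep, prov = combine(sample, config, rng)
                if ((ts.mask > 0) & ~keep).any():
                    raise ContractError("labeled pixel outside the keep mask")
                try:
                    painted = repaint(
                        predictor,
                        schedule,
                        ts.image,
                        keep.astype(np.uint8),
                        rng=rng,
                        jump_length=config.jump_length,
                        n_resample=config.n_resample,
                    )
                except Exception as exc:  # noqa: BLE001 - redraw on any failure
                    last_exc = exc
                    continue
                emitted = ts.replace(
                    image=painted,
                    provenance=ts.provenance
                    + [
                        {
                            "transform": "repaint",
                            "seed": seed,
                            "spawn_key": (i, k, retry),
                            "jump_length": config.jump_length,
                            "n_resample": config.n_resample,
                        }
                    ],
                )
                out.append(emitted)
                break
            else:
                raise GenerationError(
                    f"repaint failed 3 times for sample {i} augmentation {k}"
                ) from last_exc
    return out
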