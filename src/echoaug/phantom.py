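"""Synthetic speckled sector phantoms with exact LV/MYO masks.

This module is the package's self-contained data source: it renders
fan-shaped B-mode-like frames with an elliptical LV cavity (dark) wrapped by
a myocardial annulus (bright), multiplicative Rayleigh-like speckle, and
emits exact masks, geometry and physical spacing alongside every image.
Presets mimic the depth/angle/EF distributions of the two source dataset
families (LV-focused vs. more varied acquisitions).

Cine sequences model the LV as a 3-D ellipsoid whose volume oscillates
sinusoidally between EDV and ESV; the two orthogonal long-axis cross
sections are rendered as the A2C and A4C views, and ground-truth volumes
come from the closed form (4/3) pi a b c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import GenerationError, InvalidArgumentError
from .geometry import SectorGeometry, sector_support
from .transforms import LabeledSample, LV, MYO

__all__ = [
    "PhantomConfig",
    "hunt4like",
    "camuslike",
    "generate_sample",
    "generate_cine",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition- and anatomy-parameter distributions for the phantom."""

    depth_mean_mm: float = 127.8
    depth_sd_mm: float = 12.2
    angle_mean_deg: float = 65.5
    angle_sd_deg: float = 4.0
    ef_mean: float = 0.591
    ef_sd: float = 0.066
    lv_long_semi_mm: tuple = (32.0, 44.0)  # semi-axis along the LV long axis
    lv_short_semi_mm: tuple = (16.0, 24.0)
    myo_thickness_mm: float = 8.0
    speckle_scale: float = 0.35
    speckle_smoothing_px: float = 1.2
    image_size: int = 256
    anatomy_scale: float = 1.0  # shrink the LV for very coarse renderings

    def __post_init__(self):
        if self.depth_sd_mm < 0 or self.angle_sd_deg < 0 or self.ef_sd < 0:
            raise InvalidArgumentError("standard deviations must be >= 0")
        if self.myo_thickness_mm <= 0:
            raise InvalidArgumentError("myocardial thickness must be positive")

    def with_(self, **kwargs):
        return replace(self, **kwargs)


def hunt4like(**overrides) -> PhantomConfig:
    """LV-focused acquisitions: shallow depth, narrow angle, high EF."""
    return PhantomConfig(**overrides)


def camuslike(**overrides) -> PhantomConfig:
    """More varied acquisitions: deeper, wider, broader EF range."""
    cfg = PhantomConfig(
        depth_mean_mm=151.6,
        depth_sd_mm=24.5,
        angle_mean_deg=75.2,
        angle_sd_deg=5.8,
        ef_mean=0.525,
        ef_sd=0.123,
    )
    return cfg.with_(**overrides) if overrides else cfg


PRESETS = {"hunt4like": hunt4like, "camuslike": camuslike}


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, semi_u, semi_v, orient_deg):
    """Pixels inside an ellipse with semi-axis ``semi_u`` along the direction
    ``orient_deg`` (degrees from straight down, + toward +col)."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    dr = rr - center[0]
    dc = cc - center[1]
    a = math.radians(orient_deg)
    u = dr * math.cos(a) + dc * math.sin(a)
    v = -dr * math.sin(a) + dc * math.cos(a)
    return (u / semi_u) ** 2 + (v / semi_v) ** 2 <= 1.0


def _speckle(shape, rng, smoothing, scale):
    """Unit-mean multiplicative speckle from squared smoothed Gaussians."""
    g1 = ndimage.gaussian_filter(rng.standard_normal(shape), smoothing)
    g2 = ndimage.gaussian_filter(rng.standard_normal(shape), smoothing)
    sp = g1**2 + g2**2
    sp /= sp.mean()
    return (1.0 - scale) + scale * sp


_BG, _MYO_INT, _LV_INT = 0.35, 0.75, 0.08


def _render(support, lv, myo, rng, config):
    base = np.zeros(support.shape)
    base[support] = _BG
    base[myo] = _MYO_INT
    base[lv] = _LV_INT
    img = base * _speckle(support.shape, rng, config.speckle_smoothing_px, config.speckle_scale)
    img[~support] = 0.0
    return np.clip(img, 0.0, 1.0)


def _draw_acquisition(config, rng):
    depth = float(np.clip(rng.normal(config.depth_mean_mm, config.depth_sd_mm), 60.0, None))
    angle = float(np.clip(rng.normal(config.angle_mean_deg, config.angle_sd_deg), 30.0, 110.0))
    return depth, angle


def _sector_frame(config, depth_mm, angle_deg):
    S = config.image_size
    spacing = depth_mm / S
    apex = (2.0, (S - 1) / 2.0)
    radius = S - 2.0 - apex[0]
    geom = SectorGeometry(apex=apex, opening_angle=angle_deg, radius=radius)
    return geom, (spacing, spacing)


# ---------------------------------------------------------------------------
# single frames
# ---------------------------------------------------------------------------

def generate_sample(config: PhantomConfig, seed: int):
    """One speckled sector frame with exact LV/MYO masks.

    Returns ``(LabeledSample, truth)`` where ``truth`` records the drawn
    acquisition and anatomy parameters.  Raises :class:`GenerationError` when
    the LV does not fit inside the sector after 20 redraws.
    """
    rng = np.random.default_rng(seed)
    S = config.image_size
    for _ in range(20):
        depth, angle = _draw_acquisition(config, rng)
        geom, spacing = _sector_frame(config, depth, angle)
        support = sector_support(geom, (S, S))

        a_mm = config.anatomy_scale * float(rng.uniform(*config.lv_long_semi_mm))
        b_mm = config.anatomy_scale * float(rng.uniform(*config.lv_short_semi_mm))
        a_px, b_px = a_mm / spacing[0], b_mm / spacing[1]
        th_px = max(1.5, config.anatomy_scale * config.myo_thickness_mm / spacing[0])
        orient = float(rng.uniform(-10.0, 10.0))
        frac = float(rng.uniform(0.45, 0.62))
        ar, ac = geom.axis_vector
        center = (
            geom.apex[0] + frac * geom.radius * ar,
            geom.apex[1] + frac * geom.radius * ac,
        )
        lv = _ellipse_mask((S, S), center, a_px, b_px, orient)
        outer = _ellipse_mask((S, S), center, a_px + th_px, b_px + th_px, orient)
        inner_support = ndimage.binary_erosion(support, border_value=0)
        if not lv.any() or not (outer & ~inner_support).sum() == 0:
            continue
        myo = outer & ~lv
        mask = np.zeros((S, S), dtype=np.uint8)
        mask[myo] = MYO
        mask[lv] = LV
        image = _render(support, lv, myo, rng, config)
        sample = LabeledSample(
            image=image,
            mask=mask,
            geometry=geom,
            spacing=spacing,
            provenance=[{"transform": "phantom", "seed": int(seed)}],
        )
        truth = {
            "depth_mm": depth,
            "angle_deg": angle,
            "geometry": geom,
            "lv_semi_axes_mm": (a_mm, b_mm),
            "lv_center_px": center,
            "lv_orientation_deg": orient,
        }
        return sample, truth
    raise GenerationError("LV did not fit in the sector after 20 redraws")


# ---------------------------------------------------------------------------
# cine sequences
# ---------------------------------------------------------------------------

def generate_cine(config: PhantomConfig, n_frames: int, ef_target: float, seed: int):
    """A2C and A4C frame/mask sequences with a prescribed ejection fraction.

    The LV is a 3-D ellipsoid with semi-axes ``(a, b, c)``; ``b`` and ``c``
    are scaled by ``sqrt(V(t)/EDV)`` so the volume follows
    ``V(t) = ESV + (EDV - ESV) (1 + cos(2 pi k / n)) / 2`` with
    ``ESV = (1 - ef_target) EDV``.

    Returns a dict with ``a2c``/``a4c`` lists of :class:`LabeledSample` and a
    ``truth`` record (ED/ES indices, EDV, ESV in ml, EF).
    """
    if not 0.0 < ef_target < 1.0:
        raise InvalidArgumentError(f"ef_target must be in (0, 1), got {ef_target}")
    n_frames = int(n_frames)
    if n_frames < 2:
        raise InvalidArgumentError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    S = config.image_size

    for _ in range(20):
        depth, angle = _draw_acquisition(config, rng)
        geom, spacing = _sector_frame(config, depth, angle)
        support = sector_support(geom, (S, S))
        a_mm = config.anatomy_scale * float(rng.uniform(*config.lv_long_semi_mm))
        b_mm = config.anatomy_scale * float(rng.uniform(*config.lv_short_semi_mm))
        c_mm = b_mm * float(rng.uniform(0.9, 1.1))
        th_px = max(1.5, config.anatomy_scale * config.myo_thickness_mm / spacing[0])
        frac = float(rng.uniform(0.45, 0.58))
        ar, ac = geom.axis_vector
        center = (
            geom.apex[0] + frac * geom.radius * ar,
            geom.apex[1] + frac * geom.radius * ac,
        )
        # require the ED-size outer shell of both views inside the sector
        big = max(b_mm, c_mm)
        outer = _ellipse_mask(
            (S, S), center, a_mm / spacing[0] + th_px, big / spacing[1] + th_px, 0.0
        )
        inner_support = ndimage.binary_erosion(support, border_value=0)
        if (outer & ~inner_support).sum() == 0:
            break
    else:
        raise GenerationError("LV did not fit in the sector after 20 redraws")

    edv_ml = 4.0 / 3.0 * math.pi * a_mm * b_mm * c_mm / 1000.0
    esv_ml = (1.0 - ef_target) * edv_ml
    k = np.arange(n_frames)
    volumes = esv_ml + (edv_ml - esv_ml) * (1.0 + np.cos(2.0 * math.pi * k / n_frames)) / 2.0
    scales = np.sqrt(volumes / edv_ml)

    views = {"a2c": b_mm, "a4c": c_mm}
    out = {"a2c": [], "a4c": []}
    for view, short_mm in views.items():
        for s in scales:
            a_px = a_mm / spacing[0]
            b_px = s * short_mm / spacing[1]
            lv = _ellipse_mask((S, S), center, a_px, b_px, 0.0)
            shell = _ellipse_mask((S, S), center, a_px + th_px, b_px + th_px, 0.0)
            myo = shell & ~lv
            mask = np.zeros((S, S), dtype=np.uint8)
            mask[myo] = MYO
            mask[lv] = LV
            image = _render(support, lv, myo, rng, config)
            out[view].append(
                LabeledSample(
                    image=image,
                    mask=mask,
                    geometry=geom,
                    spacing=spacing,
                    provenance=[{"transform": "phantom_cine", "view": view}],
                )
            )
    out["truth"] = {
        "ed_index": 0,
        "es_index": int(np.argmin(volumes)),
        "edv_ml": float(edv_ml),
        "esv_ml": float(esv_ml),
        "ef": float(ef_target),
        "semi_axes_mm": (a_mm, b_mm, c_mm),
        "volumes_ml": volumes.tolist(),
    }
    return out
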