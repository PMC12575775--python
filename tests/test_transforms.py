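"""The five generative augmentations and their label-safety guarantees."""

import math

import numpy as np
import pytest

from echoaug import phantom, transforms as tr
from echoaug.errors import ContractError, GenerationError, InvalidArgumentError
from echoaug.geometry import detect_sector
from echoaug.metrics import dice
from conftest import SMALL_ANATOMY


@pytest.fixture(scope="module")
def sample256():
    s, truth = phantom.generate_sample(phantom.hunt4like(image_size=256), seed=3)
    return s, truth


# ---------------------------------------------------------------------------
# LabeledSample / AugmentationConfig
# ---------------------------------------------------------------------------

def test_labeled_sample_validation():
    with pytest.raises(InvalidArgumentError):
        tr.LabeledSample(image=np.zeros((4, 4)), mask=np.zeros((3, 3)))
    with pytest.raises(InvalidArgumentError):
        tr.LabeledSample(image=np.zeros((4, 4)), mask=np.full((4, 4), 7))
    with pytest.raises(InvalidArgumentError):
        tr.LabeledSample(image=np.zeros((4, 4)), mask=np.zeros((4, 4)), spacing=(0, 1))


def test_augmentation_config_validation():
    with pytest.raises(InvalidArgumentError):
        tr.AugmentationConfig(depth_lambda_range=(100, 0))
    with pytest.raises(InvalidArgumentError):
        tr.AugmentationConfig(combination_probability=1.5)


# ---------------------------------------------------------------------------
# depth increase
# ---------------------------------------------------------------------------

def test_depth_identity(phantom_sample_64):
    s, _ = phantom_sample_64
    out, keep = tr.depth_increase(s, 0)
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)
    assert out.spacing == s.spacing
    assert np.array_equal(keep, s.support())


def test_depth_area_scaling_oracle(sample256):
    s, _ = sample256
    out, keep = tr.depth_increase(s, 128)
    ratio = (out.mask == 1).sum() / (s.mask == 1).sum()
    expected = (256 / 384) ** 2
    assert abs(ratio - expected) / expected < 0.05
    assert not ((out.mask > 0) & ~keep).any()


def test_depth_spacing_bookkeeping(sample256):
    s, _ = sample256
    out, _ = tr.depth_increase(s, 150)
    assert out.spacing[0] == pytest.approx(s.spacing[0] * 406 / 256, rel=1e-12)
    assert out.spacing[1] == pytest.approx(s.spacing[1] * 406 / 256, rel=1e-12)


def test_depth_physical_lv_area_invariant(sample256):
    s, _ = sample256
    area0 = (s.mask == 1).sum() * s.spacing[0] * s.spacing[1]
    out, _ = tr.depth_increase(s, 100)
    area1 = (out.mask == 1).sum() * out.spacing[0] * out.spacing[1]
    assert abs(area1 - area0) / area0 < 0.05


def test_depth_range_validation(phantom_sample_64):
    s, _ = phantom_sample_64
    with pytest.raises(InvalidArgumentError):
        tr.depth_increase(s, -1)
    with pytest.raises(InvalidArgumentError):
        tr.depth_increase(s, 151)


# ---------------------------------------------------------------------------
# tilt
# ---------------------------------------------------------------------------

def test_tilt_identity(phantom_sample_64):
    s, _ = phantom_sample_64
    out, keep = tr.tilt(s, 0)
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)


def test_tilt_round_trip_dice(phantom_sample_128):
    s, _ = phantom_sample_128
    fwd, _ = tr.tilt(s, 20)
    back, _ = tr.tilt(fwd, -20)
    assert dice(back.mask, s.mask, 1) >= 0.98
    assert dice(back.mask, s.mask, 2) >= 0.98


def test_tilt_labeled_pixels_stay_in_keep():
    rng = np.random.default_rng(0)
    for i in range(10):
        s, _ = phantom.generate_sample(phantom.hunt4like(image_size=64), seed=100 + i)
        theta = float(rng.uniform(-29, 29))
        out, keep = tr.tilt(s, theta)
        assert not ((out.mask > 0) & ~keep).any()


def test_tilt_requires_geometry(phantom_sample_64):
    s, _ = phantom_sample_64
    bare = s.replace(geometry=None)
    with pytest.raises(ContractError):
        tr.tilt(bare, 10)
    with pytest.raises(InvalidArgumentError):
        tr.tilt(s, 31)


# ---------------------------------------------------------------------------
# width adjustment
# ---------------------------------------------------------------------------

def test_width_identity(phantom_sample_64):
    s, _ = phantom_sample_64
    out, keep = tr.width_adjust(s, 1.0)
    assert np.array_equal(out.image, s.image)
    assert out.spacing == s.spacing


def test_width_angle_oracle(phantom_sample_128):
    s, truth = phantom_sample_128
    out, _ = tr.width_adjust(s, 0.5)
    est, _ = detect_sector(out.image)
    half = math.radians(truth["geometry"].opening_angle / 2)
    expected = 2 * math.degrees(math.atan(0.5 * math.tan(half)))
    assert abs(est.opening_angle - expected) < 2.0


def test_width_area_scales_with_factor(phantom_sample_128):
    s, _ = phantom_sample_128
    for f in (0.6, 1.4):
        out, keep = tr.width_adjust(s, f)
        ratio = (out.mask == 1).sum() / (s.mask == 1).sum()
        assert abs(ratio - f) / f < 0.05
        assert not ((out.mask > 0) & ~keep).any()


def test_width_spacing_and_validation(phantom_sample_64):
    s, _ = phantom_sample_64
    out, _ = tr.width_adjust(s, 1.25)
    assert out.spacing[1] == pytest.approx(s.spacing[1] / 1.25)
    assert out.spacing[0] == s.spacing[0]
    with pytest.raises(InvalidArgumentError):
        tr.width_adjust(s, 0.4)
    with pytest.raises(InvalidArgumentError):
        tr.width_adjust(s, 1.6)


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def test_translate_zero_length_identity(phantom_sample_64):
    s, _ = phantom_sample_64
    out, keep = tr.translate(s, 123.0, 0.0)
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)


def test_translate_pure_row_shift_exact(phantom_sample_64):
    s, _ = phantom_sample_64
    # angle 270 degrees (image-down): shift of (+10 rows, 0 cols)
    out, keep = tr.translate(s, 270.0, 10.0)
    expected = np.zeros_like(s.mask)
    expected[10:, :] = s.mask[:-10, :]
    assert np.array_equal(out.mask, expected)


def test_translate_never_gains_labeled_pixels(phantom_sample_64):
    s, _ = phantom_sample_64
    rng = np.random.default_rng(1)
    for _ in range(10):
        out, keep = tr.translate(s, float(rng.uniform(0, 360)), float(rng.uniform(0, 50)))
        assert (out.mask > 0).sum() <= (s.mask > 0).sum()
        assert not ((out.mask > 0) & ~keep).any()


def test_translate_shift_convention():
    assert tr.translation_shift(0.0, 10.0) == (0, 10)  # image-right
    assert tr.translation_shift(90.0, 10.0) == (-10, 0)  # image-up
    assert tr.translation_shift(270.0, 10.0) == (10, 0)  # image-down


# ---------------------------------------------------------------------------
# combination / blackout
# ---------------------------------------------------------------------------

class _ForcedRng:
    """Stub rng driving the combination draw deterministically."""

    def __init__(self, flags, uniforms=()):
        self._flags = list(flags)
        self._uniforms = list(uniforms)

    def random(self):
        return 0.0 if self._flags.pop(0) else 1.0

    def uniform(self, lo, hi):
        return self._uniforms.pop(0) if self._uniforms else (lo + hi) / 2.0


def test_combine_all_off_is_identity(phantom_sample_64):
    s, _ = phantom_sample_64
    out, keep, prov = tr.combine(s, tr.AugmentationConfig(), _ForcedRng([0, 0, 0, 0]))
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)
    assert not any(prov["flags"].values())
    assert np.array_equal(keep, s.support())


def test_combine_matches_manual_sequential_application(phantom_sample_128):
    s, _ = phantom_sample_128
    rng = np.random.default_rng(77)
    cfg = tr.AugmentationConfig()
    out, keep, prov = tr.combine(s, cfg, rng)
    manual, mkeep = tr.apply_combination(s, prov["flags"], prov["params"])
    assert np.array_equal(out.image, manual.image)
    assert np.array_equal(out.mask, manual.mask)
    assert np.array_equal(keep, mkeep)


def test_combine_application_frequency():
    cfg = tr.AugmentationConfig()
    rng = np.random.default_rng(0)
    counts = np.zeros(4)
    n = 10_000
    for _ in range(n):
        flags, _ = tr._draw_combination(cfg, rng)
        counts += [flags["depth"], flags["tilt"], flags["width"], flags["translate"]]
    assert np.all(counts / n >= 0.48)
    assert np.all(counts / n <= 0.52)


def test_combine_label_safety_100_random_draws():
    rng = np.random.default_rng(42)
    cfg = tr.AugmentationConfig()
    for i in range(20):
        s, _ = phantom.generate_sample(phantom.hunt4like(image_size=64), seed=500 + i)
        for _ in range(5):
            out, keep, _ = tr.combine(s, cfg, rng)
            assert not ((out.mask > 0) & ~keep).any()


def test_blackout_baseline_matches_combine_pre_repaint(phantom_sample_64):
    s, _ = phantom_sample_64
    cfg = tr.AugmentationConfig()
    out_c, keep, _ = tr.combine(s, cfg, np.random.default_rng(9))
    out_b = tr.blackout_baseline(s, cfg, np.random.default_rng(9))
    expected = np.where(keep, out_c.image, 0.0)
    assert np.array_equal(out_b.image, expected)
    assert np.array_equal(out_b.mask, out_c.mask)
    assert np.all(out_b.image[~keep] == 0.0)


def test_blackout_identity_draw(phantom_sample_64):
    s, _ = phantom_sample_64
    out = tr.blackout_baseline(s, tr.AugmentationConfig(), _ForcedRng([0, 0, 0, 0]))
    # identity transform: only off-support pixels (already black) are zeroed
    assert np.array_equal(out.image, np.where(s.support(), s.image, 0.0))


# ---------------------------------------------------------------------------
# DDPM-training preprocessing
# ---------------------------------------------------------------------------

def test_narrow_width_identity(phantom_sample_128):
    s, _ = phantom_sample_128
    out = tr.narrow_width_pretrain(s.image, 0.0, geometry=s.geometry)
    assert np.array_equal(out, s.image)


def test_narrow_width_angle_oracle():
    s, truth = phantom.generate_sample(
        phantom.hunt4like(image_size=128, angle_mean_deg=75.0, angle_sd_deg=0.0), seed=2
    )
    geom = truth["geometry"]
    out = tr.narrow_width_pretrain(s.image, 20.0, geometry=geom)
    est, _ = detect_sector(out)
    f = math.tan(math.radians(geom.opening_angle / 2)) / math.tan(
        math.radians((geom.opening_angle - 20) / 2)
    )
    recovered = 2 * math.degrees(
        math.atan(math.tan(math.radians(est.opening_angle / 2)) / f)
    )
    assert abs(recovered - (geom.opening_angle - 20)) < 2.0


def test_narrow_width_restores_lateral_extent():
    s, truth = phantom.generate_sample(phantom.hunt4like(image_size=128), seed=4)
    out = tr.narrow_width_pretrain(s.image, 15.0, geometry=truth["geometry"])
    cols_orig = np.flatnonzero((s.image > 0.02).any(axis=0))
    cols_out = np.flatnonzero((out > 0.02).any(axis=0))
    extent_orig = cols_orig[-1] - cols_orig[0]
    extent_out = cols_out[-1] - cols_out[0]
    assert extent_out >= extent_orig - 2


def test_narrow_width_validation(phantom_sample_64):
    s, _ = phantom_sample_64
    with pytest.raises(InvalidArgumentError):
        tr.narrow_width_pretrain(s.image, 25.0, geometry=s.geometry)
    narrow = s.geometry.with_(opening_angle=15.0)
    with pytest.raises(InvalidArgumentError):
        tr.narrow_width_pretrain(s.image, 16.0, geometry=narrow)


# ---------------------------------------------------------------------------
# frame subsampling
# ---------------------------------------------------------------------------

def test_subsample_bounds_on_100_frames():
    frames = list(range(100))
    for seed in range(20):
        kept = tr.subsample_every_nth(frames, np.random.default_rng(seed))
        assert 9 <= len(kept) <= 13
        assert kept[0] == 0
        gaps = np.diff(kept)
        assert np.all((gaps >= 8) & (gaps <= 12))


def test_subsample_single_frame_and_determinism():
    assert tr.subsample_every_nth(["only"], np.random.default_rng(0)) == ["only"]
    frames = list(range(200))
    a = tr.subsample_every_nth(frames, np.random.default_rng(5))
    b = tr.subsample_every_nth(frames, np.random.default_rng(5))
    assert a == b
    with pytest.raises(InvalidArgumentError):
        tr.subsample_every_nth([], np.random.default_rng(0))


# ---------------------------------------------------------------------------
# full augmentation protocol
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def augment_setup(image_model):
    cfg = tr.AugmentationConfig(
        n_augment_per_image=5,
        depth_lambda_range=(0, 18),
        translation_length_range=(0, 6),
        jump_length=2,
        n_resample=2,
    )
    out = tr.augment_dataset(
        image_model["samples"],
        image_model["predictor"],
        image_model["sampling_schedule"],
        cfg,
        seed=5,
    )
    return cfg, out


def test_augment_emits_six_times_input(image_model, augment_setup):
    _, out = augment_setup
    assert len(out) == 6 * len(image_model["samples"])


def test_augment_labeled_pixels_bit_identical(image_model, augment_setup):
    cfg, out = augment_setup
    # re-derive the pre-repaint transformed image from the recorded provenance
    for i, original in enumerate(image_model["samples"]):
        for k in range(cfg.n_augment_per_image):
            emitted = out[i * 6 + 1 + k]
            rec = next(
                p for p in emitted.provenance if p.get("transform") == "repaint"
            )
            ss = np.random.SeedSequence(entropy=5, spawn_key=tuple(rec["spawn_key"]))
            pre, keep, _ = tr.combine(original, cfg, np.random.default_rng(ss))
            labeled = emitted.mask > 0
            assert np.array_equal(emitted.image[labeled], pre.image[labeled])
            assert np.array_equal(emitted.mask, pre.mask)
            assert np.array_equal(emitted.image[keep], pre.image[keep])


def test_augment_deterministic(image_model, augment_setup):
    cfg, out = augment_setup
    out2 = tr.augment_dataset(
        image_model["samples"],
        image_model["predictor"],
        image_model["sampling_schedule"],
        cfg,
        seed=5,
    )
    for a, b in zip(out, out2):
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)


def test_augment_empty_input_rejected(image_model):
    with pytest.raises(InvalidArgumentError):
        tr.augment_dataset(
            [], image_model["predictor"], image_model["sampling_schedule"],
            tr.AugmentationConfig(), seed=0,
        )


def test_augment_retries_then_fails(image_model):
    class _Boom:
        data_shape = image_model["predictor"].data_shape

        def __call__(self, x, t):
            raise RuntimeError("synthetic failure")

    with pytest.raises(GenerationError):
        tr.augment_dataset(
            image_model["samples"][:1], _Boom(), image_model["sampling_schedule"],
            tr.AugmentationConfig(n_augment_per_image=1, jump_length=2, n_resample=0),
            seed=0,
        )
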