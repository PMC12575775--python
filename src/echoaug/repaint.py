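"""Mask-guided inpainting on top of an unconditionally trained DDPM.

Known pixels (``keep_mask == 1``) are substituted into the reverse chain with
the noise level appropriate for each step; only the complement is
synthesized.  Forward "jumps" re-noise the composite so the generated region
harmonizes with the kept one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddpm import p_sample_step, posterior_params
from .errors import InvalidArgumentError
from .schedule import NoiseSchedule

__all__ = ["RepaintPlan", "build_jump_schedule", "repaint"]


def build_jump_schedule(T_sampling: int, jump_length: int = 10, n_resample: int = 10):
    """Sequence of latent levels visited during repainting.

    The list starts at ``T_sampling`` and ends at 0; consecutive entries
    differ by exactly 1.  A decreasing pair is a reverse (denoise) step, an
    increasing pair a forward (re-noise) step.  After every block of
    ``jump_length`` reverse steps the chain jumps forward ``jump_length``
    steps and descends again, ``n_resample`` times per block.  With
    ``n_resample = 0`` this is the plain descending chain.
    """
    T_sampling = int(T_sampling)
    jump_length = int(jump_length)
    n_resample = int(n_resample)
    if T_sampling < 1:
        raise InvalidArgumentError("T_sampling must be positive")
    if jump_length < 1:
        raise InvalidArgumentError("jump_length must be >= 1")
    if n_resample < 0:
        raise InvalidArgumentError("n_resample must be >= 0")
    ts = [T_sampling]
    t = T_sampling
    while t > 0:
        for _ in range(jump_length):
            if t == 0:
                break
            t -= 1
            ts.append(t)
        if t > 0:
            for _ in range(n_resample):
                for _ in range(jump_length):
                    t += 1
                    ts.append(t)
                for _ in range(jump_length):
                    t -= 1
                    ts.append(t)
    return ts


@dataclass
class RepaintPlan:
    """Jump-schedule hyperparameters plus the mask of pixels to keep."""

    keep_mask: np.ndarray
    jump_length: int = 10
    n_resample: int = 10
    times: list = field(default=None)

    def resolve_times(self, schedule: NoiseSchedule):
        if self.times is not None:
            return self.times
        return build_jump_schedule(schedule.T, self.jump_length, self.n_resample)


def repaint(
    predictor,
    schedule: NoiseSchedule,
    known_image,
    keep_mask,
    plan: RepaintPlan | None = None,
    rng=None,
    *,
    seed=None,
    jump_length: int = 10,
    n_resample: int = 10,
    known_noising: str = "one_shot",
):
    """Synthesize the complement of ``keep_mask`` around ``known_image``.

    Parameters
    ----------
    known_image:
        Grid in [0, 1] matching the predictor's data shape (an optional
        leading batch axis is allowed; the whole batch then shares one noise
        stream, equivalent to independent seeds per element).
    keep_mask:
        Binary grid; 1 marks pixels taken verbatim from ``known_image``.
    plan:
        Optional :class:`RepaintPlan`; overrides ``jump_length``/``n_resample``.
    known_noising:
        ``"one_shot"`` draws the known latent from q(x_t | x_0) independently
        at each level (the standard choice); ``"per_step"`` walks a single
        coherent trajectory of the known region using the closed-form
        posterior.

    The output is bit-identical to ``known_image`` on the kept region.
    """
    img = np.asarray(known_image, dtype=np.float64)
    m = np.asarray(keep_mask)
    batched = img.shape != predictor.data_shape
    core_shape = img.shape[1:] if batched else img.shape
    if core_shape != predictor.data_shape:
        raise InvalidArgumentError(
            f"image shape {img.shape} incompatible with predictor {predictor.data_shape}"
        )
    if m.shape != core_shape and m.shape != img.shape:
        raise InvalidArgumentError(
            f"keep_mask shape {m.shape} does not match image shape {img.shape}"
        )
    if not np.isin(np.unique(m), (0, 1)).all():
        raise InvalidArgumentError("keep_mask must be binary")
    mf = m.astype(np.float64)
    if batched and mf.shape == core_shape:
        mf = np.broadcast_to(mf, img.shape)
    if known_noising not in ("one_shot", "per_step"):
        raise InvalidArgumentError(f"unknown known_noising mode {known_noising!r}")

    if plan is None:
        plan = RepaintPlan(keep_mask=m, jump_length=jump_length, n_resample=n_resample)
    times = plan.resolve_times(schedule)

    if rng is None:
        rng = np.random.default_rng(seed)

    x0_known = 2.0 * img - 1.0
    x = rng.standard_normal(img.shape)
    xk = None
    if known_noising == "per_step":
        ab = schedule.alpha_bar_at(schedule.T)
        xk = np.sqrt(ab) * x0_known + np.sqrt(1.0 - ab) * rng.standard_normal(img.shape)

    for prev, cur in zip(times[:-1], times[1:]):
        if cur == prev - 1:
            x = p_sample_step(predictor, x, prev, schedule, rng)
            if cur > 0:
                if known_noising == "one_shot":
                    ab = schedule.alpha_bar_at(cur)
                    x_known = np.sqrt(ab) * x0_known + np.sqrt(
                        1.0 - ab
                    ) * rng.standard_normal(img.shape)
                else:
                    mean, var = posterior_params(x0_known, xk, prev, schedule)
                    x_known = mean + np.sqrt(var) * rng.standard_normal(img.shape)
                    xk = x_known
            else:
                x_known = x0_known
            x = mf * x_known + (1.0 - mf) * x
        elif cur == prev + 1:
            beta = schedule.beta_at(cur)
            x = np.sqrt(1.0 - beta) * x + np.sqrt(beta) * rng.standard_normal(img.shape)
            if known_noising == "per_step" and xk is not None:
                xk = np.sqrt(1.0 - beta) * xk + np.sqrt(beta) * rng.standard_normal(
                    img.shape
                )
        else:  # pragma: no cover - malformed plan
            raise InvalidArgumentError("jump schedule must move in unit steps")

    out = (np.clip(x, -1.0, 1.0) + 1.0) / 2.0
    keep = mf.astype(bool)
    out[keep] = img[keep]
    return out
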