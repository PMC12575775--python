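"""Variance schedules for the forward diffusion process.

The schedule owns the per-step noise variances ``beta_t`` and every quantity
derived from them (``alpha_t``, the cumulative product ``alpha_bar_t`` and the
closed-form posterior variance ``beta_tilde_t``).  Timesteps are 1-based:
``t = 1 .. T``, with ``alpha_bar_0 := 1`` so that the reverse chain terminates
exactly at the data.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError, TimestepRangeError

#: betas are clipped at this value so every forward step keeps a sliver of signal
BETA_MAX = 0.999

#: small offset in the cosine schedule that keeps beta_1 away from zero
COSINE_S = 0.008


class NoiseSchedule:
    """Per-timestep noise variances and derived cumulative quantities.

    Parameters
    ----------
    beta:
        Sequence of T variances, each strictly inside (0, 1).
    timestep_map:
        Optional mapping from the 1-based timesteps of *this* schedule to the
        1-based timesteps of the schedule a predictor was trained with.  Used
        by respaced (shortened) sampling schedules; identity by default.
    """

    def __init__(self, beta, timestep_map=None):
        beta = np.asarray(beta, dtype=np.float64)
        if beta.ndim != 1 or beta.size < 1:
            raise InvalidArgumentError("beta must be a non-empty 1-D sequence")
        if np.any(beta <= 0.0) or np.any(beta >= 1.0):
            raise InvalidArgumentError("every beta_t must lie strictly in (0, 1)")
        self.beta = beta
        self.alpha = 1.0 - beta
        self.alpha_bar = np.cumprod(self.alpha)
        # alpha_bar_prev[t-1] == alpha_bar_{t-1}, with alpha_bar_0 = 1
        self.alpha_bar_prev = np.concatenate(([1.0], self.alpha_bar[:-1]))
        self.posterior_variance = (
            (1.0 - self.alpha_bar_prev) / (1.0 - self.alpha_bar) * beta
        )
        if timestep_map is None:
            timestep_map = np.arange(1, beta.size + 1)
        timestep_map = np.asarray(timestep_map, dtype=np.int64)
        if timestep_map.shape != beta.shape:
            raise InvalidArgumentError("timestep_map must have one entry per beta")
        self.timestep_map = timestep_map

    @property
    def T(self) -> int:
        return int(self.beta.size)

    # -- 1-based accessors -------------------------------------------------
    def check_t(self, t: int, low: int = 1) -> int:
        t = int(t)
        if not low <= t <= self.T:
            raise TimestepRangeError(
                f"timestep {t} outside [{low}, {self.T}]"
            )
        return t

    def beta_at(self, t) -> float:
        return float(self.beta[self.check_t(t) - 1])

    def alpha_at(self, t) -> float:
        return float(self.alpha[self.check_t(t) - 1])

    def alpha_bar_at(self, t) -> float:
        """``alpha_bar_t``; accepts t = 0 and returns 1 there."""
        t = self.check_t(t, low=0)
        return 1.0 if t == 0 else float(self.alpha_bar[t - 1])

    def posterior_variance_at(self, t) -> float:
        return float(self.posterior_variance[self.check_t(t) - 1])

    def model_t(self, t):
        """Map a (possibly respaced) timestep to the trained model's timestep."""
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise TimestepRangeError(f"timestep {t} outside [1, {self.T}]")
        mapped = self.timestep_map[t - 1]
        return int(mapped) if mapped.ndim == 0 else mapped


def build_cosine_schedule(T: int) -> NoiseSchedule:
    """Cosine schedule: ``alpha_bar_t = f(t)/f(0)`` with
    ``f(t) = cos^2(((t/T + s)/(1 + s)) * pi/2)``, ``s = 0.008``; betas clipped
    at :data:`BETA_MAX`.
    """
    T = int(T)
    if T < 1:
        raise InvalidArgumentError(f"T must be a positive integer, got {T}")
    steps = np.arange(T + 1, dtype=np.float64)
    f = np.cos(((steps / T + COSINE_S) / (1.0 + COSINE_S)) * np.pi / 2.0) ** 2
    alpha_bar = f / f[0]
    beta = 1.0 - alpha_bar[1:] / alpha_bar[:-1]
    beta = np.clip(beta, 1e-12, BETA_MAX)
    return NoiseSchedule(beta)


def respace_schedule(schedule: NoiseSchedule, n_steps: int) -> NoiseSchedule:
    """Evenly spaced sub-schedule with recomputed betas for fast sampling.

    Keeps ``n_steps`` of the original timesteps (always including the last)
    and recomputes betas so the cumulative products match the originals at
    the kept steps.  The returned schedule carries a ``timestep_map`` back to
    the original timesteps for the predictor's time embedding.
    """
    n_steps = int(n_steps)
    if not 1 <= n_steps <= schedule.T:
        raise InvalidArgumentError(
            f"n_steps must be in [1, {schedule.T}], got {n_steps}"
        )
    idx = np.unique(np.round(np.linspace(0, schedule.T - 1, n_steps)).astype(int))
    kept_bar = schedule.alpha_bar[idx]
    prev = np.concatenate(([1.0], kept_bar[:-1]))
    # no BETA_MAX clip here: the recomputed betas must reproduce the kept
    # cumulative products exactly (they stay inside (0, 1) by construction)
    beta = 1.0 - kept_bar / prev
    return NoiseSchedule(beta, timestep_map=idx + 1)
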