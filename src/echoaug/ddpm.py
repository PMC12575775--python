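"""Improved denoising diffusion probabilistic model on dense grids.

Everything runs on float64 numpy arrays.  Latents live in [-1, 1]; images in
[0, 1] are converted at module boundaries.  The predictor is a small
fully-connected encoder-decoder with an input skip connection and an explicit
backward pass, which is sufficient for the scaled-down grids this package
trains on (2-pixel toys up to small phantom crops).

The reverse process predicts the forward noise ``eps`` and a variance
interpolation coefficient ``v`` in [0, 1]; the per-pixel reverse variance is
``exp(v * log beta_t + (1 - v) * log beta_tilde_t)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import (
    ContractError,
    InvalidArgumentError,
)
from .schedule import NoiseSchedule, build_cosine_schedule

__all__ = [
    "TrainingConfig",
    "MLPPredictor",
    "LossAwareSampler",
    "q_sample",
    "posterior_params",
    "predict_x0_from_eps",
    "interpolated_logvar",
    "p_sample_step",
    "hybrid_loss",
    "importance_sample_timestep",
    "train",
    "generate",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# forward process and closed-form posterior
# ---------------------------------------------------------------------------

def q_sample(x0, t, eps, schedule: NoiseSchedule):
    """Draw from q(x_t | x_0): ``sqrt(abar_t) x0 + sqrt(1 - abar_t) eps``.

    ``t`` may be a scalar (applied to the whole grid) or a 1-D array pairing
    one timestep with each leading-axis sample of ``x0``.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise InvalidArgumentError("x0 and eps must share a shape")
    if np.ndim(t) == 0:
        ab = schedule.alpha_bar_at(schedule.check_t(t))
    else:
        t = np.asarray(t, dtype=np.int64)
        if np.any(t < 1) or np.any(t > schedule.T):
            schedule.check_t(int(t.min()) if t.min() < 1 else int(t.max()))
        ab = schedule.alpha_bar[t - 1].reshape((-1,) + (1,) * (x0.ndim - 1))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def posterior_params(x0, x_t, t, schedule: NoiseSchedule):
    """Mean and variance of the closed-form posterior q(x_{t-1} | x_t, x_0).

    mean = sqrt(abar_{t-1}) beta_t / (1 - abar_t) * x0
         + sqrt(alpha_t) (1 - abar_{t-1}) / (1 - abar_t) * x_t
    variance = beta_tilde_t (zero at t = 1 since abar_0 = 1).
    """
    x0 = np.asarray(x0, dtype=np.float64)
    x_t = np.asarray(x_t, dtype=np.float64)
    if x0.shape != x_t.shape:
        raise InvalidArgumentError("x0 and x_t must share a shape")
    t = schedule.check_t(t)
    ab = schedule.alpha_bar_at(t)
    ab_prev = schedule.alpha_bar_at(t - 1)
    beta = schedule.beta_at(t)
    alpha = schedule.alpha_at(t)
    coef0 = math.sqrt(ab_prev) * beta / (1.0 - ab)
    coeft = math.sqrt(alpha) * (1.0 - ab_prev) / (1.0 - ab)
    mean = coef0 * x0 + coeft * x_t
    return mean, schedule.posterior_variance_at(t)


def predict_x0_from_eps(x_t, t, eps_hat, schedule: NoiseSchedule, clamp=True):
    """Invert the forward marginal: ``(x_t - sqrt(1-abar_t) eps) / sqrt(abar_t)``."""
    x_t = np.asarray(x_t, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if x_t.shape != eps_hat.shape:
        raise InvalidArgumentError("x_t and eps_hat must share a shape")
    ab = schedule.alpha_bar_at(t)
    x0 = (x_t - math.sqrt(1.0 - ab) * eps_hat) / math.sqrt(ab)
    if clamp:
        x0 = np.clip(x0, -1.0, 1.0)
    return x0


def interpolated_logvar(v_hat, t, schedule: NoiseSchedule):
    """log variance = v * log(beta_t) + (1 - v) * log(beta_tilde_t)."""
    t = schedule.check_t(t, low=2)  # beta_tilde_1 == 0, no defined interpolation
    v = np.asarray(v_hat, dtype=np.float64)
    log_beta = math.log(schedule.beta_at(t))
    log_tilde = math.log(schedule.posterior_variance_at(t))
    return v * log_beta + (1.0 - v) * log_tilde


def p_sample_step(predictor, x_t, t, schedule: NoiseSchedule, rng):
    """One learned reverse step x_t -> x_{t-1}; at t = 1 returns the mean."""
    x_t = np.asarray(x_t, dtype=np.float64)
    t = schedule.check_t(t)
    eps_hat, v_hat = predictor(x_t, schedule.model_t(t))
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    v_hat = np.asarray(v_hat, dtype=np.float64)
    if eps_hat.shape != x_t.shape or v_hat.shape != x_t.shape:
        raise ContractError(
            "predictor outputs must match the latent shape: "
            f"{eps_hat.shape}/{v_hat.shape} vs {x_t.shape}"
        )
    x0_hat = predict_x0_from_eps(x_t, t, eps_hat, schedule)
    mean, _ = posterior_params(x0_hat, x_t, t, schedule)
    if t == 1:
        return mean
    logvar = interpolated_logvar(v_hat, t, schedule)
    return mean + np.exp(0.5 * logvar) * rng.standard_normal(x_t.shape)


def gaussian_kl(mean1, logvar1, mean2, logvar2):
    """KL( N(mean1, e^logvar1) || N(mean2, e^logvar2) ), elementwise."""
    return 0.5 * (
        logvar2
        - logvar1
        + (np.exp(logvar1) + (mean1 - mean2) ** 2) / np.exp(logvar2)
        - 1.0
    )


# ---------------------------------------------------------------------------
# predictor
# ---------------------------------------------------------------------------

def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class MLPPredictor:
    """Fully-connected denoiser with a sinusoidal time embedding.

    Maps a flattened latent plus time embedding through ``hidden`` tanh layers
    to ``2 * D`` outputs: the first ``D`` are the predicted noise ``eps_hat``
    (with an additive skip from the input latent scaled by a learned-free
    constant of 0 — the raw head), the last ``D`` pass through a sigmoid to
    give the variance-interpolation field ``v_hat`` in [0, 1].

    Deterministic for fixed parameters and inputs.
    """

    def __init__(self, data_shape, hidden=(128, 128), time_embed_dim=16, seed=0):
        self.data_shape = tuple(int(s) for s in data_shape)
        self.hidden = tuple(int(h) for h in hidden)
        self.time_embed_dim = int(time_embed_dim)
        if self.time_embed_dim % 2 != 0:
            raise InvalidArgumentError("time_embed_dim must be even")
        self.D = int(np.prod(self.data_shape))
        dims = [self.D + self.time_embed_dim, *self.hidden, 2 * self.D]
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            scale = math.sqrt(1.0 / din)
            if i == len(dims) - 2:
                scale *= 0.1  # start close to eps_hat = 0, v_hat = 0.5
            self.weights.append(rng.normal(0.0, scale, size=(din, dout)))
            self.biases.append(np.zeros(dout))
        self.trained_T = None
        self.training_log = []
        self.holdout_losses = None

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_params(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.weights, self.biases)))

    def describe(self) -> str:
        return (
            f"MLPPredictor(data_shape={self.data_shape}, hidden={self.hidden}, "
            f"time_embed_dim={self.time_embed_dim}, n_params={self.n_params})"
        )

    def parameters(self):
        return self.weights + self.biases

    # -- forward/backward --------------------------------------------------
    def _time_embedding(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        half = self.time_embed_dim // 2
        freqs = np.exp(-math.log(10000.0) * np.arange(half) / half)
        ang = t[:, None] * freqs[None, :]
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)

    def _as_batch(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.shape == self.data_shape:
            return x.reshape(1, self.D), True
        if x.shape[1:] == self.data_shape:
            return x.reshape(x.shape[0], self.D), False
        raise ContractError(
            f"latent shape {x.shape} incompatible with data shape {self.data_shape}"
        )

    def _forward(self, xb, t):
        """xb: (B, D); t scalar or (B,). Returns (eps, v, cache)."""
        B = xb.shape[0]
        temb = self._time_embedding(t)
        if temb.shape[0] == 1 and B > 1:
            temb = np.repeat(temb, B, axis=0)
        h = np.concatenate([xb, temb], axis=1)
        acts = [h]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ W + b)
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        eps = out[:, : self.D]
        vraw = out[:, self.D :]
        v = _sigmoid(vraw)
        return eps, v, (acts, v)

    def __call__(self, x, t):
        xb, squeeze = self._as_batch(x)
        eps, v, _ = self._forward(xb, t)
        shape = self.data_shape if squeeze else (xb.shape[0],) + self.data_shape
        return eps.reshape(shape), v.reshape(shape)

    def _backward(self, cache, g_eps, g_v):
        """Gradients of a scalar loss wrt parameters given output gradients.

        g_eps, g_v: (B, D) gradients wrt eps_hat and v_hat (post-sigmoid).
        """
        acts, v = cache
        g_out = np.concatenate([g_eps, g_v * v * (1.0 - v)], axis=1)
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        g = g_out
        for i in range(len(self.weights) - 1, -1, -1):
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            if i > 0:
                g = (g @ self.weights[i].T) * (1.0 - acts[i] ** 2)
        return gW + gb

    # -- serialization -----------------------------------------------------
    def state_arrays(self):
        arrs = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrs[f"W{i}"] = w
            arrs[f"b{i}"] = b
        return arrs

    def load_state_arrays(self, arrs):
        for i in range(len(self.weights)):
            self.weights[i] = np.asarray(arrs[f"W{i}"], dtype=np.float64)
            self.biases[i] = np.asarray(arrs[f"b{i}"], dtype=np.float64)


# ---------------------------------------------------------------------------
# hybrid loss
# ---------------------------------------------------------------------------

def _hybrid_terms(predictor, x0, t, eps, schedule, weights=None):
    """Shared forward pass for the hybrid loss.

    Returns the scalar MSE and VLB terms plus the output gradients needed for
    training.  The mean is detached in the KL term: gradients flow only to the
    variance head (and to the noise head via the MSE term).
    """
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    t = np.atleast_1d(np.asarray(t, dtype=np.int64))
    data_shape = getattr(predictor, "data_shape", None)
    if data_shape is not None and x0.shape == tuple(data_shape):
        x0 = x0[None]
        eps = eps[None]
    B = x0.shape[0]
    if B == 0:
        raise InvalidArgumentError("empty batch")
    if t.size == 1 and B > 1:
        t = np.full(B, int(t[0]))
    if np.any(t < 1) or np.any(t > schedule.T):
        raise InvalidArgumentError("timesteps outside [1, T]")
    if weights is None:
        weights = np.ones(B)
    weights = np.asarray(weights, dtype=np.float64)

    D = int(np.prod(x0.shape[1:]))
    x0b = x0.reshape(B, D)
    epsb = eps.reshape(B, D)
    ab = schedule.alpha_bar[t - 1][:, None]
    ab_prev = schedule.alpha_bar_prev[t - 1][:, None]
    beta = schedule.beta[t - 1][:, None]
    alpha = schedule.alpha[t - 1][:, None]
    tilde = schedule.posterior_variance[t - 1][:, None]
    xtb = np.sqrt(ab) * x0b + np.sqrt(1.0 - ab) * epsb

    if hasattr(predictor, "_forward"):
        eps_hat, v_hat, cache = predictor._forward(xtb, schedule.model_t(t))
    else:  # generic callable contract (e.g. stub predictors in tests)
        eps_hat, v_hat = predictor(xtb.reshape(x0.shape), schedule.model_t(t))
        eps_hat = np.asarray(eps_hat, dtype=np.float64).reshape(B, D)
        v_hat = np.asarray(v_hat, dtype=np.float64).reshape(B, D)
        cache = None

    # MSE on the noise
    w = weights[:, None]
    mse_per = ((eps_hat - epsb) ** 2).mean(axis=1)
    mse = float((weights * mse_per).mean())
    g_eps = 2.0 * w * (eps_hat - epsb) / (D * B)

    # VLB term, mean detached
    x0_hat = np.clip((xtb - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab), -1.0, 1.0)
    coef0 = np.sqrt(ab_prev) * beta / (1.0 - ab)
    coeft = np.sqrt(alpha) * (1.0 - ab_prev) / (1.0 - ab)
    mean_q = coef0 * x0b + coeft * xtb
    mean_p = coef0 * x0_hat + coeft * xtb

    g_v = np.zeros_like(v_hat)
    vlb_per = np.zeros(B)
    at1 = t == 1
    gt1 = ~at1
    if np.any(gt1):
        log_beta = np.log(beta[gt1])
        log_tilde = np.log(tilde[gt1])
        logvar_p = v_hat[gt1] * log_beta + (1.0 - v_hat[gt1]) * log_tilde
        kl = gaussian_kl(mean_q[gt1], log_tilde, mean_p[gt1], logvar_p)
        vlb_per[gt1] = kl.mean(axis=1)
        dkl_dlogvar = 0.5 * (
            1.0
            - (np.exp(log_tilde) + (mean_q[gt1] - mean_p[gt1]) ** 2)
            / np.exp(logvar_p)
        )
        g_v[gt1] = dkl_dlogvar * (log_beta - log_tilde)
    if np.any(at1):
        # terminal step: Gaussian posterior has zero variance; score the mean
        # against the data with the beta_1 scale (value only, no gradient)
        vlb_per[at1] = ((mean_p[at1] - x0b[at1]) ** 2).mean(axis=1) / (
            2.0 * beta[at1][:, 0]
        )
    vlb = float((weights * vlb_per).mean())
    g_v *= w / (D * B)

    per_sample = mse_per + vlb_per
    return mse, vlb, g_eps, g_v, cache, per_sample, t


def hybrid_loss(predictor, x0, t, eps, schedule, vlb_weight=0.001):
    """MSE on the predicted noise plus ``vlb_weight`` times the per-step KL
    between the closed-form posterior and the predicted reverse Gaussian.
    """
    if vlb_weight < 0:
        raise InvalidArgumentError("vlb_weight must be non-negative")
    mse, vlb, *_ = _hybrid_terms(predictor, x0, t, eps, schedule)
    return mse + vlb_weight * vlb


# ---------------------------------------------------------------------------
# importance-sampled timesteps
# ---------------------------------------------------------------------------

class LossAwareSampler:
    """Timestep sampler weighted by recent per-timestep losses.

    Until every timestep has ``history`` recorded losses the sampler is
    uniform; afterwards timestep ``t`` is drawn with probability proportional
    to the square root of the running mean of its recorded losses (so a
    timestep whose loss is 100x larger is visited 10x as often), and the
    returned importance weight is the inverse of ``T * p_t``.
    """

    def __init__(self, T: int, history: int = 10):
        self.T = int(T)
        self.history = int(history)
        self._losses = np.zeros((self.T, self.history))
        self._counts = np.zeros(self.T, dtype=np.int64)

    @property
    def warmed_up(self) -> bool:
        return bool(np.all(self._counts >= self.history))

    def update(self, t, loss):
        i = int(t) - 1
        self._losses[i, self._counts[i] % self.history] = float(loss)
        self._counts[i] += 1

    def probabilities(self):
        if not self.warmed_up:
            return np.full(self.T, 1.0 / self.T)
        w = np.sqrt(np.maximum(self._losses.mean(axis=1), 0.0))
        w = np.maximum(w, 1e-12)
        return w / w.sum()

    def sample(self, rng, size=None):
        p = self.probabilities()
        idx = rng.choice(self.T, size=size, p=p)
        t = idx + 1
        weight = 1.0 / (self.T * p[idx])
        return t, weight


def importance_sample_timestep(sampler: LossAwareSampler, rng):
    """Draw one timestep (and its importance weight) from the sampler."""
    t, w = sampler.sample(rng)
    return int(t), float(w)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    T: int = 1000
    image_size: int = 64
    batch_size: int = 64
    learning_rate: float = 1e-3
    n_steps: int = 2000
    vlb_weight: float = 0.001
    importance_history: int = 10
    seed: int = 0
    frame_stride_range: tuple = (8, 12)
    hidden: tuple = (128, 128)
    time_embed_dim: int = 16
    ema_decay: float = 0.999  # exponential moving average of the weights
    lr_final_fraction: float = 0.1  # linear decay of the learning rate

    def __post_init__(self):
        lo, hi = self.frame_stride_range
        if lo < 1 or lo > hi:
            raise InvalidArgumentError(
                f"frame_stride_range must satisfy 1 <= low <= high, got {(lo, hi)}"
            )
        if self.T < 1:
            raise InvalidArgumentError("T must be positive")


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _holdout_loss(predictor, data, schedule, vlb_weight, seed=1234):
    rng = np.random.default_rng(seed)
    t = rng.integers(1, schedule.T + 1, size=data.shape[0])
    eps = rng.standard_normal(data.shape)
    mse, vlb, *_ = _hybrid_terms(predictor, data, t, eps, schedule)
    return mse + vlb_weight * vlb


def train(dataset, config: TrainingConfig, rng=None):
    """Train an :class:`MLPPredictor` on latent grids in [-1, 1].

    Returns the predictor with ``schedule``, ``training_log`` (list of
    ``(step, loss, vlb)``) and ``holdout_losses`` (initial, final) attached.
    """
    try:
        data = np.asarray(dataset, dtype=np.float64)
    except ValueError as exc:  # ragged
        raise InvalidArgumentError("all samples must share a shape") from exc
    if data.ndim < 2 or data.shape[0] == 0:
        raise InvalidArgumentError("dataset must be a non-empty array of grids")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    schedule = build_cosine_schedule(config.T)
    predictor = MLPPredictor(
        data.shape[1:],
        hidden=config.hidden,
        time_embed_dim=config.time_embed_dim,
        seed=config.seed,
    )
    predictor.trained_T = config.T

    n_hold = max(1, data.shape[0] // 10)
    holdout, trainset = data[:n_hold], data[n_hold:]
    if trainset.shape[0] == 0:
        trainset = data
    loss0 = _holdout_loss(predictor, holdout, schedule, config.vlb_weight)

    sampler = LossAwareSampler(config.T, history=config.importance_history)
    opt = _Adam(predictor.parameters(), config.learning_rate)
    ema = [p.copy() for p in predictor.parameters()]
    log = []
    for step in range(config.n_steps):
        idx = rng.integers(0, trainset.shape[0], size=config.batch_size)
        x0 = trainset[idx]
        t, w = sampler.sample(rng, size=config.batch_size)
        eps = rng.standard_normal(x0.shape)
        mse, vlb, g_eps, g_v, cache, per_sample, t = _hybrid_terms(
            predictor, x0, t, eps, schedule, weights=w
        )
        grads = predictor._backward(cache, g_eps, g_v * config.vlb_weight)
        frac = step / max(1, config.n_steps - 1)
        opt.lr = config.learning_rate * (1.0 - (1.0 - config.lr_final_fraction) * frac)
        opt.step(predictor.parameters(), grads)
        d = min(config.ema_decay, (step + 1) / (step + 10))
        for e, p in zip(ema, predictor.parameters()):
            e *= d
            e += (1.0 - d) * p
        for ti, li in zip(t, per_sample):
            sampler.update(ti, li)
        log.append((step, mse + config.vlb_weight * vlb, vlb))
    for p, e in zip(predictor.parameters(), ema):
        p[...] = e

    loss1 = _holdout_loss(predictor, holdout, schedule, config.vlb_weight)
    predictor.schedule = schedule
    predictor.training_log = log
    predictor.holdout_losses = (loss0, loss1)
    return predictor


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(predictor, schedule: NoiseSchedule, count: int, seed: int):
    """Run the full reverse chain from unit-normal noise.

    Returns ``count`` latents clamped to [-1, 1]; bit-reproducible for a
    fixed seed.
    """
    count = int(count)
    if count < 0:
        raise InvalidArgumentError("count must be non-negative")
    shape = (count,) + predictor.data_shape
    if count == 0:
        return np.zeros(shape)
    if predictor.trained_T is not None and schedule.timestep_map[-1] > predictor.trained_T:
        raise ContractError("schedule timesteps exceed the predictor's trained T")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape)
    for t in range(schedule.T, 0, -1):
        x = p_sample_step(predictor, x, t, schedule, rng)
    return np.clip(x, -1.0, 1.0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path, predictor, schedule=None, config: TrainingConfig | None = None):
    """Single-archive checkpoint: parameters + schedule + config, versioned."""
    if schedule is None:
        schedule = getattr(predictor, "schedule", None)
    if schedule is None:
        raise InvalidArgumentError("no schedule supplied or attached to predictor")
    meta = {
        "version": CHECKPOINT_VERSION,
        "data_shape": list(predictor.data_shape),
        "hidden": list(predictor.hidden),
        "time_embed_dim": predictor.time_embed_dim,
        "trained_T": predictor.trained_T,
        "config": asdict(config) if config is not None else None,
    }
    arrs = predictor.state_arrays()
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        beta=schedule.beta,
        timestep_map=schedule.timestep_map,
        **arrs,
    )


def load_checkpoint(path):
    """Load a checkpoint; returns ``(predictor, schedule, config_dict)``.

    Reloaded predictors produce bit-identical outputs on identical inputs.
    """
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise InvalidArgumentError(
                f"unsupported checkpoint version {meta['version']}"
            )
        schedule = NoiseSchedule(z["beta"], timestep_map=z["timestep_map"])
        predictor = MLPPredictor(
            meta["data_shape"],
            hidden=tuple(meta["hidden"]),
            time_embed_dim=meta["time_embed_dim"],
        )
        predictor.load_state_arrays(z)
    predictor.trained_T = meta["trained_T"]
    predictor.schedule = schedule
    cfg = meta.get("config")
    if cfg is not None:
        cfg["frame_stride_range"] = tuple(cfg["frame_stride_range"])
        cfg["hidden"] = tuple(cfg["hidden"])
    return predictor, schedule, cfg
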