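"""Forward process, posterior, reverse step and loss — against independent
closed-form and Monte-Carlo oracles."""

import numpy as np
import pytest

from echoaug import ddpm
from echoaug.errors import (
    ContractError,
    InvalidArgumentError,
    TimestepRangeError,
)
from echoaug.schedule import build_cosine_schedule


@pytest.fixture(scope="module")
def sched():
    return build_cosine_schedule(50)


# ---------------------------------------------------------------------------
# q_sample
# ---------------------------------------------------------------------------

def test_q_sample_zero_noise_scales_exactly(sched):
    x0 = np.linspace(-1, 1, 12).reshape(3, 4)
    for t in (1, 25, 50):
        out = ddpm.q_sample(x0, t, np.zeros_like(x0), sched)
        assert np.allclose(out, np.sqrt(sched.alpha_bar_at(t)) * x0)


def test_q_sample_terminal_step_is_nearly_pure_noise():
    sched = build_cosine_schedule(1000)
    rng = np.random.default_rng(0)
    x0 = rng.uniform(-1, 1, size=(8, 8))
    eps = rng.standard_normal((8, 8))
    out = ddpm.q_sample(x0, 1000, eps, sched)
    assert np.linalg.norm(out - eps) / np.linalg.norm(eps) < 0.05


def test_q_sample_monte_carlo_moments(sched):
    # scalar x0 = 0.5 at a mid-schedule timestep: empirical mean/variance of
    # the output must match the closed form within 3 standard errors
    t = 25
    n = 100_000
    rng = np.random.default_rng(123)
    eps = rng.standard_normal(n)
    out = ddpm.q_sample(np.full(n, 0.5), t, eps, sched)
    ab = sched.alpha_bar_at(t)
    se_mean = np.sqrt(1 - ab) / np.sqrt(n)
    assert abs(out.mean() - np.sqrt(ab) * 0.5) < 3 * se_mean
    se_var = (1 - ab) * np.sqrt(2.0 / (n - 1))
    assert abs(out.var(ddof=1) - (1 - ab)) < 3 * se_var


def test_q_sample_range_and_shape_errors(sched):
    x0 = np.zeros(4)
    with pytest.raises(TimestepRangeError):
        ddpm.q_sample(x0, 0, np.zeros(4), sched)
    with pytest.raises(TimestepRangeError):
        ddpm.q_sample(x0, 51, np.zeros(4), sched)
    with pytest.raises(InvalidArgumentError):
        ddpm.q_sample(x0, 1, np.zeros(5), sched)


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------

def test_posterior_terminates_at_data(sched):
    x0 = np.array([0.3, -0.7])
    x1 = np.array([0.1, 0.2])
    mean, var = ddpm.posterior_params(x0, x1, 1, sched)
    assert np.allclose(mean, x0)
    assert var == 0.0


def test_posterior_matches_gaussian_product_oracle(sched):
    # independent derivation: q(x_{t-1}|x_t, x0) is the normalized product of
    # the Gaussians q(x_t|x_{t-1}) (as a function of x_{t-1}) and q(x_{t-1}|x0)
    rng = np.random.default_rng(7)
    x0 = rng.uniform(-1, 1, size=(3, 3))
    xt = rng.uniform(-1, 1, size=(3, 3))
    for t in (2, 13, 50):
        alpha, beta = sched.alpha_at(t), sched.beta_at(t)
        ab_prev = sched.alpha_bar_at(t - 1)
        prec = alpha / beta + 1.0 / (1.0 - ab_prev)
        var_oracle = 1.0 / prec
        mean_oracle = var_oracle * (
            np.sqrt(alpha) / beta * xt + np.sqrt(ab_prev) / (1.0 - ab_prev) * x0
        )
        mean, var = ddpm.posterior_params(x0, xt, t, sched)
        assert np.isclose(var, var_oracle, rtol=1e-12)
        assert np.allclose(mean, mean_oracle, rtol=1e-12)


def test_posterior_collapses_on_noiseless_trajectory(sched):
    # x_t from the zero-noise forward path keeps the posterior mean on the
    # zero-noise path of the previous step
    x0 = np.array([[0.4, -0.2], [0.9, 0.0]])
    for t in (2, 20, 50):
        xt = ddpm.q_sample(x0, t, np.zeros_like(x0), sched)
        mean, _ = ddpm.posterior_params(x0, xt, t, sched)
        expected = np.sqrt(sched.alpha_bar_at(t - 1)) * x0
        assert np.allclose(mean, expected, atol=1e-12)


def test_posterior_rejects_t_zero(sched):
    with pytest.raises(TimestepRangeError):
        ddpm.posterior_params(np.zeros(2), np.zeros(2), 0, sched)


# ---------------------------------------------------------------------------
# predict_x0_from_eps
# ---------------------------------------------------------------------------

def test_predict_x0_inverts_q_sample(sched):
    rng = np.random.default_rng(3)
    x0 = rng.uniform(-0.9, 0.9, size=(5, 5))
    eps = rng.standard_normal((5, 5))
    for t in (1, 30, 50):
        xt = ddpm.q_sample(x0, t, eps, sched)
        rec = ddpm.predict_x0_from_eps(xt, t, eps, sched, clamp=False)
        assert np.allclose(rec, x0, atol=1e-9)


def test_predict_x0_zero_inputs(sched):
    out = ddpm.predict_x0_from_eps(np.zeros((2, 2)), 10, np.zeros((2, 2)), sched)
    assert np.array_equal(out, np.zeros((2, 2)))


def test_predict_x0_oracle_and_clamp(sched):
    t = 10
    ab = sched.alpha_bar_at(t)
    xt = np.array([0.5])
    eps_hat = np.array([-2.0])
    raw = (xt - np.sqrt(1 - ab) * eps_hat) / np.sqrt(ab)
    assert np.allclose(
        ddpm.predict_x0_from_eps(xt, t, eps_hat, sched, clamp=False), raw
    )
    assert ddpm.predict_x0_from_eps(xt, t, eps_hat, sched)[0] == np.clip(raw, -1, 1)[0]


# ---------------------------------------------------------------------------
# reverse step
# ---------------------------------------------------------------------------

def test_variance_interpolation_endpoints(sched):
    for t in (2, 25, 50):
        lv1 = ddpm.interpolated_logvar(np.ones(3), t, sched)
        assert np.allclose(np.exp(lv1), sched.beta_at(t))
        lv0 = ddpm.interpolated_logvar(np.zeros(3), t, sched)
        assert np.allclose(np.exp(lv0), sched.posterior_variance_at(t))


class _ConstStub:
    """Predictor returning fixed eps and v grids."""

    def __init__(self, eps_value, v_value, shape=(2,)):
        self.data_shape = shape
        self.eps_value = eps_value
        self.v_value = v_value

    def __call__(self, x, t):
        return (
            np.full_like(x, self.eps_value),
            np.full_like(x, self.v_value),
        )


def test_p_sample_step_matches_hand_computation(sched):
    stub = _ConstStub(eps_value=0.2, v_value=0.3)
    t = 20
    x_t = np.array([0.1, -0.4])
    rng = np.random.default_rng(42)
    out = ddpm.p_sample_step(stub, x_t, t, sched, rng)
    # replicate by hand with the same recorded normal draw
    eps_hat = np.full(2, 0.2)
    x0_hat = np.clip(
        (x_t - np.sqrt(1 - sched.alpha_bar_at(t)) * eps_hat)
        / np.sqrt(sched.alpha_bar_at(t)),
        -1,
        1,
    )
    mean, _ = ddpm.posterior_params(x0_hat, x_t, t, sched)
    logvar = 0.3 * np.log(sched.beta_at(t)) + 0.7 * np.log(
        sched.posterior_variance_at(t)
    )
    draw = np.random.default_rng(42).standard_normal(2)
    assert np.allclose(out, mean + np.exp(0.5 * logvar) * draw)


def test_p_sample_step_adds_no_noise_at_t1(sched):
    stub = _ConstStub(0.0, 0.5)
    x_t = np.array([0.3, 0.3])
    out1 = ddpm.p_sample_step(stub, x_t, 1, sched, np.random.default_rng(0))
    out2 = ddpm.p_sample_step(stub, x_t, 1, sched, np.random.default_rng(999))
    assert np.array_equal(out1, out2)


class _BadShapeStub:
    data_shape = (2,)

    def __call__(self, x, t):
        return np.zeros(3), np.zeros(3)


def test_p_sample_step_contract_error(sched):
    with pytest.raises(ContractError):
        ddpm.p_sample_step(_BadShapeStub(), np.zeros(2), 5, sched, np.random.default_rng(0))


def test_forward_posterior_marginal_consistency(sched):
    # marginalizing q(x_{t-1} | x_t, x0) over x_t ~ q(x_t | x0) must
    # reproduce q(x_{t-1} | x0): checked by Monte-Carlo moments on scalars
    t = 30
    x0 = np.full(100_000, 0.37)
    rng = np.random.default_rng(5)
    xt = ddpm.q_sample(x0, t, rng.standard_normal(x0.shape), sched)
    mean, var = ddpm.posterior_params(x0, xt, t, sched)
    draws = mean + np.sqrt(var) * rng.standard_normal(x0.shape)
    ab_prev = sched.alpha_bar_at(t - 1)
    n = x0.size
    se_mean = np.sqrt(1 - ab_prev) / np.sqrt(n)
    assert abs(draws.mean() - np.sqrt(ab_prev) * 0.37) < 3 * se_mean
    se_var = (1 - ab_prev) * np.sqrt(2.0 / (n - 1))
    assert abs(draws.var(ddof=1) - (1 - ab_prev)) < 3 * se_var


# ---------------------------------------------------------------------------
# hybrid loss
# ---------------------------------------------------------------------------

class _OracleStub:
    """Returns the true eps (closed over) and v = 0 (posterior variance)."""

    def __init__(self, eps):
        self.eps = eps

    def __call__(self, x, t):
        return self.eps.reshape(x.shape), np.zeros_like(x)


def test_hybrid_loss_zero_for_perfect_prediction(sched):
    rng = np.random.default_rng(11)
    x0 = rng.uniform(-0.5, 0.5, size=(6, 4))
    eps = rng.standard_normal((6, 4))
    t = np.array([5, 17, 28, 33, 41, 50])
    loss = ddpm.hybrid_loss(_OracleStub(eps), x0, t, eps, sched, vlb_weight=0.5)
    assert loss == pytest.approx(0.0, abs=1e-12)


def test_hybrid_loss_reduces_to_mse_without_vlb(sched):
    rng = np.random.default_rng(2)
    x0 = rng.uniform(-0.5, 0.5, size=(4, 3))
    eps = rng.standard_normal((4, 3))
    stub = _ConstStub(0.25, 0.9, shape=(3,))
    t = np.array([3, 9, 20, 44])
    loss = ddpm.hybrid_loss(stub, x0, t, eps, sched, vlb_weight=0.0)
    # plain MSE oracle
    assert loss == pytest.approx(np.mean((eps - 0.25) ** 2), rel=1e-12)


def test_gaussian_kl_closed_form():
    # KL(N(1, 4) || N(0, 9)) computed by hand
    m1, v1, m2, v2 = 1.0, 4.0, 0.0, 9.0
    expected = 0.5 * (np.log(v2 / v1) + (v1 + (m1 - m2) ** 2) / v2 - 1)
    got = ddpm.gaussian_kl(m1, np.log(v1), m2, np.log(v2))
    assert got == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.5 * (np.log(9 / 4) + 5 / 9 - 1))


def test_hybrid_loss_nonnegative_and_empty_batch_error(sched):
    rng = np.random.default_rng(8)
    x0 = rng.uniform(-1, 1, size=(5, 2))
    eps = rng.standard_normal((5, 2))
    stub = _ConstStub(0.0, 0.5)
    loss = ddpm.hybrid_loss(stub, x0, np.array([2, 7, 19, 33, 50]), eps, sched, 0.01)
    assert loss >= 0
    with pytest.raises(InvalidArgumentError):
        ddpm.hybrid_loss(stub, np.zeros((0, 2)), np.array([]), np.zeros((0, 2)), sched)
    with pytest.raises(InvalidArgumentError):
        ddpm.hybrid_loss(stub, x0, np.array([2] * 5), eps, sched, vlb_weight=-1)


# ---------------------------------------------------------------------------
# importance sampling
# ---------------------------------------------------------------------------

def test_importance_sampler_uniform_during_warmup():
    s = ddpm.LossAwareSampler(10, history=10)
    for t in range(1, 10):  # timestep 10 never updated -> warm-up persists
        for _ in range(10):
            s.update(t, 1.0)
    assert not s.warmed_up
    assert np.allclose(s.probabilities(), 0.1)


def test_importance_sampler_uniform_for_equal_losses():
    s = ddpm.LossAwareSampler(5, history=10)
    for t in range(1, 6):
        for _ in range(10):
            s.update(t, 2.0)
    rng = np.random.default_rng(0)
    ts, _ = s.sample(rng, size=100_000)
    freq = np.bincount(ts, minlength=6)[1:] / 100_000
    assert np.all(np.abs(freq - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 100_000))


def test_importance_sampler_square_root_law():
    # one timestep with a 100x larger loss is drawn ~10x as often
    s = ddpm.LossAwareSampler(11, history=10)
    for t in range(1, 12):
        for _ in range(10):
            s.update(t, 100.0 if t == 1 else 1.0)
    p = s.probabilities()
    assert p[0] / p[1] == pytest.approx(10.0, rel=1e-9)
    rng = np.random.default_rng(1)
    ts, w = s.sample(rng, size=100_000)
    f1 = np.mean(ts == 1)
    f2 = np.mean(ts == 2)
    assert f1 / f2 == pytest.approx(10.0, rel=0.15)
    # importance weights invert the sampling probabilities
    assert np.allclose(w, 1.0 / (11 * p[ts - 1]))


def test_importance_sample_timestep_wrapper():
    s = ddpm.LossAwareSampler(4, history=2)
    t, w = ddpm.importance_sample_timestep(s, np.random.default_rng(0))
    assert 1 <= t <= 4
    assert w == pytest.approx(1.0)
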