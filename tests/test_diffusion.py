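"""Noise schedules, forward/reverse kernels, EMA, diffusion training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scldm as m
from scldm.diffusion import DEFAULT_BETA_MAX, DEFAULT_BETA_MIN


# ---------------------------------------------------------------- schedules
def test_linear_schedule_endpoints_at_canonical_range():
    s = m.build_schedule("linear", 1000, 1e-5, 0.5e-2)
    assert s.betas[0] == pytest.approx(1e-5, rel=1e-12)
    assert s.betas[-1] == pytest.approx(0.005, rel=1e-12)


@pytest.mark.parametrize("kind", ["linear", "quadratic", "sigmoid"])
def test_single_step_schedule(kind):
    s = m.build_schedule(kind, 1, 0.01, 0.3)
    np.testing.assert_allclose(s.betas, [0.01])
    assert s.alpha_bars[0] == pytest.approx(0.99)


def test_alpha_bar_matches_brute_force_product():
    s = m.build_schedule("linear", 1000, 1e-5, 0.5e-2)
    prod = 1.0
    for b in s.betas:
        prod *= 1.0 - b
    assert s.alpha_bars[-1] == pytest.approx(prod, abs=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(kind=st.sampled_from(["linear", "quadratic", "sigmoid"]),
       T=st.integers(min_value=2, max_value=400),
       bmin=st.floats(min_value=1e-6, max_value=1e-3),
       spread=st.floats(min_value=1.0, max_value=200.0))
def test_schedule_invariants_randomised(kind, T, bmin, spread):
    bmax = min(bmin * spread, 0.999)
    s = m.build_schedule(kind, T, bmin, bmax)
    assert (s.betas >= bmin - 1e-15).all() and (s.betas <= bmax + 1e-15).all()
    np.testing.assert_array_equal(s.alphas, 1.0 - s.betas)
    assert (np.diff(s.alpha_bars) < 0).all()          # strictly decreasing
    assert s.alpha_bars[-1] < s.alpha_bars[0]


def test_schedule_domain_errors():
    with pytest.raises(ValueError):
        m.build_schedule("linear", 10, 0.0, 0.1)
    with pytest.raises(ValueError):
        m.build_schedule("linear", 10, 0.1, 1.0)
    with pytest.raises(ValueError):
        m.build_schedule("cosine", 10, 1e-5, 1e-2)


# ----------------------------------------------------------- forward kernel
def test_q_sample_zero_noise_scales_by_sqrt_alpha_bar():
    s = m.build_schedule("linear", 100)
    z0 = np.arange(4.0)
    out = m.q_sample(z0, 37, np.zeros(4), s)
    np.testing.assert_allclose(out, np.sqrt(s.alpha_bar(37)) * z0, atol=1e-15)


def test_q_sample_large_t_is_mostly_noise():
    s = m.build_schedule("linear", 1000)
    z0 = np.ones(8) / np.sqrt(8.0)
    eps = np.random.default_rng(0).standard_normal(8)
    out = m.q_sample(z0, 1000, eps, s)
    bound = np.sqrt(s.alpha_bar(1000)) * np.linalg.norm(z0) \
        + abs(np.sqrt(1 - s.alpha_bar(1000)) - 1.0) * np.linalg.norm(eps)
    assert np.linalg.norm(out - eps) <= bound + 1e-12


def test_q_sample_t_out_of_range():
    s = m.build_schedule("linear", 10)
    with pytest.raises(IndexError):
        m.q_sample(np.zeros(2), 11, np.zeros(2), s)
    with pytest.raises(ValueError, match="shape"):
        m.q_sample(np.zeros(2), 5, np.zeros(3), s)


def test_closed_form_matches_composed_one_step_kernels():
    # composing t one-step kernels must agree with q(z_t | z_0):
    # mean exactly (algebraic identity), variance within Monte-Carlo error
    s = m.build_schedule("linear", 64, 1e-4, 0.05)
    t = 64
    assert np.prod(np.sqrt(s.alphas[:t])) == pytest.approx(
        np.sqrt(s.alpha_bar(t)), abs=1e-14)
    rng = np.random.default_rng(0)
    n = 100_000
    z0 = 1.3
    z = np.full(n, z0)
    for step in range(1, t + 1):
        z = m.q_step(z, step, rng.standard_normal(n), s)
    true_var = 1.0 - s.alpha_bar(t)
    se_mean = np.sqrt(true_var / n)
    se_var = true_var * np.sqrt(2.0 / (n - 1))
    assert abs(z.mean() - np.sqrt(s.alpha_bar(t)) * z0) < 3 * se_mean
    assert abs(z.var() - true_var) < 3 * se_var


def test_terminal_kl_closed_form_small_for_default_schedule():
    # nats per dimension: the chain is approximately standard Gaussian at T
    s = m.build_schedule("linear", 1000, DEFAULT_BETA_MIN, DEFAULT_BETA_MAX)
    z0 = np.ones(16) / 4.0  # unit norm
    kl = m.terminal_kl(s, z0)
    assert kl["per_dim"] < 1e-2
    assert kl["total"] == pytest.approx(
        0.5 * (16 * ((1 - kl["alpha_bar_T"]) - 1 - np.log(1 - kl["alpha_bar_T"]))
               + kl["alpha_bar_T"]), rel=1e-12)


# ----------------------------------------------------------------------- EMA
def test_ema_trivial_and_closed_form():
    assert m.ema_update(np.zeros(3), np.ones(3), 0.0) == pytest.approx(np.ones(3))
    assert m.ema_update(np.array([0.0]), np.array([1.0]), 0.999)[0] == pytest.approx(0.001)
    with pytest.raises(ValueError):
        m.ema_update(np.zeros(2), np.zeros(2), 1.0)
    with pytest.raises(ValueError):
        m.ema_update(np.zeros(2), np.zeros(3), 0.5)


def test_ema_geometric_convergence():
    decay, k, c, s0 = 0.999, 500, 1.0, 0.0
    s = np.array([s0])
    for _ in range(k):
        s = m.ema_update(s, np.array([c]), decay)
    expected = c + (s0 - c) * decay**k
    assert abs(s[0] - expected) < 1e-10


# ------------------------------------------------------------ reverse kernel
def _tiny_ddm(T=10, d=2, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((64, d))
    sched = m.build_schedule("linear", T, 1e-3, 0.05)
    return m.LatentDiffusion(Z, sched, hidden=(8,), seed=seed).fit(epochs=1)


def test_p_sample_final_step_is_noise_free():
    res = _tiny_ddm()
    z = np.ones((3, 2))
    a = res.p_sample_step(z, 1, noise=np.full((3, 2), 9.0))
    b = res.p_sample_step(z, 1, noise=np.full((3, 2), -9.0))
    np.testing.assert_array_equal(a, b)


def test_p_sample_with_zero_eps_net_rescales():
    res = _tiny_ddm()
    for k in res.ema_params:
        res.ema_params[k] = np.zeros_like(res.ema_params[k])
    z = np.array([[1.0, -2.0]])
    out = res.p_sample_step(z, 5, noise=np.zeros((1, 2)))
    np.testing.assert_allclose(out, z / np.sqrt(res.schedule.alpha(5)), atol=1e-14)


def test_p_sample_matches_symbolic_expansion_for_T3_scalar():
    # with a perfect noise oracle and J = 0, the update must equal the
    # symbolic expression (1/sqrt(a_t)) (z_t - (1-a_t)/sqrt(1-ab_t) * eps)
    import sympy as sp

    sched = m.build_schedule("linear", 3, 0.01, 0.2)
    res = _tiny_ddm(T=3, d=1)
    res.model.schedule = sched
    res.schedule = sched
    z0v, epsv = 0.8, -0.45

    b = sp.symbols("b1 b2 b3")
    z0s, es = sp.symbols("z0 eps")
    alphas = [1 - bi for bi in b]
    ab = [alphas[0], alphas[0] * alphas[1], alphas[0] * alphas[1] * alphas[2]]
    subs = {b[i]: sched.betas[i] for i in range(3)} | {z0s: z0v, es: epsv}

    for t in (3, 2, 1):
        zts = sp.sqrt(ab[t - 1]) * z0s + sp.sqrt(1 - ab[t - 1]) * es
        sym = (zts - (1 - alphas[t - 1]) / sp.sqrt(1 - ab[t - 1]) * es) \
            / sp.sqrt(alphas[t - 1])
        expected = float(sym.subs(subs))
        res.predict_eps = lambda z, tt, use_ema=True: np.full_like(z, epsv)
        z_t = m.q_sample(np.array([[z0v]]), t, np.array([[epsv]]), sched)
        out = res.p_sample_step(z_t, t, noise=np.zeros((1, 1)))
        assert out[0, 0] == pytest.approx(expected, abs=1e-12)


# -------------------------------------------------------------------- training
def test_zero_epochs_leaves_ema_equal_to_init():
    rng = np.random.default_rng(1)
    Z = rng.standard_normal((32, 3))
    res = m.LatentDiffusion(Z, m.build_schedule("linear", 10), seed=2).fit(epochs=0)
    for k in res.params:
        np.testing.assert_array_equal(res.params[k], res.ema_params[k])


def test_training_beats_untrained_network(cluster_models):
    ddm = cluster_models["ddm"]
    Z = cluster_models["vae"].encode(cluster_models["pp"])
    untrained = m.LatentDiffusion(Z, ddm.schedule, hidden=(128, 128), seed=0).fit(epochs=0)
    assert ddm.loss_on(Z, seed=0) < untrained.loss_on(Z, seed=0)
    h = ddm.history["loss"]
    assert h.iloc[-1] < h.iloc[0]


def test_loss_approaches_bayes_floor_on_1d_gaussian(gauss1d_ddm):
    # optimal eps-prediction loss for standard-normal z0, estimated by the
    # conditional-mean (linear regression) oracle per timestep
    sched, ddm = gauss1d_ddm["sched"], gauss1d_ddm["ddm"]
    rng = np.random.default_rng(42)
    floors = []
    for t in range(1, sched.T + 1):
        ab = sched.alpha_bar(t)
        z0 = rng.standard_normal(40_000)
        eps = rng.standard_normal(40_000)
        zt = np.sqrt(ab) * z0 + np.sqrt(1 - ab) * eps
        c = (eps @ zt) / (zt @ zt)           # brute-force conditional mean slope
        floors.append(np.mean((eps - c * zt) ** 2))
    floor = float(np.mean(floors))
    mc = np.mean([ddm.loss_on(np.random.default_rng(100 + i).standard_normal((30_000, 1)),
                              seed=200 + i) for i in range(4)])
    assert mc < 1.10 * floor
    assert mc > 0.95 * floor  # cannot meaningfully beat the floor


def test_fit_deterministic_under_seed():
    rng = np.random.default_rng(3)
    Z = rng.standard_normal((64, 2))
    r1 = m.LatentDiffusion(Z, m.build_schedule("linear", 20), seed=9).fit(epochs=3)
    r2 = m.LatentDiffusion(Z, m.build_schedule("linear", 20), seed=9).fit(epochs=3)
    assert abs(r1.history["loss"].iloc[-1] - r2.history["loss"].iloc[-1]) < 1e-6


# ------------------------------------------------------------------ sampling
def test_generate_empty_and_deterministic(cluster_models):
    ddm = cluster_models["ddm"]
    assert ddm.generate(0).shape == (0, ddm.d_latent)
    a = ddm.generate(5, seed=7)
    b = ddm.generate(5, seed=7)
    np.testing.assert_array_equal(a, b)
    assert (ddm.generate(5, seed=8) != a).any()


def test_generated_moments_match_training_latents(cluster_models):
    ddm, vae, pp = (cluster_models[k] for k in ("ddm", "vae", "pp"))
    Z = vae.encode(pp)
    G = ddm.generate(2000, seed=3)
    # reference tolerance: moment error between two independent halves of Z
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(Z))
    half = len(Z) // 2
    from scldm.metrics import moment_diagnostics
    ref = moment_diagnostics(Z[idx[:half]], Z[idx[half:]])
    got = moment_diagnostics(Z, G)
    assert got["mean_error"] < 5 * ref["mean_error"] + 0.3
    assert got["cov_frobenius_error"] < 5 * ref["cov_frobenius_error"] + 0.5


def test_save_load_round_trip(tmp_path):
    res = _tiny_ddm()
    p = tmp_path / "ddm.npz"
    res.save(p)
    back = m.DiffusionResults.load(p)
    z = np.random.default_rng(0).standard_normal((4, 2))
    np.testing.assert_allclose(back.predict_eps(z, 3), res.predict_eps(z, 3), atol=1e-12)
    np.testing.assert_array_equal(back.schedule.betas, res.schedule.betas)
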