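"""Interpolation paths: endpoint identity, granularity, similarity profiles."""

import numpy as np
import pytest

import scldm as m
from scldm.interpolate import InterpolationPath


def monotone_violation_fraction(values, direction, rel_tol=1e-3):
    """Fraction of steps moving against ``direction`` by more than
    ``rel_tol`` of the profile's total range (micro-wiggles don't count)."""
    v = np.asarray(values, dtype=float)
    rng = v.max() - v.min()
    d = np.diff(v) * (1 if direction == "up" else -1)
    return float(np.mean(d < -rel_tol * max(rng, 1e-12)))


def test_endpoint_identity_under_shared_noise(trajectory_models):
    tm = trajectory_models
    path = m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                                t_mix=20, n_steps=11, seed=0)
    # under shared noise, lambda = 0 equals the single-endpoint pipeline
    single = m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xa"],
                                  t_mix=20, n_steps=11, seed=0)
    np.testing.assert_allclose(path.expressions[0], single.expressions[0], atol=1e-10)
    np.testing.assert_allclose(path.expressions[0], single.expressions[-1], atol=1e-10)


def test_t_mix_zero_degenerates_to_vae_interpolation(trajectory_models):
    tm = trajectory_models
    vae = tm["vae"]
    path = m.interpolate_qspace(vae, tm["ddm"], tm["xa"], tm["xb"],
                                t_mix=0, n_steps=7, seed=0)
    z1, z2 = vae.encode(tm["xa"][None, :]), vae.encode(tm["xb"][None, :])
    lam = path.lambdas[:, None]
    np.testing.assert_allclose(path.expressions,
                               vae.decode((1 - lam) * z1 + lam * z2), atol=1e-10)


def test_zspace_t_noise_zero_equals_plain_vae_path(trajectory_models):
    tm = trajectory_models
    a = m.interpolate_zspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                             t_noise=0, n_steps=7, seed=0)
    b = m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                             t_mix=0, n_steps=7, seed=0)
    np.testing.assert_allclose(a.expressions, b.expressions, atol=1e-12)


def test_zspace_endpoint_identity(trajectory_models):
    tm = trajectory_models
    path = m.interpolate_zspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                                t_noise=15, n_steps=9, seed=0)
    single = m.interpolate_zspace(tm["vae"], tm["ddm"], tm["xb"], tm["xb"],
                                  t_noise=15, n_steps=9, seed=0)
    np.testing.assert_allclose(path.expressions[-1], single.expressions[-1], atol=1e-10)


def test_qspace_pipeline_reconstructs_bit_exactly(trajectory_models):
    # rebuilding the q-space grid from the endpoints with the recorded seed
    # and denoising it reproduces the stored path latents bit for bit
    tm = trajectory_models
    vae, ddm, sched = tm["vae"], tm["ddm"], tm["ddm"].schedule
    path = m.interpolate_qspace(vae, ddm, tm["xa"], tm["xb"],
                                t_mix=20, n_steps=11, seed=5)
    z1, z2 = vae.encode(tm["xa"][None, :]), vae.encode(tm["xb"][None, :])
    rng = np.random.default_rng(np.random.SeedSequence((5, 101)))
    eps = rng.standard_normal(z1.shape)
    q1 = m.q_sample(z1, 20, eps, sched)
    q2 = m.q_sample(z2, 20, eps, sched)
    lam = path.lambdas[:, None]
    q_grid = (1 - lam) * q1 + lam * q2
    z_path = ddm.denoise_from(q_grid, 20, noise_record=ddm.make_noise_record(20, rng))
    np.testing.assert_array_equal(z_path, path.latents)


def test_similarity_profile_monotone_trend(trajectory_models):
    tm = trajectory_models
    path = m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                                t_mix=20, n_steps=400, seed=0)
    prof = m.similarity_profile(path, tm["xa"], tm["xb"])
    assert prof["corr_a"].iloc[0] > prof["corr_b"].iloc[0]
    assert prof["corr_b"].iloc[-1] > prof["corr_a"].iloc[-1]
    assert monotone_violation_fraction(prof["corr_a"], "down") <= 0.05
    assert monotone_violation_fraction(prof["corr_b"], "up") <= 0.05


def test_similarity_profile_trivial_cases():
    ref_a = np.array([1.0, 2.0, 3.0, 0.5])
    ref_b = np.array([3.0, 0.1, 0.2, 4.0])
    path = InterpolationPath(lambdas=np.linspace(0, 1, 3), t_mix=0, method="qspace",
                             latents=np.zeros((3, 1)),
                             expressions=np.tile(ref_a, (3, 1)))
    prof = m.similarity_profile(path, ref_a, ref_b)
    np.testing.assert_allclose(prof["corr_a"], 1.0, atol=1e-12)
    # joint per-gene affine rescaling leaves Pearson r unchanged
    scale, shift = 2.5, -1.0
    path2 = InterpolationPath(lambdas=path.lambdas, t_mix=0, method="qspace",
                              latents=path.latents,
                              expressions=path.expressions * scale + shift)
    prof2 = m.similarity_profile(path2, ref_a * scale + shift, ref_b * scale + shift)
    np.testing.assert_allclose(prof2["corr_a"], prof["corr_a"], atol=1e-12)


def test_similarity_profile_zero_variance_errors():
    path = InterpolationPath(lambdas=np.linspace(0, 1, 2), t_mix=0, method="qspace",
                             latents=np.zeros((2, 1)),
                             expressions=np.array([[1.0, 1.0], [1.0, 2.0]]))
    with pytest.raises(ValueError, match="step 0"):
        m.similarity_profile(path, np.array([1.0, 2.0]), np.array([2.0, 1.0]))


def test_path_stays_on_data_manifold(trajectory_models):
    tm = trajectory_models
    path = m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                                t_mix=20, n_steps=400, seed=0)
    sup = m.support_distances(path, tm["Z"])
    assert sup["frac_within"] == 1.0


def test_coarser_mixing_gives_more_varied_paths(trajectory_models):
    tm = trajectory_models
    T = tm["ddm"].schedule.T

    def seed_variance(t_mix):
        paths = [m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                                      t_mix=t_mix, n_steps=30, seed=s).expressions
                 for s in range(5)]
        return float(np.stack(paths).var(axis=0).mean())

    assert seed_variance(T) >= seed_variance(T // 10)


def test_n_steps_and_t_mix_validation(trajectory_models):
    tm = trajectory_models
    with pytest.raises(ValueError):
        m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                             t_mix=10, n_steps=1, seed=0)
    with pytest.raises(IndexError):
        m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                             t_mix=10_000, n_steps=5, seed=0)


def test_path_to_anndata_carries_annotations(trajectory_models):
    tm = trajectory_models
    path = m.interpolate_qspace(tm["vae"], tm["ddm"], tm["xa"], tm["xb"],
                                t_mix=20, n_steps=5, seed=0)
    adata = path.to_anndata()
    assert adata.shape == (5, len(tm["xa"]))
    np.testing.assert_allclose(adata.obs["lambda"], path.lambdas)
    assert (adata.obs["t_mix"] == 20).all()
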