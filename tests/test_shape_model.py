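"""Point-distribution model: PCA building, sampling, likelihoods, kernel
augmentation and Gaussian-process posterior regression, each checked against
dense linear-algebra oracles on small meshes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapedent.errors import CorrespondenceError
from shapedent.shape_model import (
    PointDistributionModel,
    ShapeCoefficients,
    augment_with_gaussian_kernel,
    build_pca_model,
    coefficients_of,
    instance,
    load_model,
    log_likelihood,
    mahalanobis,
    posterior_regression,
    sample,
    save_model,
    vertex_marginal,
    vertex_marginals,
)
from conftest import make_displaced_cohort, make_grid_mesh, make_quad_mesh

# ---------------------------------------------------------------------------
# dense oracles
# ---------------------------------------------------------------------------

def dense_sample_covariance(meshes):
    data = np.stack([m.vertices.reshape(-1) for m in meshes])
    mean = data.mean(0)
    centered = data - mean
    return mean, centered.T @ centered / (len(meshes) - 1)


def model_covariance(model: PointDistributionModel) -> np.ndarray:
    return model.components @ model.components.T


def dense_gaussian_conditioning(mean, cov, obs_rows, y, noise):
    """Joint-Gaussian conditioning by Schur complement on the dense covariance."""
    h = np.zeros((len(obs_rows), len(mean)))
    for r, c in enumerate(obs_rows):
        h[r, c] = 1.0
    s = h @ cov @ h.T + noise * np.eye(len(obs_rows))
    gain = cov @ h.T @ np.linalg.inv(s)
    post_mean = mean + gain @ (y - h @ mean)
    post_cov = cov - gain @ h @ cov
    return post_mean, post_cov


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------

def test_pca_matches_dense_covariance_eigendecomposition():
    cohort = make_displaced_cohort(make_quad_mesh(), 5, scale=0.2)
    model = build_pca_model(cohort)
    mean, cov = dense_sample_covariance(cohort)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    np.testing.assert_allclose(model.mean, mean, atol=1e-12)
    assert model.rank == 4
    np.testing.assert_allclose(
        model.eigenvalues, evals[: model.rank], rtol=1e-8
    )
    for i in range(model.rank):
        pc = model.components[:, i] / np.sqrt(model.eigenvalues[i])
        assert abs(abs(pc @ evecs[:, i]) - 1.0) < 1e-8


def test_pca_rank_bounded_by_n_minus_one():
    cohort = make_displaced_cohort(make_quad_mesh(), 9, scale=0.2)
    model = build_pca_model(cohort)
    assert model.rank <= 8


def test_pca_reproduces_training_meshes():
    cohort = make_displaced_cohort(make_quad_mesh(), 5, scale=0.2)
    model = build_pca_model(cohort)
    for m in cohort:
        rec = instance(model, coefficients_of(model, m))
        assert np.abs(rec.vertices - m.vertices).max() < 1e-6


def test_pca_rejects_degenerate_input(quad_mesh):
    with pytest.raises(ValueError, match="at least 2"):
        build_pca_model([quad_mesh])
    with pytest.raises(ValueError, match="no variation"):
        build_pca_model([quad_mesh, quad_mesh.copy()])
    other = make_grid_mesh(3, 3)
    with pytest.raises(CorrespondenceError):
        build_pca_model([quad_mesh, other])


# ---------------------------------------------------------------------------
# instance / coefficients
# ---------------------------------------------------------------------------

def test_instance_zero_is_exactly_the_mean(toy_model):
    mesh = instance(toy_model, ShapeCoefficients(np.zeros(toy_model.rank)))
    np.testing.assert_array_equal(mesh.vertices.reshape(-1), toy_model.mean)


def test_instance_unit_first_coefficient(toy_model):
    alpha = np.zeros(toy_model.rank)
    alpha[0] = 1.0
    mesh = instance(toy_model, ShapeCoefficients(alpha))
    np.testing.assert_array_equal(
        mesh.vertices.reshape(-1), toy_model.mean + toy_model.components[:, 0]
    )


def test_projection_round_trip_in_span(toy_model):
    alpha = ShapeCoefficients(np.array([1.3, -0.7, 0.2, 2.0]))
    mesh = instance(toy_model, alpha)
    back = coefficients_of(toy_model, mesh)
    assert np.abs(back.alpha - alpha.alpha).max() < 1e-9
    again = instance(toy_model, back)
    assert np.abs(again.vertices - mesh.vertices).max() < 1e-9


def test_projection_off_span_matches_pseudo_inverse(toy_model):
    rng = np.random.default_rng(5)
    mesh = instance(toy_model, ShapeCoefficients(rng.standard_normal(toy_model.rank)))
    noisy = mesh.with_vertices(mesh.vertices + rng.normal(0, 0.05, mesh.vertices.shape))
    alpha = coefficients_of(toy_model, noisy).alpha
    resid = noisy.vertices.reshape(-1) - toy_model.mean
    expected = np.linalg.pinv(toy_model.components) @ resid
    assert np.abs(alpha - expected).max() < 1e-8


def test_coefficient_length_checked(toy_model):
    with pytest.raises(ValueError):
        instance(toy_model, ShapeCoefficients(np.zeros(toy_model.rank + 1)))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_sampling_is_deterministic_per_seed(toy_model):
    m1, c1 = sample(toy_model, 42)
    m2, c2 = sample(toy_model, 42)
    np.testing.assert_array_equal(m1.vertices, m2.vertices)
    np.testing.assert_array_equal(c1.alpha, c2.alpha)
    m3, _ = sample(toy_model, 43)
    assert np.abs(m1.vertices - m3.vertices).max() > 0


def test_sampling_moments_standard_normal(toy_model):
    n = 10_000
    draws = np.array([sample(toy_model, 1000 + i)[1].alpha[0] for i in range(n)])
    assert abs(draws.mean()) < 4 / np.sqrt(n)
    assert abs(draws.var() - 1.0) < 0.06


def test_empirical_vertex_covariance_converges_to_model():
    base = make_quad_mesh()
    model = build_pca_model(make_displaced_cohort(base, 4, scale=0.3))
    n = 20_000
    rng = np.random.default_rng(7)
    alphas = rng.standard_normal((n, model.rank))
    fields = alphas @ model.components.T  # (n, 3N) zero-mean deviations
    emp = fields.T @ fields / n
    cov = model_covariance(model)
    # Monte-Carlo error bound for each covariance entry from the eigenvalues:
    # var(emp_ij) = (cov_ii * cov_jj + cov_ij^2) / n
    sd = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / n)
    assert np.all(np.abs(emp - cov) < 6 * sd + 1e-12)


# ---------------------------------------------------------------------------
# likelihood and Mahalanobis distance
# ---------------------------------------------------------------------------

def test_log_likelihood_at_origin_rank_one(quad_mesh):
    model = PointDistributionModel(
        quad_mesh,
        quad_mesh.vertices.reshape(-1),
        np.eye(12)[:, :1],
        np.array([1.0]),
    )
    assert log_likelihood(model, ShapeCoefficients([0.0])) == pytest.approx(
        -0.9189385, abs=1e-6
    )


def test_log_likelihood_closed_form_rank_two(quad_mesh):
    comps = np.zeros((12, 2))
    comps[0, 0] = comps[1, 1] = 1.0
    model = PointDistributionModel(
        quad_mesh, quad_mesh.vertices.reshape(-1), comps, np.array([1.0, 1.0])
    )
    assert log_likelihood(model, ShapeCoefficients([1.0, 1.0])) == pytest.approx(
        -(np.log(2 * np.pi) + 1.0), abs=1e-12
    )


def test_mahalanobis_is_coefficient_norm(toy_model):
    assert mahalanobis(toy_model, ShapeCoefficients(np.zeros(4))) == 0.0
    assert mahalanobis(toy_model, ShapeCoefficients([3.0, 4.0, 0.0, 0.0])) == pytest.approx(5.0)


def test_mahalanobis_matches_pseudo_inverse_quadratic_form(toy_model):
    alpha = ShapeCoefficients([0.5, -1.2, 0.8, 0.3])
    s = instance(toy_model, alpha).vertices.reshape(-1)
    diff = s - toy_model.mean
    d2 = diff @ np.linalg.pinv(model_covariance(toy_model)) @ diff
    assert abs(np.sqrt(d2) - mahalanobis(toy_model, alpha)) < 1e-8


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-5, 5), min_size=4, max_size=4))
def test_mahalanobis_likelihood_identity(alpha):
    """mahal^2 + 2 log-likelihood + r log(2 pi) = 0 for every coefficient vector."""
    model = build_pca_model(make_displaced_cohort(make_quad_mesh(), 5))
    c = ShapeCoefficients(alpha)
    lhs = mahalanobis(model, c) ** 2 + 2 * log_likelihood(model, c) + model.rank * np.log(2 * np.pi)
    assert abs(lhs) < 1e-9


def test_likelihood_decreases_with_norm(toy_model):
    lls = [
        log_likelihood(toy_model, ShapeCoefficients([r, 0, 0, 0])) for r in (0.0, 0.5, 1.5, 3.0)
    ]
    assert all(a > b for a, b in zip(lls, lls[1:]))


# ---------------------------------------------------------------------------
# vertex marginals
# ---------------------------------------------------------------------------

def test_vertex_marginal_rank_one_outer_product(quad_mesh):
    comps = np.arange(12.0).reshape(12, 1) + 1.0
    lam = float((comps**2).sum())
    model = PointDistributionModel(
        quad_mesh, quad_mesh.vertices.reshape(-1), comps, np.array([lam])
    )
    _, cov = vertex_marginal(model, 2)
    rows = comps[6:9, 0]
    np.testing.assert_allclose(cov, np.outer(rows, rows))


def test_vertex_marginal_trace_identity(toy_model):
    total = sum(
        np.trace(vertex_marginal(toy_model, i)[1]) for i in range(toy_model.n_vertices)
    )
    np.testing.assert_allclose(total, toy_model.eigenvalues.sum(), rtol=1e-8)


def test_vertex_marginals_positive_semidefinite(toy_model):
    covs = vertex_marginals(toy_model)
    for c in covs:
        assert np.linalg.eigvalsh(c).min() > -1e-10


# ---------------------------------------------------------------------------
# kernel augmentation
# ---------------------------------------------------------------------------

def _toy_10_vertex_model(seed=11):
    base = make_grid_mesh(5, 2, spacing=2.0)  # 10 vertices
    return build_pca_model(make_displaced_cohort(base, 4, scale=0.2, seed=seed))


def test_augmentation_full_rank_equals_dense_kernel_sum():
    model = _toy_10_vertex_model()
    s2, bw = 2.0, 3.0
    aug = augment_with_gaussian_kernel(model, s2, bw, extra_rank=30)  # all 3N terms
    pts = model.mean.reshape(-1, 3)
    d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
    kmat = s2 * np.exp(-d2 / bw**2)
    dense = np.kron(kmat, np.eye(3))
    # interleave: cov entry between (vertex i, axis a) and (vertex j, axis b)
    expected = model_covariance(model) + dense
    got = model_covariance(aug)
    err = np.linalg.norm(got - expected) / np.linalg.norm(expected)
    assert err < 1e-6


def test_augmentation_bandwidth_zero_limit_gives_nugget():
    # with a negligible parent, the combined spectrum exposes the kernel's:
    # far below the vertex spacing the kernel matrix is s^2 * identity and
    # every kept direction carries eigenvalue s^2
    base = make_grid_mesh(5, 2, spacing=2.0)
    parent = build_pca_model(make_displaced_cohort(base, 4, scale=1e-6))
    aug = augment_with_gaussian_kernel(parent, 4.0, 1e-4, extra_rank=3)
    np.testing.assert_allclose(aug.eigenvalues[:3], 4.0, rtol=1e-6)


def test_augmentation_adds_requested_rank():
    model = _toy_10_vertex_model()
    aug = augment_with_gaussian_kernel(model, 2.0, 3.0, extra_rank=5)
    assert aug.rank == model.rank + 5


def test_augmentation_never_reduces_marginal_variance():
    model = _toy_10_vertex_model()
    aug = augment_with_gaussian_kernel(model, 2.0, 3.0, extra_rank=6)
    for i in range(model.n_vertices):
        before = np.diag(vertex_marginal(model, i)[1])
        after = np.diag(vertex_marginal(aug, i)[1])
        assert np.all(after >= before - 1e-9)


def test_augmentation_validates_parameters(toy_model):
    with pytest.raises(ValueError):
        augment_with_gaussian_kernel(toy_model, -1.0, 2.0, 3)
    with pytest.raises(ValueError):
        augment_with_gaussian_kernel(toy_model, 1.0, 2.0, 0)


# ---------------------------------------------------------------------------
# posterior regression
# ---------------------------------------------------------------------------

def test_posterior_at_mean_observations_is_mean(toy_model):
    obs = [(0, toy_model.mean[0:3]), (3, toy_model.mean[9:12])]
    post = posterior_regression(toy_model, obs, noise_variance=0.7)
    assert np.abs(post.map_coefficients.alpha).max() < 1e-12
    np.testing.assert_allclose(post.model.mean, toy_model.mean, atol=1e-9)


def test_posterior_interpolates_with_tiny_noise(toy_model):
    target = instance(toy_model, ShapeCoefficients([1.0, -0.5, 0.3, 0.2]))
    post = posterior_regression(toy_model, [(1, target.vertices[1])], noise_variance=1e-12)
    assert np.abs(post.model.mean[3:6] - target.vertices[1]).max() < 1e-5


def test_posterior_matches_dense_gaussian_conditioning(toy_model):
    rng = np.random.default_rng(13)
    y = np.concatenate([rng.uniform(-1, 1, 3) + toy_model.mean[0:3],
                        rng.uniform(-1, 1, 3) + toy_model.mean[6:9]])
    noise = 0.5
    post = posterior_regression(
        toy_model, [(0, y[:3]), (2, y[3:])], noise_variance=noise
    )
    obs_rows = [0, 1, 2, 6, 7, 8]
    exp_mean, exp_cov = dense_gaussian_conditioning(
        toy_model.mean, model_covariance(toy_model), obs_rows, y, noise
    )
    np.testing.assert_allclose(post.model.mean, exp_mean, atol=1e-8)
    np.testing.assert_allclose(model_covariance(post.model), exp_cov, atol=1e-8)


def test_posterior_variance_never_exceeds_parent(toy_model):
    post = posterior_regression(toy_model, [(1, np.array([5.0, 5.0, 5.0]))], 0.3)
    for i in range(toy_model.n_vertices):
        parent = np.diag(vertex_marginal(toy_model, i)[1])
        cond = np.diag(vertex_marginal(post.model, i)[1])
        assert np.all(cond <= parent + 1e-9)


def test_posterior_infinite_noise_returns_parent(toy_model):
    post = posterior_regression(toy_model, [(0, np.zeros(3))], noise_variance=1e12)
    assert np.abs(post.map_coefficients.alpha).max() < 1e-6
    np.testing.assert_allclose(post.model.mean, toy_model.mean, atol=1e-6)
    np.testing.assert_allclose(
        model_covariance(post.model), model_covariance(toy_model), atol=1e-6
    )


def test_posterior_validates_input(toy_model):
    with pytest.raises(ValueError):
        posterior_regression(toy_model, [], 1.0)
    with pytest.raises(ValueError):
        posterior_regression(toy_model, [(99, np.zeros(3))], 1.0)
    with pytest.raises(ValueError):
        posterior_regression(toy_model, [(0, np.zeros(3))], 0.0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_model_archive_round_trip_bit_exact(toy_model, tmp_path):
    p = tmp_path / "model.zip"
    save_model(toy_model, p)
    back = load_model(p)
    np.testing.assert_array_equal(back.mean, toy_model.mean)
    np.testing.assert_array_equal(back.components, toy_model.components)
    np.testing.assert_array_equal(back.eigenvalues, toy_model.eigenvalues)
    np.testing.assert_array_equal(back.reference.vertices, toy_model.reference.vertices)
    np.testing.assert_array_equal(back.reference.triangles, toy_model.reference.triangles)
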