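"""Simultaneous robust shape reconstruction and healthy/unhealthy labelling.

A corrupted target (e.g. a mandible with missing teeth) violates the
correspondence assumption of plain model fitting: some model vertices have
no counterpart on the target. The strategy here fits the model only to
regions believed healthy, starting from a handful of user-supplied
landmarks, and lets the healthy set grow outward along the mesh adjacency:

1. estimate the rigid pose from landmarks and condition the model on them
   (Gaussian-process posterior regression);
2. mark frontier vertices (unhealthy vertices 1-ring adjacent to a healthy
   one) healthy when the target surface near their predicted position is
   within a Mahalanobis threshold of the model's per-vertex marginal;
3. re-condition the model on closest-point correspondences of all healthy
   vertices, refine the pose, and repeat until no vertex is added.

Vertices never reached by the growth are labelled unhealthy; over a missing
tooth the model keeps predicting the full tooth while the target offers
only the gum below it, the discrepancy stays above threshold, and the whole
tooth region remains unhealthy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .mesh_core import (
    LandmarkSet,
    RigidTransform,
    SurfaceProximity,
    TriangleMesh,
    procrustes_align,
    vertex_adjacency,
)
from .shape_model import (
    PointDistributionModel,
    PosteriorModel,
    ShapeCoefficients,
    posterior_regression,
    vertex_marginals,
)

__all__ = [
    "LabelMap",
    "FitConfig",
    "FitResult",
    "reconstruction_loss",
    "initialize_from_landmarks",
    "grow_healthy_regions",
    "region_growing_fit",
]

HEALTHY = 1
UNHEALTHY = 0


@dataclass
class LabelMap:
    """Per-reference-vertex binary label: 1 = healthy, 0 = unhealthy."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8).reshape(-1)
        if not np.all((self.labels == 0) | (self.labels == 1)):
            raise ValueError("labels must be binary")

    @property
    def n_healthy(self) -> int:
        return int(self.labels.sum())

    def healthy_vertices(self) -> np.ndarray:
        return np.nonzero(self.labels == HEALTHY)[0]

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy())


@dataclass
class FitConfig:
    """Knobs of the robust fit.

    noise_variance: isotropic observation noise sigma^2 (mm^2) used both in
        the posterior regression on healthy correspondences and in the
        growth criterion.
    mahalanobis_threshold: tau; a frontier vertex becomes healthy when the
        Mahalanobis distance of (closest target point - predicted position)
        under (marginal covariance + sigma^2 I) is <= tau. The default 3.0
        admits ~99.7% of a 3-DOF Gaussian.
    landmark_noise_variance: sigma^2 (mm^2) for the landmark observations
        used at initialisation.
    max_outer_iterations: hard cap on grow/refit rounds; growth is monotone
        so the loop always terminates, the cap only guards cost.
    """

    noise_variance: float = 1.0
    mahalanobis_threshold: float = 3.0
    landmark_noise_variance: float = 1.0
    max_outer_iterations: int = 200

    def __post_init__(self) -> None:
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")
        if self.mahalanobis_threshold <= 0:
            raise ValueError("mahalanobis_threshold must be positive")
        if self.landmark_noise_variance <= 0:
            raise ValueError("landmark_noise_variance must be positive")
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be >= 1")


@dataclass
class FitResult:
    reconstruction: TriangleMesh  # posterior mean in target pose
    coefficients: ShapeCoefficients  # MAP coefficients under the parent model
    pose: RigidTransform  # maps model frame to target frame
    label_map: LabelMap
    residuals: np.ndarray  # per-vertex distance to closest target point (mm)
    trace: list[int] = field(default_factory=list)  # healthy count per iteration
    converged: bool = True


def reconstruction_loss(
    model_instance: TriangleMesh,
    target: TriangleMesh,
    correspondences: list[tuple[int, np.ndarray]],
) -> float:
    """Average Euclidean distance between named model vertices and their
    corresponding target points."""
    if len(correspondences) == 0:
        raise ValueError("correspondence list is empty")
    idx = np.array([int(i) for i, _ in correspondences], dtype=np.int64)
    pts = np.array([np.asarray(p, float).reshape(3) for _, p in correspondences])
    if idx.min() < 0 or idx.max() >= model_instance.n_vertices:
        raise ValueError("correspondence vertex index out of range")
    d = np.linalg.norm(model_instance.vertices[idx] - pts, axis=1)
    return float(d.mean())


def _match_landmarks(
    model_landmarks: LandmarkSet, target_landmarks: LandmarkSet
) -> list[str]:
    names = model_landmarks.names
    if sorted(names) != sorted(target_landmarks.names):
        raise ValueError(
            "landmark names do not match one-to-one between model and target sets"
        )
    if len(names) < 3:
        raise ValueError("at least 3 landmarks are required")
    return names


def initialize_from_landmarks(
    model: PointDistributionModel,
    model_landmarks: LandmarkSet,
    target_landmarks: LandmarkSet,
    config: FitConfig | None = None,
) -> tuple[RigidTransform, PosteriorModel, np.ndarray]:
    """Landmark-seeded initialisation of the robust fit.

    The pose is the rigid Procrustes alignment of the mean-shape landmark
    positions onto the target landmarks; the model is conditioned on the
    pose-normalised target landmarks; the initial healthy set is exactly the
    landmark vertices.
    """
    config = config or FitConfig()
    names = _match_landmarks(model_landmarks, target_landmarks)
    model_landmarks.validate_for(model.reference)
    vidx = model_landmarks.vertex_indices(names)
    mean_pts = model.mean.reshape(-1, 3)[vidx]
    target_pts = target_landmarks.points(names)
    pose = procrustes_align(mean_pts, target_pts)
    local = pose.inverse().apply(target_pts)
    posterior = posterior_regression(
        model,
        list(zip(vidx.tolist(), local)),
        config.landmark_noise_variance,
    )
    return pose, posterior, vidx.copy()


def _growth_candidates(labels: np.ndarray, adjacency) -> np.ndarray:
    healthy = np.nonzero(labels == HEALTHY)[0]
    if healthy.size == 0:
        return healthy
    cand = np.unique(np.concatenate([adjacency[i] for i in healthy]))
    return cand[labels[cand] == UNHEALTHY]


def mahalanobis_inlier_distances(
    posterior: PosteriorModel,
    target_points: np.ndarray,
    vertex_indices: np.ndarray,
    noise_variance: float,
) -> np.ndarray:
    """Per-vertex Mahalanobis distance of (target point - predicted position)
    under the posterior 3x3 marginal covariance plus sigma^2 I."""
    mdl = posterior.model
    pred = mdl.mean.reshape(-1, 3)[vertex_indices]
    cov = vertex_marginals(mdl, vertex_indices)
    cov = cov + noise_variance * np.eye(3)[None, :, :]
    diff = np.asarray(target_points) - pred
    sol = np.linalg.solve(cov, diff[:, :, None])[:, :, 0]
    return np.sqrt(np.einsum("ij,ij->i", diff, sol))


def grow_healthy_regions(
    posterior: PosteriorModel,
    target: TriangleMesh,
    current_labels: LabelMap,
    config: FitConfig | None = None,
    adjacency=None,
    proximity: SurfaceProximity | None = None,
    pose: RigidTransform | None = None,
) -> LabelMap:
    """One region-growing sweep: promote frontier vertices whose target
    surface neighbourhood is plausible under the posterior marginal.

    Candidates are unhealthy vertices 1-ring adjacent to a healthy one. For
    each candidate the closest target surface point to the posterior-mean
    vertex position is found; the candidate becomes healthy when the
    Mahalanobis distance of the offset under (marginal covariance +
    noise_variance * I) is at most the threshold. Healthy vertices are never
    demoted. ``pose`` maps the model frame to the target frame (identity if
    omitted, i.e. target given in the model frame).
    """
    config = config or FitConfig()
    mdl = posterior.model
    if current_labels.labels.shape[0] != mdl.n_vertices:
        raise GeometryError("label map does not match model topology")
    if adjacency is None:
        adjacency = vertex_adjacency(mdl.reference)
    if proximity is None:
        proximity = SurfaceProximity(target)
    if pose is None:
        pose = RigidTransform.identity()
    labels = current_labels.labels.copy()
    cand = _growth_candidates(labels, adjacency)
    if cand.size == 0:
        return LabelMap(labels)
    pred_local = mdl.mean.reshape(-1, 3)[cand]
    closest_world, _, _ = proximity.query(pose.apply(pred_local))
    closest_local = pose.inverse().apply(closest_world)
    dist = mahalanobis_inlier_distances(
        posterior, closest_local, cand, config.noise_variance
    )
    labels[cand[dist <= config.mahalanobis_threshold]] = HEALTHY
    return LabelMap(labels)


def region_growing_fit(
    model: PointDistributionModel,
    target: TriangleMesh,
    model_landmarks: LandmarkSet,
    target_landmarks: LandmarkSet,
    config: FitConfig | None = None,
) -> FitResult:
    """Landmark-seeded alternating reconstruction and healthy-region growth.

    Alternates Gaussian-process posterior regression on closest-point
    correspondences of the current healthy set with one growth sweep, until
    no vertex is added (or the iteration cap is reached, in which case the
    result is returned with ``converged=False`` and a warning). Vertices
    never labelled healthy form the unhealthy (pathological) set. The
    reconstruction is the final posterior mean placed in the target pose.
    """
    config = config or FitConfig()
    names = _match_landmarks(model_landmarks, target_landmarks)
    lm_idx = model_landmarks.vertex_indices(names)
    lm_targets = target_landmarks.points(names)

    adjacency = vertex_adjacency(model.reference)
    proximity = SurfaceProximity(target)

    pose, posterior, seeds = initialize_from_landmarks(
        model, model_landmarks, target_landmarks, config
    )
    labels = LabelMap(np.zeros(model.n_vertices, dtype=np.uint8))
    labels.labels[seeds] = HEALTHY
    trace = [labels.n_healthy]
    lm_lookup = {int(i): t for i, t in zip(lm_idx, lm_targets)}

    converged = False
    for _ in range(config.max_outer_iterations):
        grown = grow_healthy_regions(
            posterior, target, labels, config, adjacency, proximity, pose
        )
        if grown.n_healthy == labels.n_healthy:
            labels = grown
            trace.append(labels.n_healthy)
            converged = True
            break
        labels = grown
        trace.append(labels.n_healthy)

        healthy = labels.healthy_vertices()
        pred_world = pose.apply(posterior.model.mean.reshape(-1, 3)[healthy])
        corr_world, _, _ = proximity.query(pred_world)
        # landmark correspondences are known exactly; keep them pinned
        for row, vi in enumerate(healthy):
            if int(vi) in lm_lookup:
                corr_world[row] = lm_lookup[int(vi)]
        # refine pose on healthy correspondences, then re-condition the
        # parent model in the updated model frame
        pose = procrustes_align(
            posterior.model.mean.reshape(-1, 3)[healthy], corr_world
        )
        corr_local = pose.inverse().apply(corr_world)
        posterior = posterior_regression(
            model,
            list(zip(healthy.tolist(), corr_local)),
            config.noise_variance,
        )
    else:
        warnings.warn(
            "region growing hit max_outer_iterations before convergence"
        )

    recon_local = posterior.model.mean.reshape(-1, 3)
    recon_world = pose.apply(recon_local)
    _, _, residuals = proximity.query(recon_world)
    reconstruction = model.reference.with_vertices(recon_world, keep_scalars=False)
    reconstruction.scalars["healthy"] = labels.labels.copy()
    return FitResult(
        reconstruction=reconstruction,
        coefficients=posterior.map_coefficients,
        pose=pose,
        label_map=labels,
        residuals=residuals,
        trace=trace,
        converged=converged,
    )
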