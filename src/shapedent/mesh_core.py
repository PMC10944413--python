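"""Triangle meshes, landmarks, rigid transforms, file I/O and proximity queries.

All coordinates are in millimetres. Vertex and triangle indices are 0-based
in memory; writers emit each file format's native convention (OBJ is 1-based
on disk). Meshes "in correspondence" share the same triangle list and vertex
count, so vertex k means the same anatomical location on every mesh.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import GeometryError, MeshFormatError

__all__ = [
    "TriangleMesh",
    "Landmark",
    "LandmarkSet",
    "RigidTransform",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "procrustes_align",
    "closest_points",
    "vertex_adjacency",
]

_MESH_FORMATS = ("ply", "stl", "obj")


@dataclass
class TriangleMesh:
    """A triangle surface mesh with optional named per-vertex scalar channels.

    Parameters
    ----------
    vertices : (N, 3) float array, millimetres.
    triangles : (M, 3) int array of 0-based vertex indices.
    scalars : mapping of channel name to (N,) array.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshFormatError("triangles must be an (M, 3) array")
        if self.n_vertices < 3:
            raise MeshFormatError(
                f"mesh needs at least 3 vertices, got {self.n_vertices}"
            )
        if self.n_triangles < 1:
            raise MeshFormatError("mesh needs at least 1 triangle")
        if self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices:
            bad = self.triangles.max() if self.triangles.max() >= self.n_vertices else self.triangles.min()
            raise MeshFormatError(
                f"triangle references vertex {bad} outside [0, {self.n_vertices})"
            )
        for name, arr in self.scalars.items():
            arr = np.asarray(arr)
            if arr.shape != (self.n_vertices,):
                raise MeshFormatError(
                    f"scalar channel {name!r} has shape {arr.shape}, "
                    f"expected ({self.n_vertices},)"
                )
            self.scalars[name] = arr

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def in_correspondence_with(self, other: "TriangleMesh") -> bool:
        """True if both meshes share vertex count and triangle list."""
        return (
            self.n_vertices == other.n_vertices
            and self.triangles.shape == other.triangles.shape
            and bool(np.array_equal(self.triangles, other.triangles))
        )

    def with_vertices(self, vertices: np.ndarray, keep_scalars: bool = True) -> "TriangleMesh":
        """A mesh with the same topology but new vertex positions."""
        scal = dict(self.scalars) if keep_scalars else {}
        return TriangleMesh(np.asarray(vertices, float).copy(), self.triangles, scal)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.scalars.items()},
        )


@dataclass(frozen=True)
class Landmark:
    name: str
    point: np.ndarray  # (3,)
    vertex_index: int | None = None


class LandmarkSet:
    """An ordered collection of uniquely named 3D landmarks.

    Model-side landmark sets additionally carry the reference-mesh vertex
    index each landmark sits on, so the same anatomical point can be found
    on every mesh in correspondence.
    """

    def __init__(self, landmarks: list[Landmark] | None = None) -> None:
        self._landmarks: list[Landmark] = []
        self._by_name: dict[str, Landmark] = {}
        for lm in landmarks or []:
            self.add(lm)

    def add(self, lm: Landmark) -> None:
        if lm.name in self._by_name:
            raise MeshFormatError(f"duplicate landmark name {lm.name!r}")
        pt = np.asarray(lm.point, dtype=np.float64).reshape(3)
        lm = Landmark(lm.name, pt, lm.vertex_index)
        self._landmarks.append(lm)
        self._by_name[lm.name] = lm

    def __len__(self) -> int:
        return len(self._landmarks)

    def __iter__(self):
        return iter(self._landmarks)

    def __getitem__(self, name: str) -> Landmark:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [lm.name for lm in self._landmarks]

    def points(self, order: list[str] | None = None) -> np.ndarray:
        """Landmark coordinates as an (L, 3) array, optionally in a given name order."""
        names = order if order is not None else self.names
        return np.array([self._by_name[n].point for n in names], dtype=np.float64)

    def vertex_indices(self, order: list[str] | None = None) -> np.ndarray:
        names = order if order is not None else self.names
        idx = []
        for n in names:
            vi = self._by_name[n].vertex_index
            if vi is None:
                raise GeometryError(f"landmark {n!r} has no reference vertex index")
            idx.append(vi)
        return np.array(idx, dtype=np.int64)

    def validate_for(self, mesh: TriangleMesh) -> None:
        """Check that all carried vertex indices are valid for ``mesh``."""
        for lm in self._landmarks:
            if lm.vertex_index is not None and not (
                0 <= lm.vertex_index < mesh.n_vertices
            ):
                raise MeshFormatError(
                    f"landmark {lm.name!r} vertex index {lm.vertex_index} "
                    f"invalid for mesh with {mesh.n_vertices} vertices"
                )


@dataclass
class RigidTransform:
    """Proper rigid motion: x -> rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8:
            raise GeometryError(f"rotation not orthonormal (max deviation {err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-8:
            raise GeometryError(f"rotation determinant {det:.10f} != +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``inner`` first, then self."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _MESH_FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; use one of {_MESH_FORMATS}")
    return fmt


def _weld_exact(vertices: np.ndarray, triangles: np.ndarray):
    """Merge bitwise-identical vertex coordinates (used for STL triangle soup)."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[triangles]


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from PLY, STL or OBJ.

    Vertex order is preserved for PLY and OBJ. STL stores a triangle soup, so
    vertices are welded at bitwise-equal coordinates and the original shared
    vertex identity (but not order) is recovered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, fmt)
    try:
        tm = _trimesh.load(
            str(path), file_type=fmt, process=False, maintain_order=True, force="mesh"
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise MeshFormatError(f"failed to parse {path}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    triangles = np.asarray(tm.faces, dtype=np.int64)
    scalars: dict[str, np.ndarray] = {}
    if fmt == "stl":
        vertices, triangles = _weld_exact(vertices, triangles)
    elif fmt == "ply":
        raw = tm.metadata.get("_ply_raw", {}).get("vertex", {})
        data = raw.get("data", {})
        if isinstance(data, dict):  # ascii parse: dict of columns
            items = data.items()
        else:  # binary parse: structured array
            items = ((n, data[n]) for n in (data.dtype.names or ()))
        for name, col in items:
            if name not in ("x", "y", "z"):
                scalars[name] = np.asarray(col).reshape(-1)
    if triangles.size and (triangles.min() < 0 or triangles.max() >= len(vertices)):
        raise MeshFormatError(
            f"{path}: face references vertex {int(triangles.max())} "
            f"of {len(vertices)}"
        )
    return TriangleMesh(vertices, triangles, scalars)


def _write_ply(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    # double-precision vertices so geometry round-trips below 1e-6 mm
    names = list(mesh.scalars)
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {mesh.n_vertices}")
    header += [f"property double {c}" for c in ("x", "y", "z")]
    for name in names:
        header.append(f"property double {name}")
    header.append(f"element face {mesh.n_triangles}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")
    cols = [mesh.vertices] + [
        np.asarray(mesh.scalars[n], float).reshape(-1, 1) for n in names
    ]
    vdata = np.hstack(cols)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(vdata.astype("<f8").tobytes())
            for tri in mesh.triangles:
                fh.write(struct.pack("<Biii", 3, *(int(i) for i in tri)))
        else:
            for row in vdata:
                fh.write((" ".join(f"{x:.17g}" for x in row) + "\n").encode())
            for tri in mesh.triangles:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n".encode())


def write_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    fmt: str | None = None,
    binary: bool = True,
) -> None:
    """Write a mesh to PLY (ASCII or binary little-endian), STL or OBJ.

    PLY carries per-vertex scalar channels and round-trips geometry exactly;
    OBJ keeps topology and coordinates to 1e-8; STL is lossy (triangle soup,
    float32 coordinates) and drops shared-vertex identity.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        _write_ply(mesh, path, binary=binary)
        return
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    try:
        if fmt == "stl":
            tm.export(str(path), file_type="stl" if binary else "stl_ascii")
        else:
            tm.export(str(path), file_type="obj")
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark set from a JSON array of {name, point, vertex_index}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        try:
            records = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MeshFormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise MeshFormatError(f"{path}: expected a JSON array of landmark records")
    lms = LandmarkSet()
    for rec in records:
        try:
            lms.add(
                Landmark(
                    name=rec["name"],
                    point=np.asarray(rec["point"], dtype=np.float64),
                    vertex_index=rec.get("vertex_index"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise MeshFormatError(f"{path}: malformed landmark record {rec!r}") from exc
    return lms


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    records = [
        {
            "name": lm.name,
            "point": [float(x) for x in lm.point],
            "vertex_index": None if lm.vertex_index is None else int(lm.vertex_index),
        }
        for lm in landmarks
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# rigid alignment
# ---------------------------------------------------------------------------

def procrustes_align(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment (rotation + translation, no scaling).

    Finds the proper rigid transform T minimising sum ||T(moving_i) - fixed_i||^2
    over paired point lists. Scaling is deliberately excluded: overall size is
    part of the shape signal and is left to the shape model.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise GeometryError(
            f"point lists must be matching (L, 3) arrays, got {moving.shape} vs {fixed.shape}"
        )
    if moving.shape[0] < 3:
        raise GeometryError("rigid alignment needs at least 3 point pairs")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    # collinear (rank < 2) clouds leave a rotation DOF undetermined
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
        raise GeometryError("degenerate (collinear) point configuration")
    rot, _ = Rotation.align_vectors(b, a)  # proper rotation by construction
    r = rot.as_matrix()
    return RigidTransform(r, fc - r @ mc)


# ---------------------------------------------------------------------------
# closest-point queries
# ---------------------------------------------------------------------------

def _point_triangle_closest(points: np.ndarray, tri_a, tri_b, tri_c) -> np.ndarray:
    """Closest point on each triangle (a,b,c) to each query point.

    Vectorised barycentric clamping; ``points`` and triangle corner arrays are
    broadcast-compatible (..., 3). Returns closest points with the same shape.
    """
    ab = tri_b - tri_a
    ac = tri_c - tri_a
    ap = points - tri_a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)
    bp = points - tri_b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)
    cp = points - tri_c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    inner = tri_a + v[..., None] * ab + w[..., None] * ac

    # edge/vertex regions
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        t_bc = np.clip(
            np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0),
            0,
            1,
        )
    out = inner
    on_bc = tri_b + t_bc[..., None] * (tri_c - tri_b)
    out = np.where((va <= 0)[..., None] & (d4 - d3 >= 0)[..., None] & (d5 - d6 >= 0)[..., None], on_bc, out)
    on_ac = tri_a + t_ac[..., None] * ac
    out = np.where((vb <= 0)[..., None] & (d2 >= 0)[..., None] & (d6 <= 0)[..., None], on_ac, out)
    on_ab = tri_a + t_ab[..., None] * ab
    out = np.where((vc <= 0)[..., None] & (d1 >= 0)[..., None] & (d3 <= 0)[..., None], on_ab, out)
    out = np.where((d6 >= 0)[..., None] & (d5 <= d6)[..., None], np.broadcast_to(tri_c, out.shape), out)
    out = np.where((d3 >= 0)[..., None] & (d4 <= d3)[..., None], np.broadcast_to(tri_b, out.shape), out)
    out = np.where((d1 <= 0)[..., None] & (d2 <= 0)[..., None], np.broadcast_to(tri_a, out.shape), out)
    return out


class SurfaceProximity:
    """Exact closest-point queries against a fixed triangle mesh.

    Candidate triangles are found through a k-d tree on triangle centroids;
    a conservative radius bound guarantees the nearest triangle is always
    among the candidates, so distances are exact. Ties are broken by the
    lowest triangle index for reproducibility.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 24) -> None:
        self.mesh = mesh
        tri = mesh.vertices[mesh.triangles]  # (M, 3, 3)
        self._tri = tri
        self._centroids = tri.mean(axis=1)
        # max centroid-to-corner distance bounds how far a triangle's surface
        # can extend beyond its centroid
        self._radius = float(
            np.sqrt(((tri - self._centroids[:, None, :]) ** 2).sum(-1)).max()
        )
        self._tree = cKDTree(self._centroids)
        self._k = min(k, mesh.n_triangles)

    def query(self, points: np.ndarray):
        points = np.asarray(points, dtype=np.float64)
        if points.size == 0:
            return (
                np.zeros((0, 3)),
                np.zeros(0, dtype=np.int64),
                np.zeros(0),
            )
        single = points.ndim == 1
        points = np.atleast_2d(points)
        k = self._k
        dc, idx = self._tree.query(points, k=k)
        if k == 1:
            dc = dc[:, None]
            idx = idx[:, None]
        best_pt, best_tri, best_d = self._eval_candidates(points, idx)
        if k < self.mesh.n_triangles:
            # a triangle outside the k candidates has centroid distance
            # >= dc[:, -1]; its surface cannot come closer than that minus
            # the radius bound. Re-examine points whose best distance does
            # not beat that bound, in vectorised batches of growing k.
            unsafe = np.nonzero(best_d > dc[:, -1] - self._radius)[0]
            if unsafe.size:
                # any triangle beating the current best has its centroid
                # within best_d + radius of the query: one ragged ball query
                # per unsafe point, padded with the current best triangle
                balls = self._tree.query_ball_point(
                    points[unsafe], best_d[unsafe] + self._radius + 1e-9,
                    return_sorted=True,
                )
                width = max(len(b) for b in balls)
                idx_u = np.tile(best_tri[unsafe][:, None], (1, width))
                for row, b in enumerate(balls):
                    idx_u[row, : len(b)] = b
                p, t, d = self._eval_candidates(points[unsafe], idx_u)
                best_pt[unsafe], best_tri[unsafe], best_d[unsafe] = p, t, d
        if single:
            return best_pt[0], int(best_tri[0]), float(best_d[0])
        return best_pt, best_tri, best_d

    def _eval_candidates(self, points, idx):
        tri = self._tri[idx]  # (Q, K, 3, 3)
        cp = _point_triangle_closest(
            points[:, None, :], tri[:, :, 0], tri[:, :, 1], tri[:, :, 2]
        )
        d = np.sqrt(((cp - points[:, None, :]) ** 2).sum(-1))
        # tie-break: among equal distances pick the lowest triangle index
        order = np.lexsort((idx, d), axis=1)
        first = order[:, 0]
        rows = np.arange(len(points))
        return cp[rows, first], idx[rows, first].astype(np.int64), d[rows, first]


def closest_points(query: np.ndarray, surface: TriangleMesh):
    """For each query point, the exact closest surface point on the mesh.

    Returns ``(points, triangle_indices, distances)``. Distances are the
    Euclidean point-to-triangle distances; ties between triangles are broken
    by the lowest triangle index.
    """
    return SurfaceProximity(surface).query(query)


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """1-ring vertex neighbourhoods: adjacency[i] = sorted neighbours of vertex i."""
    edges = np.vstack(
        [mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]], mesh.triangles[:, [2, 0]]]
    )
    edges = np.vstack([edges, edges[:, ::-1]])
    edges = np.unique(edges, axis=0)
    adjacency: list[np.ndarray] = []
    splits = np.searchsorted(edges[:, 0], np.arange(mesh.n_vertices + 1))
    for i in range(mesh.n_vertices):
        adjacency.append(edges[splits[i] : splits[i + 1], 1])
    return adjacency
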