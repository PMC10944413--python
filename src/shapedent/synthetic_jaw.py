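"""Parametric synthetic jaws in guaranteed vertex-wise correspondence.

The generator produces a stylised lower jaw as a heightfield over a
horseshoe band: an elliptical arch carries an alveolar ridge with sixteen
smooth tooth bumps (FDI 31-38 and 41-48), and both ends rise into a ramus
with a condyle and a coronoid protrusion. Because every mesh is evaluated
on the same fixed parameter grid, cohort members and corrupted targets
share the reference triangle list, i.e. they are in correspondence by
construction — the property a registration pipeline has to establish for
real scan data.

Geometric realism is deliberately limited to what the detection pipeline
consumes: teeth protrude from an arch, anterior teeth are tall and narrow,
molars and especially the rearmost teeth blend more smoothly into the jaw
(which is what makes them hard for a purely shape-based detector).

Every generated mesh carries one scalar channel per tooth
(``tooth_elev_<fdi>``, mm) holding that tooth's vertical bump contribution,
so corruption can remove exactly the geometry the tooth added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError
from .mesh_core import Landmark, LandmarkSet, RigidTransform, TriangleMesh
from .tooth_detection import MANDIBULAR_FDI, ToothRegionMap

__all__ = [
    "JawParams",
    "CorruptionSpec",
    "ToothTruth",
    "GroundTruth",
    "generate_reference_jaw",
    "generate_cohort",
    "corrupt",
    "first_dentition_params",
    "ARCH_ORDER",
]

# teeth in order along the arch, right ramus to left ramus
ARCH_ORDER: tuple[int, ...] = (48, 47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37, 38)

_DEFAULT_HEIGHTS = {
    **{f: 8.0 for f in (31, 32, 41, 42)},  # incisors
    **{f: 9.0 for f in (33, 43)},  # canines
    **{f: 7.5 for f in (34, 35, 44, 45)},  # premolars
    **{f: 6.0 for f in (36, 37, 46, 47)},  # molars
    **{f: 4.5 for f in (38, 48)},  # wisdom teeth: low, smooth transition
}
_DEFAULT_RADII = {
    **{f: 2.4 for f in (31, 32, 41, 42)},
    **{f: 2.8 for f in (33, 43)},
    **{f: 3.2 for f in (34, 35, 44, 45)},
    **{f: 4.0 for f in (36, 37, 46, 47)},
    **{f: 4.5 for f in (38, 48)},
}


@dataclass
class JawParams:
    """Shape parameters of the synthetic jaw (all lengths in mm)."""

    arch_width: float = 100.0  # condyle-to-condyle extent (x)
    arch_depth: float = 90.0  # front-to-back extent (y)
    band_width: float = 16.0  # buccal-lingual width of the surface band
    ridge_height: float = 6.0  # alveolar ridge elevation at band centre
    ramus_height: float = 40.0  # vertical rise at both arch ends
    ramus_length: float = 15.0  # decay length of the ramus rise along the arch
    condyle_height: float = 8.0
    coronoid_height: float = 6.0
    tooth_heights: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_HEIGHTS))
    tooth_radii: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_RADII))
    n_arch: int = 193  # grid nodes along the arch (odd keeps a midline node)
    n_band: int = 25  # grid nodes across the band (odd keeps a ridge-centre node)
    region_cutoff: float = 1.0  # region radius in units of the tooth radius

    def __post_init__(self) -> None:
        for name in (
            "arch_width", "arch_depth", "band_width", "ridge_height",
            "ramus_height", "ramus_length", "condyle_height", "coronoid_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for fdi in MANDIBULAR_FDI:
            if self.tooth_heights.get(fdi, 0) <= 0 or self.tooth_radii.get(fdi, 0) <= 0:
                raise ValueError(f"tooth {fdi} needs positive height and radius")
        n = self.n_arch * self.n_band
        if not 2000 <= n <= 20000:
            raise ValueError(
                f"resolution gives {n} vertices; must lie in [2000, 20000]"
            )


def first_dentition_params(base: JawParams | None = None) -> JawParams:
    """A deciduous-dentition preset: smaller, flatter anterior teeth."""
    base = base or JawParams()
    heights = dict(base.tooth_heights)
    radii = dict(base.tooth_radii)
    for fdi in (31, 32, 33, 41, 42, 43):
        heights[fdi] *= 0.65
        radii[fdi] *= 0.85
    return replace(base, tooth_heights=heights, tooth_radii=radii)


# ---------------------------------------------------------------------------
# the fixed parameter frame shared by the whole cohort
# ---------------------------------------------------------------------------

_THETA_END = np.deg2rad(130.0)
_TOOTH_GAP = 1.2  # mm between adjacent tooth stations
_TOOTH_WIDTH_FACTOR = 2.2  # station width as multiple of the tooth radius


class _JawFrame:
    """Grid layout, station and landmark node placement for a base parameter
    set. All cohort members reuse the same frame, which is what guarantees
    correspondence."""

    def __init__(self, params: JawParams) -> None:
        self.params = params
        a, b = params.arch_width / 2.0, params.arch_depth / 2.0
        # uniform-arc-length theta grid along the elliptical centreline,
        # built from a mirrored half-arch so the layout is exactly symmetric
        half = np.linspace(0.0, _THETA_END, 2048)
        speed = np.hypot(a * np.cos(half), b * np.sin(half))
        s_half = np.concatenate([[0.0], np.cumsum(np.diff(half) * 0.5 * (speed[1:] + speed[:-1]))])
        self.total_length = float(2.0 * s_half[-1])
        self.s_grid = np.linspace(0.0, self.total_length, params.n_arch)
        offsets = self.s_grid - self.total_length / 2.0
        self.theta_grid = np.sign(offsets) * np.interp(np.abs(offsets), s_half, half)
        self.v_grid = np.linspace(-params.band_width / 2, params.band_width / 2, params.n_band)
        self._place_stations()
        self._assign_regions()
        self._build_topology()
        self._place_landmarks()

    # -- helpers ----------------------------------------------------------

    def node(self, i_arch: int, j_band: int) -> int:
        return i_arch * self.params.n_band + j_band

    def _nearest_arch(self, s: float) -> int:
        return int(np.argmin(np.abs(self.s_grid - s)))

    def _place_stations(self) -> None:
        p = self.params
        mid = self.total_length / 2.0
        widths = {f: _TOOTH_WIDTH_FACTOR * p.tooth_radii[f] for f in MANDIBULAR_FDI}
        self.station_s: dict[int, float] = {}
        # walk outward from the midline in both directions
        for side, teeth in ((-1, (41, 42, 43, 44, 45, 46, 47, 48)),
                            (+1, (31, 32, 33, 34, 35, 36, 37, 38))):
            offset = _TOOTH_GAP / 2.0
            for fdi in teeth:
                offset += widths[fdi] / 2.0
                i = self._nearest_arch(mid + side * offset)
                self.station_s[fdi] = float(self.s_grid[i])
                offset += widths[fdi] / 2.0 + _TOOTH_GAP
        self.j_ridge = p.n_band // 2  # v = 0 node

    def _assign_regions(self) -> None:
        p = self.params
        ss, vv = np.meshgrid(self.s_grid, self.v_grid, indexing="ij")
        codes = np.zeros(ss.size, dtype=np.int16)
        best = np.full(ss.size, np.inf)
        for fdi in MANDIBULAR_FDI:
            rho = np.hypot(ss - self.station_s[fdi], vv) / p.tooth_radii[fdi]
            rho = rho.reshape(-1)
            take = (rho <= p.region_cutoff) & (rho < best)
            codes[take] = fdi
            best = np.minimum(best, np.where(rho <= p.region_cutoff, rho, np.inf))
        self.region_codes = codes
        self.ss, self.vv = ss, vv

    def _build_topology(self) -> None:
        na, nb = self.params.n_arch, self.params.n_band
        i, j = np.meshgrid(np.arange(na - 1), np.arange(nb - 1), indexing="ij")
        v00 = i * nb + j
        v01 = v00 + 1
        v10 = v00 + nb
        v11 = v10 + 1
        t1 = np.stack([v00, v10, v01], axis=-1).reshape(-1, 3)
        t2 = np.stack([v01, v10, v11], axis=-1).reshape(-1, 3)
        self.triangles = np.vstack([t1, t2]).astype(np.int64)

    def _place_landmarks(self) -> None:
        p = self.params
        nb = p.n_band
        j_cond = nb // 2 + nb // 4  # lingual quarter of the band
        j_coro = nb // 2 - nb // 4
        self.condyle_s = 3.0
        self.coronoid_s = 12.0
        mid_i = self._nearest_arch(self.total_length / 2.0)
        spots: list[tuple[str, int]] = []
        for side, tag in ((0, "right"), (1, "left")):
            end_s = self.condyle_s if side == 0 else self.total_length - self.condyle_s
            cor_s = self.coronoid_s if side == 0 else self.total_length - self.coronoid_s
            i_cond = self._nearest_arch(end_s)
            i_coro = self._nearest_arch(cor_s)
            spots.append((f"condyle_{tag}_a", self.node(i_cond, j_cond)))
            spots.append((f"condyle_{tag}_b", self.node(i_cond, j_cond - 1)))
            spots.append((f"coronoid_{tag}", self.node(i_coro, j_coro)))
        for fdi, tag in ((48, "right"), (38, "left")):
            i = self._nearest_arch(self.station_s[fdi])
            spots.append((f"wisdom_{tag}", self.node(i, self.j_ridge)))
        spots.append(("papilla_31_41", self.node(mid_i, self.j_ridge)))
        spots.append(("chin", self.node(mid_i, nb - 1)))  # outer band edge, midline
        self.landmark_nodes = spots
        self.j_cond, self.j_coro = j_cond, j_coro


def _evaluate(frame: _JawFrame, params: JawParams, size_scale: float = 1.0):
    """Vertex positions and per-tooth elevation channels for one subject."""
    base = frame.params
    a, b = params.arch_width / 2.0, params.arch_depth / 2.0
    theta = frame.theta_grid[:, None]
    v = frame.v_grid[None, :]
    cx = a * np.sin(theta)
    cy = -b * np.cos(theta)
    # outward in-plane normal of the ellipse
    nx = b * np.sin(theta)
    ny = -a * np.cos(theta)
    norm = np.hypot(nx, ny)
    nx, ny = nx / norm, ny / norm
    x = cx + v * nx
    y = cy + v * ny

    s = frame.s_grid[:, None]
    ridge_sigma = base.band_width / 3.0
    z = params.ridge_height * np.exp(-(v / ridge_sigma) ** 2)
    z = z + params.ramus_height * (
        np.exp(-((s / params.ramus_length) ** 2))
        + np.exp(-(((frame.total_length - s) / params.ramus_length) ** 2))
    )
    for end_s in (frame.condyle_s, frame.total_length - frame.condyle_s):
        z = z + params.condyle_height * np.exp(
            -((s - end_s) ** 2 + (v - frame.v_grid[frame.j_cond]) ** 2) / 4.0**2
        )
    for end_s in (frame.coronoid_s, frame.total_length - frame.coronoid_s):
        z = z + params.coronoid_height * np.exp(
            -((s - end_s) ** 2 + (v - frame.v_grid[frame.j_coro]) ** 2) / 3.5**2
        )

    channels: dict[str, np.ndarray] = {}
    for fdi in MANDIBULAR_FDI:
        elev = params.tooth_heights[fdi] * np.exp(
            -((s - frame.station_s[fdi]) ** 2 + v**2) / params.tooth_radii[fdi] ** 2
        )
        z = z + elev
        channels[f"tooth_elev_{fdi}"] = size_scale * elev.reshape(-1)

    vertices = size_scale * np.stack(
        [x.reshape(-1), y.reshape(-1), z.reshape(-1)], axis=1
    )
    return vertices, channels


def generate_reference_jaw(
    params: JawParams | None = None,
) -> tuple[TriangleMesh, ToothRegionMap, LandmarkSet]:
    """The reference jaw with its tooth-region map and 10-landmark layout.

    The landmark layout mirrors the seeding scheme used on real mandibles:
    two per condyle, one per coronoid, one on each wisdom tooth, one on the
    interdental papilla between teeth 31 and 41, and one on the chin.
    """
    params = params or JawParams()
    frame = _JawFrame(params)
    vertices, channels = _evaluate(frame, params)
    mesh = TriangleMesh(vertices, frame.triangles, channels)
    regions = ToothRegionMap(frame.region_codes)
    landmarks = LandmarkSet(
        [
            Landmark(name, mesh.vertices[node], vertex_index=node)
            for name, node in frame.landmark_nodes
        ]
    )
    return mesh, regions, landmarks


def _subject_params(params: JawParams, variation_scale: float, rng) -> tuple[JawParams, float]:
    """Smoothly perturbed per-subject parameters.

    Baseline coefficients of variation (scaled by ``variation_scale``):
    overall size 3%, arch width/depth 2%, ridge height 5%, ramus height 4%,
    tooth heights 6%, tooth radii 3%.
    """
    def jitter(cv: float, n: int = 1):
        vals = 1.0 + variation_scale * cv * rng.standard_normal(n)
        return np.clip(vals, 0.2, 5.0)

    size_scale = float(jitter(0.03)[0])
    heights = {
        f: params.tooth_heights[f] * float(j)
        for f, j in zip(MANDIBULAR_FDI, jitter(0.06, 16))
    }
    radii = {
        f: params.tooth_radii[f] * float(j)
        for f, j in zip(MANDIBULAR_FDI, jitter(0.03, 16))
    }
    subject = replace(
        params,
        arch_width=params.arch_width * float(jitter(0.02)[0]),
        arch_depth=params.arch_depth * float(jitter(0.02)[0]),
        ridge_height=params.ridge_height * float(jitter(0.05)[0]),
        ramus_height=params.ramus_height * float(jitter(0.04)[0]),
        tooth_heights=heights,
        tooth_radii=radii,
    )
    return subject, size_scale


def generate_cohort(
    params: JawParams | None = None,
    n: int = 9,
    variation_scale: float = 1.0,
    seed: int = 0,
) -> list[TriangleMesh]:
    """n jaws sharing the reference topology, with seeded smooth shape variation.

    ``variation_scale`` multiplies the baseline per-parameter coefficients of
    variation (see ``_subject_params``); 0 reproduces the reference exactly.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    params = params or JawParams()
    frame = _JawFrame(params)
    rng = np.random.default_rng(seed)
    meshes = []
    for _ in range(n):
        subject, size_scale = _subject_params(params, variation_scale, rng)
        vertices, channels = _evaluate(frame, subject, size_scale)
        meshes.append(TriangleMesh(vertices, frame.triangles, channels))
    return meshes


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

_MODES = ("full_removal", "root_remnant", "gap_closure")


@dataclass
class CorruptionSpec:
    """What to do to a pristine jaw to make it a test target.

    ``modes`` maps FDI codes to a corruption mode: ``full_removal`` collapses
    the tooth onto the arch, ``root_remnant`` keeps ``remnant_fraction`` of
    its height, ``gap_closure`` removes the tooth and shifts the two flanking
    teeth ``gap_shift_mm`` toward the gap. Afterwards Gaussian surface noise
    and a random rigid motion (both seeded) are applied.
    """

    modes: dict[int, str] = field(default_factory=dict)
    remnant_fraction: float = 0.4
    gap_shift_mm: float = 2.0
    noise_sigma: float = 0.0
    max_rotation_deg: float = 0.0
    max_translation_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for fdi, mode in self.modes.items():
            if fdi not in MANDIBULAR_FDI:
                raise ValueError(f"{fdi} is not a mandibular FDI code")
            if mode not in _MODES:
                raise ValueError(f"unknown corruption mode {mode!r}")
        if not 0 < self.remnant_fraction < 1:
            raise ValueError("remnant_fraction must lie in (0, 1)")
        if self.noise_sigma < 0 or self.max_rotation_deg < 0 or self.max_translation_mm < 0:
            raise ValueError("noise and perturbation magnitudes must be >= 0")

    @property
    def removed_teeth(self) -> set[int]:
        return set(self.modes)


@dataclass(frozen=True)
class ToothTruth:
    binary: int  # 1 = present, 0 = absent
    category: str  # present | absent | root | gap_closure


@dataclass
class GroundTruth:
    """Per-tooth annotation consistent with the geometric edit applied, plus
    the rigid motion the target received."""

    teeth: dict[int, ToothTruth]
    transform: RigidTransform


def _region_peak_xy(mesh: TriangleMesh, regions: ToothRegionMap, fdi: int) -> np.ndarray:
    verts = regions.vertices_of(fdi)
    elev = mesh.scalars[f"tooth_elev_{fdi}"][verts]
    return mesh.vertices[verts[int(np.argmax(elev))], :2]


def _neighbours(fdi: int) -> list[int]:
    i = ARCH_ORDER.index(fdi)
    out = []
    if i > 0:
        out.append(ARCH_ORDER[i - 1])
    if i < len(ARCH_ORDER) - 1:
        out.append(ARCH_ORDER[i + 1])
    return out


def corrupt(
    mesh: TriangleMesh,
    regions: ToothRegionMap,
    spec: CorruptionSpec,
) -> tuple[TriangleMesh, GroundTruth]:
    """Apply the corruption spec to a generator-produced jaw.

    The input must carry the generator's ``tooth_elev_<fdi>`` channels in the
    generator's canonical frame (tooth bumps rise along +z): removal works by
    subtracting each tooth's recorded elevation at its region vertices, so
    non-region vertices are untouched before noise. Ground truth labels
    full-removal and gap-closure teeth absent; a root remnant keeps its
    binary "present" label and is flagged by category, mirroring how such
    findings are annotated as exceptional rather than plainly missing.
    """
    if mesh.n_vertices != regions.n_vertices:
        raise GeometryError("mesh and region map disagree on vertex count")
    for fdi in spec.modes:
        if regions.vertices_of(fdi).size == 0:
            raise ValueError(f"cannot corrupt tooth {fdi}: its region is empty")
        if f"tooth_elev_{fdi}" not in mesh.scalars:
            raise ValueError(f"mesh lacks the tooth_elev_{fdi} channel")
    out = mesh.vertices.copy()
    truth: dict[int, ToothTruth] = {
        fdi: ToothTruth(1, "present") for fdi in MANDIBULAR_FDI
    }
    for fdi, mode in spec.modes.items():
        verts = regions.vertices_of(fdi)
        elev = mesh.scalars[f"tooth_elev_{fdi}"][verts]
        if mode == "full_removal":
            out[verts, 2] -= elev
            truth[fdi] = ToothTruth(0, "absent")
        elif mode == "root_remnant":
            out[verts, 2] -= (1.0 - spec.remnant_fraction) * elev
            truth[fdi] = ToothTruth(1, "root")
        else:  # gap_closure
            out[verts, 2] -= elev
            truth[fdi] = ToothTruth(0, "gap_closure")
            gap_xy = _region_peak_xy(mesh, regions, fdi)
            for nb in _neighbours(fdi):
                if nb in spec.modes:
                    continue
                nb_verts = regions.vertices_of(nb)
                direction = gap_xy - _region_peak_xy(mesh, regions, nb)
                nrm = np.linalg.norm(direction)
                if nrm > 0:
                    out[nb_verts, :2] += spec.gap_shift_mm * direction / nrm
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, out.shape)
    transform = RigidTransform.identity()
    if spec.max_rotation_deg > 0 or spec.max_translation_mm > 0:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0.0, spec.max_rotation_deg))
        from scipy.spatial.transform import Rotation

        r = Rotation.from_rotvec(angle * axis).as_matrix()
        tdir = rng.standard_normal(3)
        tdir /= np.linalg.norm(tdir)
        t = rng.uniform(0.0, spec.max_translation_mm) * tdir
        centroid = out.mean(axis=0)
        transform = RigidTransform(r, centroid - r @ centroid + t)
        out = transform.apply(out)
    return TriangleMesh(out, mesh.triangles.copy()), GroundTruth(truth, transform)
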