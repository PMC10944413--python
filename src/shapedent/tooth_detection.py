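"""Per-tooth present/missing calls from a fitted binary label map.

Tooth regions are annotated once on the model's reference topology (each
reference vertex belongs to at most one mandibular FDI tooth, 31-38 and
41-48). After robust fitting has produced a healthy/unhealthy label per
vertex, a tooth is called missing when at least a threshold fraction
(default 70%) of its region's vertices are labelled unhealthy.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CorrespondenceError, MeshFormatError
from .mesh_core import TriangleMesh

__all__ = [
    "MANDIBULAR_FDI",
    "ToothRegionMap",
    "DetectionConfig",
    "ToothCall",
    "DetectionResult",
    "load_tooth_regions",
    "detect_missing_teeth",
    "end_to_end_detect",
]

# mandibular teeth in FDI notation, evaluated left quadrant 31..38 then
# right quadrant 41..48
MANDIBULAR_FDI: tuple[int, ...] = tuple(range(31, 39)) + tuple(range(41, 49))
NONE_CODE = 0


class ToothRegionMap:
    """Assignment of every reference vertex to one FDI tooth or NONE (jaw/gum)."""

    def __init__(self, codes: np.ndarray) -> None:
        codes = np.asarray(codes, dtype=np.int16).reshape(-1)
        bad = set(np.unique(codes)) - set(MANDIBULAR_FDI) - {NONE_CODE}
        if bad:
            raise MeshFormatError(f"invalid FDI codes in region map: {sorted(bad)}")
        self.codes = codes

    @property
    def n_vertices(self) -> int:
        return self.codes.shape[0]

    def vertices_of(self, fdi: int) -> np.ndarray:
        if fdi not in MANDIBULAR_FDI:
            raise ValueError(f"{fdi} is not a mandibular FDI code")
        return np.nonzero(self.codes == fdi)[0]

    def has_full_dentition(self) -> bool:
        """True if every one of the 16 mandibular teeth has at least one vertex."""
        present = set(np.unique(self.codes))
        return all(fdi in present for fdi in MANDIBULAR_FDI)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["vertex_index", "fdi_code"])
            for i in np.nonzero(self.codes != NONE_CODE)[0]:
                writer.writerow([int(i), int(self.codes[i])])


def load_tooth_regions(path: str | Path, reference: TriangleMesh) -> ToothRegionMap:
    """Read a vertex_index -> FDI code table (CSV or JSON).

    Vertices absent from the file default to NONE. Codes outside the 16
    mandibular FDI numbers and vertex indices outside the reference topology
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    codes = np.zeros(reference.n_vertices, dtype=np.int16)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            pairs = [(int(k), int(v)) for k, v in json.load(fh).items()]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                pairs = []
            else:
                if "vertex_index" not in reader.fieldnames or "fdi_code" not in reader.fieldnames:
                    raise MeshFormatError(
                        f"{path}: expected header vertex_index,fdi_code"
                    )
                try:
                    pairs = [
                        (int(row["vertex_index"]), int(row["fdi_code"])) for row in reader
                    ]
                except (TypeError, ValueError) as exc:
                    raise MeshFormatError(f"{path}: malformed row: {exc}") from exc
    for vi, code in pairs:
        if not 0 <= vi < reference.n_vertices:
            raise MeshFormatError(
                f"{path}: vertex index {vi} outside reference "
                f"({reference.n_vertices} vertices)"
            )
        if code not in MANDIBULAR_FDI:
            raise MeshFormatError(
                f"{path}: FDI code {code} is not a mandibular tooth (31-38, 41-48)"
            )
        codes[vi] = code
    return ToothRegionMap(codes)


@dataclass
class DetectionConfig:
    """missing_fraction_threshold: a tooth is called missing when the fraction
    of its region's vertices labelled unhealthy reaches this value (inclusive)."""

    missing_fraction_threshold: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.missing_fraction_threshold <= 1:
            raise ValueError("missing_fraction_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ToothCall:
    fdi: int
    unhealthy_fraction: float  # NaN when the region is empty
    call: str  # "present" | "missing" | "undetermined"


@dataclass
class DetectionResult:
    """Per-tooth unhealthy fractions and present/missing calls, in FDI order
    31..38 then 41..48."""

    calls: list[ToothCall] = field(default_factory=list)

    def __getitem__(self, fdi: int) -> ToothCall:
        for c in self.calls:
            if c.fdi == fdi:
                return c
        raise KeyError(fdi)

    @property
    def missing(self) -> list[int]:
        return [c.fdi for c in self.calls if c.call == "missing"]

    def to_dict(self) -> dict:
        return {
            str(c.fdi): {"unhealthy_fraction": c.unhealthy_fraction, "call": c.call}
            for c in self.calls
        }

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tooth", "unhealthy_fraction", "call"])
            for c in self.calls:
                writer.writerow([c.fdi, f"{c.unhealthy_fraction:.6f}", c.call])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def detect_missing_teeth(
    label_map,
    regions: ToothRegionMap,
    config: DetectionConfig | None = None,
) -> DetectionResult:
    """Apply the fraction-of-unhealthy-vertices rule to every mandibular tooth.

    For each tooth, unhealthy_fraction = (# region vertices with label 0) /
    (# region vertices). The call is "missing" when the fraction reaches the
    threshold (inclusive), "present" otherwise, and "undetermined" (with a
    warning) for empty regions.
    """
    config = config or DetectionConfig()
    labels = np.asarray(getattr(label_map, "labels", label_map)).reshape(-1)
    if labels.shape[0] != regions.n_vertices:
        raise CorrespondenceError(
            f"label map has {labels.shape[0]} vertices, region map "
            f"{regions.n_vertices}"
        )
    result = DetectionResult()
    for fdi in MANDIBULAR_FDI:
        verts = regions.vertices_of(fdi)
        if verts.size == 0:
            warnings.warn(f"tooth {fdi} has an empty region; call undetermined")
            result.calls.append(ToothCall(fdi, float("nan"), "undetermined"))
            continue
        fraction = float(np.mean(labels[verts] == 0))
        call = (
            "missing" if fraction >= config.missing_fraction_threshold else "present"
        )
        result.calls.append(ToothCall(fdi, fraction, call))
    return result


def end_to_end_detect(
    model,
    target: TriangleMesh,
    model_landmarks,
    target_landmarks,
    regions: ToothRegionMap,
    fit_config=None,
    detection_config: DetectionConfig | None = None,
):
    """Robust fit followed by the missing-tooth rule; deterministic given inputs.

    Returns ``(FitResult, DetectionResult)``.
    """
    from .robust_fitting import region_growing_fit

    fit = region_growing_fit(model, target, model_landmarks, target_landmarks, fit_config)
    detection = detect_missing_teeth(fit.label_map, regions, detection_config)
    return fit, detection
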