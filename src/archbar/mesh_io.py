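"""STL input/output and declarative surface-region selection.

The measurement pipeline needs six named planar regions on the two bar ends
(AP1, PP1, VP1 on the first quadrant end; AP2, PP2, VP2 on the second):
anterior, posterior and vestibular faces.  Interactive surface picking is
replaced by declarative selectors (oriented boxes or seed-point spheres)
stored in a YAML/JSON configuration, so a run is fully reproducible.

STL carries no units; this package fixes millimetres as canonical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .geometry import ReferenceFrame, _as_vec3

#: The six region names required by the bar metrology, in canonical order.
REGION_NAMES = ("AP1", "PP1", "VP1", "AP2", "PP2", "VP2")

#: Duplicate vertices closer than this (mm) are merged on load.
MERGE_TOL = 1e-9

# A TriangleMesh throughout the package is a trimesh.Trimesh (vertices (n,3)
# float mm, faces (m,3) int).
TriangleMesh = trimesh.Trimesh


class STLFormatError(ValueError):
    """Unreadable or truncated STL file."""


class EmptyMeshError(ValueError):
    """STL parsed but contains no faces."""


class InsufficientRegionError(ValueError):
    """A region selector matched fewer than 3 mesh vertices."""


def _check_binary_stl_size(path: Path) -> None:
    """Pre-validate a binary STL's declared triangle count against file size
    so truncation is reported with a byte offset instead of a numpy error."""
    size = path.stat().st_size
    if size < 84:
        raise STLFormatError(
            f"{path}: truncated STL header, {size} bytes < 84")
    with open(path, "rb") as fh:
        head = fh.read(84)
    n_tri = int(np.frombuffer(head[80:84], dtype="<u4")[0])
    expected = 84 + 50 * n_tri
    if size < expected:
        raise STLFormatError(
            f"{path}: truncated binary STL, expected {expected} bytes for "
            f"{n_tri} triangles, file ends at byte {size}")


def _looks_ascii_stl(path: Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(512)
    return (head.lstrip().lower().startswith(b"solid")
            and (b"facet" in head or b"endsolid" in head))


def read_stl(path) -> TriangleMesh:
    """Load a binary or ASCII STL as a :class:`trimesh.Trimesh`.

    Duplicate vertices within ``MERGE_TOL`` mm are merged; zero-area faces
    are dropped.  Raises :class:`STLFormatError` for unreadable/truncated
    files and :class:`EmptyMeshError` for face-less ones.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if not _looks_ascii_stl(path):
        _check_binary_stl_size(path)
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise STLFormatError(f"{path}: cannot parse STL ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise EmptyMeshError(f"{path}: STL contains no triangles")
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    mesh.update_faces(mesh.nondegenerate_faces())
    if len(mesh.faces) == 0:
        raise EmptyMeshError(f"{path}: all faces degenerate after cleanup")
    return mesh


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> Path:
    """Write ``mesh`` to ``path`` as binary (default) or ASCII STL."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "binary":
        data = trimesh.exchange.stl.export_stl(mesh)
        path.write_bytes(data)
    else:
        path.write_text(trimesh.exchange.stl.export_stl_ascii(mesh))
    return path


# ---------------------------------------------------------------------------
# Region selectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxSelector:
    """Oriented box: center (mm), half-extents (mm) along the box axes, and
    a rotation matrix whose rows are the box axes in model coordinates."""

    center: np.ndarray
    half_extents: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        he = _as_vec3(self.half_extents)
        if np.any(he <= 0):
            raise ValueError("half_extents must be positive")
        object.__setattr__(self, "half_extents", he)
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "rotation", R)

    def contains(self, points: np.ndarray) -> np.ndarray:
        local = (np.atleast_2d(points) - self.center) @ self.rotation.T
        return np.all(np.abs(local) <= self.half_extents, axis=1)

    def to_dict(self) -> dict:
        return {"kind": "box", "center": self.center.tolist(),
                "half_extents": self.half_extents.tolist(),
                "rotation": self.rotation.tolist()}


@dataclass(frozen=True)
class SphereSelector:
    """Seed point plus radius (mm)."""

    seed_point: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "seed_point", _as_vec3(self.seed_point))
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.atleast_2d(points) - self.seed_point, axis=1)
        return d <= self.radius

    def to_dict(self) -> dict:
        return {"kind": "sphere", "seed_point": self.seed_point.tolist(),
                "radius": float(self.radius)}


def _selector_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "box":
        return BoxSelector(d["center"], d["half_extents"],
                           d.get("rotation", np.eye(3)))
    if kind == "sphere":
        return SphereSelector(d["seed_point"], d["radius"])
    raise ValueError(f"unknown selector kind: {kind!r}")


@dataclass(frozen=True)
class RegionSpec:
    """Named surface region: a selector volume plus an outward normal hint
    used to orient the fitted plane."""

    name: str
    selector: "BoxSelector | SphereSelector"
    outward_hint: np.ndarray

    def __post_init__(self):
        if self.name not in REGION_NAMES:
            raise ValueError(
                f"region name must be one of {REGION_NAMES}, got {self.name!r}")
        object.__setattr__(self, "outward_hint", _as_vec3(self.outward_hint))

    def to_dict(self) -> dict:
        return {"name": self.name, "selector": self.selector.to_dict(),
                "outward_hint": self.outward_hint.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        return cls(d["name"], _selector_from_dict(d["selector"]),
                   d["outward_hint"])


def select_region(mesh: TriangleMesh, spec: RegionSpec,
                  vertices: np.ndarray | None = None) -> np.ndarray:
    """Vertices of ``mesh`` inside the selector volume, in vertex-index order.

    ``vertices`` may override the mesh's own array (e.g. frame-aligned
    coordinates).  Raises :class:`InsufficientRegionError` if fewer than 3
    vertices match.
    """
    pts = np.asarray(mesh.vertices if vertices is None else vertices,
                     dtype=float)
    mask = spec.selector.contains(pts)
    selected = pts[mask]
    if selected.shape[0] < 3:
        raise InsufficientRegionError(
            f"region {spec.name!r}: selector matched {selected.shape[0]} "
            f"vertices (need >= 3)")
    return selected


# ---------------------------------------------------------------------------
# Scan configuration
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    """Everything needed to evaluate one session of scans: the certified bar
    length, the model reference frame, the six region selectors, and the
    strategy label per scan file."""

    reference_length_mm: float
    regions: dict
    frame: ReferenceFrame = field(default_factory=ReferenceFrame)
    scans: list = field(default_factory=list)  # [{path, scan_id, strategy}]

    def __post_init__(self):
        if self.reference_length_mm <= 0:
            raise ValueError("reference_length_mm must be positive")
        missing = [n for n in REGION_NAMES if n not in self.regions]
        if missing:
            raise ValueError(f"config missing regions: {missing}")

    def to_dict(self) -> dict:
        return {
            "units": "mm",
            "reference_length_mm": float(self.reference_length_mm),
            "frame": {"origin": self.frame.origin.tolist(),
                      "axes": self.frame.axes.tolist()},
            "regions": [self.regions[n].to_dict() for n in REGION_NAMES],
            "scans": list(self.scans),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        regions = {r["name"]: RegionSpec.from_dict(r) for r in d["regions"]}
        fr = d.get("frame", {})
        frame = ReferenceFrame(fr.get("origin", np.zeros(3)),
                               fr.get("axes", np.eye(3)))
        return cls(reference_length_mm=d["reference_length_mm"],
                   regions=regions, frame=frame, scans=d.get("scans", []))

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path) -> "ScanConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)
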