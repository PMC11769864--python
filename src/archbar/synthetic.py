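"""Synthetic scan generator: an arch-plus-reference-bar mesh with known,
injected distortions.

The emulated object is a maxillary arch with a metal bar of certified
length fixed between the second molars.  Only the outer ≤ 20 mm of each bar
end is captured (scanning the full featureless bar would corrupt the
stitching), so the mesh contains two separate bar-end prisms plus an arch
ribbon.  The bar cross-section is a square standing on its corner so the
two upper 45° faces (anterior AP, posterior PP) intersect in the upper bar
edge — the line whose pose the metrology measures.

The distortion model is a rigid transform of the *second* bar end (rotation
about its centroid, then translation) plus isotropic Gaussian vertex noise:
a full-arch scan accumulates stitching error along the arch, and what the
bar metrology can see of that accumulation is exactly the relative rigid
pose error of end 2 with respect to end 1.  Smooth intermediate warps of
the arch are invisible to the measurand and are not modelled.

Model frame: X transversal (bar axis, +X toward quadrant 1), Y
anterior-posterior (arch opens toward +Y), Z vertical.  Units mm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .geometry import Plane, ReferenceFrame, rotation_matrix_xyz
from .mesh_io import (
    REGION_NAMES,
    BoxSelector,
    RegionSpec,
    ScanConfig,
    TriangleMesh,
)
from .metrology import BarMeasurement, ReferenceBar, evaluate_planes

SQ2 = np.sqrt(2.0)

#: The nine scanning strategies: segmentation (Full / Half / Sextant) x
#: movement pattern (Linear / Zig-zag / Combined).
STRATEGY_IDS = tuple(f"{seg}{mov}" for seg, mov in
                     itertools.product("FHS", "LZC"))


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Geometry of the synthetic arch-plus-bar model.

    The bar runs along X, centred on the origin; its outer end faces are
    the vestibular planes VP1 (x = +L/2) and VP2 (x = −L/2), exactly
    ``bar_length_mm`` apart.  ``cross_half_diagonal_mm`` is the half
    diagonal of the diamond cross-section (upper edge at z = +h).
    """

    bar_length_mm: float = 55.066
    cross_half_diagonal_mm: float = 3.0
    captured_end_length_mm: float = 18.0
    arch_radius_mm: float = 27.0
    arch_width_mm: float = 8.0
    arch_height_mm: float = 6.0
    # Real IOS meshes have sub-0.2 mm edge lengths; 0.5 mm keeps plane fits
    # dense enough that fit noise stays well below the injected distortions
    # while the mesh stays small.
    mesh_resolution_mm: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.captured_end_length_mm <= 20):
            raise ValueError("captured_end_length_mm must be in (0, 20]")
        if self.mesh_resolution_mm <= 0:
            raise ValueError("mesh_resolution_mm must be positive")
        if self.cross_half_diagonal_mm <= 0 or self.bar_length_mm <= 0:
            raise ValueError("bar dimensions must be positive")
        min_cells = self.cross_half_diagonal_mm * SQ2
        if self.mesh_resolution_mm > min_cells:
            raise ValueError(
                f"mesh_resolution_mm={self.mesh_resolution_mm} too coarse for "
                f"cross-section edge {min_cells:.2f} mm (needs >= 2x2 vertex "
                f"grid per face)")


@dataclass(frozen=True)
class DistortionParams:
    """Ground-truth distortion of one scan: rigid transform of end 2
    (rotation in degrees about X, Y, Z through the end-2 centroid, then
    translation in µm) plus isotropic Gaussian vertex noise (µm)."""

    end2_translation_um: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    end2_rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vertex_noise_sigma_um: float = 0.0
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.end2_translation_um, dtype=float).reshape(3)
        r = np.asarray(self.end2_rotation_deg, dtype=float).reshape(3)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("distortion parameters must be finite")
        if self.vertex_noise_sigma_um < 0:
            raise ValueError("noise sigma must be >= 0")
        object.__setattr__(self, "end2_translation_um", t)
        object.__setattr__(self, "end2_rotation_deg", r)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return rotation_matrix_xyz(self.end2_rotation_deg)

    @property
    def translation_mm(self) -> np.ndarray:
        return self.end2_translation_um / 1000.0


@dataclass
class GroundTruth:
    """Bookkeeping emitted alongside the reference model."""

    spec: SyntheticModelSpec
    planes: dict                 # name -> exact Plane, model frame
    P1: np.ndarray
    P2: np.ndarray
    end2_vertex_indices: np.ndarray
    end2_centroid: np.ndarray
    vertex_count: int
    face_count: int


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

def _grid_face(corner: np.ndarray, eu: np.ndarray, ev: np.ndarray,
               u, nv: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated planar patch: corner + u*eu + v*ev, with explicit grid
    fractions ``u`` along eu and nv+1 uniform samples along ev."""
    u = np.asarray(u, dtype=float)
    nu = len(u) - 1
    v = np.linspace(0.0, 1.0, nv + 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    verts = (corner[None, :] + uu.reshape(-1, 1) * eu[None, :]
             + vv.reshape(-1, 1) * ev[None, :])
    faces = []
    for i in range(nu):
        for j in range(nv):
            a = i * (nv + 1) + j
            b = a + (nv + 1)
            faces.append((a, b, a + 1))
            faces.append((a + 1, b, b + 1))
    return verts, np.asarray(faces, dtype=np.int64)


#: Width (mm) of the vertex-free guard band on the side faces adjacent to
#: each outer end face, so the end-face region box can be made thick enough
#: to tolerate sub-mm end displacements without catching side vertices.
END_GUARD_MM = 2.0


def _bar_end_prism(x0: float, x1: float, h: float, res: float,
                   outer: str) -> TriangleMesh:
    """Closed prism with diamond cross-section spanning x in [x0, x1].

    Cross-section corners (y, z): (0, +h), (+h, 0), (0, −h), (−h, 0); the
    four side faces are subdivided at ~``res`` mm so plane fits see a dense
    vertex grid.  ``outer`` ("x0" or "x1") marks the outer (vestibular) end,
    whose neighbouring x-interval is widened to ``END_GUARD_MM``.
    """
    length = x1 - x0
    edge = h * SQ2
    guard = min(END_GUARD_MM, length / 3.0)
    nx_body = max(2, int(np.ceil((length - guard) / res)))
    if outer == "x1":
        xs = np.concatenate([np.linspace(x0, x1 - guard, nx_body + 1), [x1]])
    else:
        xs = np.concatenate([[x0], np.linspace(x0 + guard, x1, nx_body + 1)])
    u_frac = (xs - x0) / length
    nt = max(2, int(np.ceil(edge / res)))
    corners = np.array([[0.0, h], [h, 0.0], [0.0, -h], [-h, 0.0]])
    parts = []
    # Side faces: AP (anterior-upper, +y+z), then going around.
    for k in range(4):
        a, b = corners[k], corners[(k + 1) % 4]
        corner = np.array([x0, a[0], a[1]])
        eu = np.array([length, 0.0, 0.0])
        ev = np.array([0.0, b[0] - a[0], b[1] - a[1]])
        parts.append(_grid_face(corner, eu, ev, u_frac, nt))
    # End caps: triangle fans whose rims re-use the side faces' edge
    # subdivision (nt points per diamond edge), keeping the prism watertight.
    rim_yz = np.vstack([
        corners[k] + (corners[(k + 1) % 4] - corners[k]) * (j / nt)
        for k in range(4) for j in range(nt)
    ])
    n_rim = len(rim_yz)
    for x, flip in ((x0, True), (x1, False)):
        ring = np.column_stack([np.full(n_rim, x), rim_yz[:, 0], rim_yz[:, 1]])
        verts = np.vstack([[[x, 0.0, 0.0]], ring])
        faces = np.array([[0, i + 1, (i + 1) % n_rim + 1]
                          for i in range(n_rim)])
        if flip:
            faces = faces[:, ::-1]
        parts.append((verts, faces))
    verts = np.vstack([p[0] for p in parts])
    offs = np.cumsum([0] + [len(p[0]) for p in parts[:-1]])
    faces = np.vstack([p[1] + o for p, o in zip(parts, offs)])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.merge_vertices(digits_vertex=9)
    mesh.update_faces(mesh.nondegenerate_faces())
    return mesh


def _arch_ribbon(spec: SyntheticModelSpec) -> TriangleMesh:
    """Coarse watertight arch ribbon: a rectangular cross-section swept
    along a semicircular arc, placed below the bar so it never enters a
    region selector.  Tooth anatomy is irrelevant to the measurand and
    omitted."""
    r = spec.arch_radius_mm
    w = spec.arch_width_mm / 2.0
    z1 = -spec.cross_half_diagonal_mm - 2.0  # ribbon top, below the bar
    z0 = z1 - spec.arch_height_mm
    theta = np.linspace(np.deg2rad(5.0), np.deg2rad(175.0), 33)
    n = len(theta)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # 4 corners per station, a closed loop around the cross-section.
    radii = np.array([r + w, r + w, r - w, r - w])
    zs = np.array([z0, z1, z1, z0])
    verts = np.column_stack([
        np.outer(cos_t, radii).ravel(),
        np.outer(sin_t, radii).ravel(),
        np.tile(zs, n),
    ])
    faces = []
    for i in range(n - 1):
        for k in range(4):
            a, b = 4 * i + k, 4 * i + (k + 1) % 4
            c, d = a + 4, b + 4
            faces += [(a, c, b), (b, c, d)]
    faces += [(0, 1, 2), (0, 2, 3)]                       # start cap
    base = 4 * (n - 1)
    faces += [(base, base + 2, base + 1), (base, base + 3, base + 2)]
    return trimesh.Trimesh(vertices=verts,
                           faces=np.asarray(faces, dtype=np.int64),
                           process=False)


def _region_specs(spec: SyntheticModelSpec) -> dict:
    """Oriented-box selectors for the six faces, inset from the face borders
    so vertices of adjacent faces are never captured."""
    L2 = spec.bar_length_mm / 2.0
    h = spec.cross_half_diagonal_mm
    cap = spec.captured_end_length_mm
    edge = h * SQ2
    # Tangential inset keeps shared-edge vertices of neighbouring faces out;
    # the perpendicular half-thicknesses bound the end-2 displacement the
    # fixed selectors tolerate (adjacent AP/PP faces meet at 90 deg, so all
    # off-face vertices project tangentially outside the inset box; the VP
    # thickness is limited by the side faces' guard band at the outer end).
    t_in = 0.45
    t_perp_side = 1.2
    t_perp_vp = 0.45 * min(END_GUARD_MM,
                           spec.captured_end_length_mm / 3.0)
    regions = {}
    for quad, x_out, x_in in ((1, L2, L2 - cap), (2, -L2, -L2 + cap)):
        xc = 0.5 * (x_out + x_in)
        half_len = abs(x_out - x_in) / 2.0 - t_in
        for face, n_yz in (("AP", (1.0, 1.0)), ("PP", (-1.0, 1.0))):
            ny, nz = np.array(n_yz) / SQ2
            # Face midpoint: along the unit normal, h/sqrt(2) from the axis.
            center = np.array([xc, ny * h / SQ2, nz * h / SQ2])
            # Box axes: X along the bar, tangential along the face edge,
            # normal out of the face.
            axes = np.array([[1.0, 0.0, 0.0],
                             [0.0, -nz, ny],
                             [0.0, ny, nz]])
            sel = BoxSelector(center,
                              [half_len, edge / 2.0 - t_in, t_perp_side],
                              rotation=axes)
            regions[f"{face}{quad}"] = RegionSpec(
                f"{face}{quad}", sel, [0.0, ny, nz])
        nx = 1.0 if quad == 1 else -1.0
        sel = BoxSelector([x_out, 0.0, 0.0], [t_perp_vp, h - t_in, h - t_in],
                          rotation=np.eye(3))
        regions[f"VP{quad}"] = RegionSpec(f"VP{quad}", sel, [nx, 0.0, 0.0])
    return regions


_CENTROID_CACHE: dict = {}


def _end2_centroid(spec: SyntheticModelSpec) -> np.ndarray:
    """Vertex centroid of the captured end-2 prism — the pivot the mesh
    distortion rotates about.  The cross-section is symmetric (y = z = 0)
    but the guard band makes the x-distribution non-uniform, so the
    centroid is taken from the actual generated vertices (cached)."""
    key = (spec.bar_length_mm, spec.cross_half_diagonal_mm,
           spec.captured_end_length_mm, spec.mesh_resolution_mm)
    if key not in _CENTROID_CACHE:
        L2 = spec.bar_length_mm / 2.0
        prism = _bar_end_prism(-L2, -L2 + spec.captured_end_length_mm,
                               spec.cross_half_diagonal_mm,
                               spec.mesh_resolution_mm, outer="x0")
        _CENTROID_CACHE[key] = np.asarray(prism.vertices).mean(axis=0)
    return _CENTROID_CACHE[key]


def exact_planes(spec: SyntheticModelSpec) -> dict:
    """The six face planes of the undistorted model, analytically."""
    L2 = spec.bar_length_mm / 2.0
    h = spec.cross_half_diagonal_mm
    n_ap = np.array([0.0, 1.0, 1.0]) / SQ2
    n_pp = np.array([0.0, -1.0, 1.0]) / SQ2
    top = np.array([0.0, 0.0, h])
    return {
        "AP1": Plane(top + [L2 - 1, 0, 0], n_ap),
        "PP1": Plane(top + [L2 - 1, 0, 0], n_pp),
        "VP1": Plane([L2, 0.0, 0.0], [1.0, 0.0, 0.0]),
        "AP2": Plane(top + [-L2 + 1, 0, 0], n_ap),
        "PP2": Plane(top + [-L2 + 1, 0, 0], n_pp),
        "VP2": Plane([-L2, 0.0, 0.0], [-1.0, 0.0, 0.0]),
    }


def generate_reference_model(
        spec: SyntheticModelSpec = SyntheticModelSpec()
) -> tuple[TriangleMesh, dict, GroundTruth]:
    """Build the undistorted arch-plus-bar mesh.

    Returns the mesh, the matching region specs, and a ground-truth record
    (exact face planes, ideal edge points, the end-2 vertex index set).
    Construction is fully deterministic.
    """
    L2 = spec.bar_length_mm / 2.0
    h = spec.cross_half_diagonal_mm
    res = spec.mesh_resolution_mm
    arch = _arch_ribbon(spec)
    bar1 = _bar_end_prism(L2 - spec.captured_end_length_mm, L2, h, res,
                          outer="x1")
    bar2 = _bar_end_prism(-L2, -L2 + spec.captured_end_length_mm, h, res,
                          outer="x0")
    n_arch, n_b1 = len(arch.vertices), len(bar1.vertices)
    verts = np.vstack([arch.vertices, bar1.vertices, bar2.vertices])
    faces = np.vstack([arch.faces, bar1.faces + n_arch,
                       bar2.faces + n_arch + n_b1])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    end2_idx = np.arange(n_arch + n_b1, len(verts))
    gt = GroundTruth(
        spec=spec,
        planes=exact_planes(spec),
        P1=np.array([L2, 0.0, h]),
        P2=np.array([-L2, 0.0, h]),
        end2_vertex_indices=end2_idx,
        end2_centroid=verts[end2_idx].mean(axis=0),
        vertex_count=len(verts),
        face_count=len(faces),
    )
    return mesh, _region_specs(spec), gt


def make_scan_config(spec: SyntheticModelSpec = SyntheticModelSpec(),
                     scans: list | None = None) -> ScanConfig:
    """ScanConfig matching the synthetic model (identity frame)."""
    return ScanConfig(reference_length_mm=spec.bar_length_mm,
                      regions=_region_specs(spec),
                      frame=ReferenceFrame(),
                      scans=scans or [])


# ---------------------------------------------------------------------------
# Distortion
# ---------------------------------------------------------------------------

def apply_distortion(mesh: TriangleMesh, end2_vertex_indices,
                     params: DistortionParams) -> TriangleMesh:
    """Distorted copy of ``mesh``: end-2 vertices rotated about their
    centroid then translated, Gaussian noise added to all vertices.
    Deterministic for a fixed ``params.seed``."""
    verts = np.array(mesh.vertices, dtype=float)
    idx = np.asarray(end2_vertex_indices, dtype=int)
    c = verts[idx].mean(axis=0)
    R = params.rotation_matrix
    verts[idx] = (verts[idx] - c) @ R.T + c + params.translation_mm
    if params.vertex_noise_sigma_um > 0:
        rng = np.random.default_rng(params.seed)
        verts += rng.normal(0.0, params.vertex_noise_sigma_um / 1000.0,
                            size=verts.shape)
    return trimesh.Trimesh(vertices=verts, faces=mesh.faces.copy(),
                           process=False)


def propagate_distortion(params: DistortionParams,
                         spec: SyntheticModelSpec = SyntheticModelSpec(),
                         scan_id: str = "", strategy: str = "",
                         end2_centroid: np.ndarray | None = None
                         ) -> BarMeasurement:
    """Closed-form propagation of a rigid end-2 distortion through the
    construction chain, using the exact analytic planes (no meshing, no
    fitting; vertex noise does not enter).  This is both the fast simulation
    path and the independent oracle for mesh-pipeline recovery tests."""
    planes = exact_planes(spec)
    if end2_centroid is None:
        end2_centroid = _end2_centroid(spec)
    R = params.rotation_matrix
    c = np.asarray(end2_centroid, dtype=float)
    t = params.translation_mm + c - R @ c
    for name in ("AP2", "PP2", "VP2"):
        planes[name] = planes[name].transformed(R, t)
    return evaluate_planes(planes, ReferenceBar(spec.bar_length_mm),
                           scan_id=scan_id, strategy=strategy)


# ---------------------------------------------------------------------------
# Strategy profiles and the simulated study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyProfile:
    """Distribution of distortions for one scanning strategy: per-component
    Gaussian location/scale for the end-2 translation (µm) and rotation
    (degrees), plus the vertex noise level (µm)."""

    strategy_id: str
    translation_loc_um: np.ndarray
    translation_scale_um: np.ndarray
    rotation_loc_deg: np.ndarray
    rotation_scale_deg: np.ndarray
    vertex_noise_sigma_um: float = 5.0

    def __post_init__(self):
        for name in ("translation_loc_um", "translation_scale_um",
                     "rotation_loc_deg", "rotation_scale_deg"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if "scale" in name and np.any(v < 0):
                raise ValueError(f"{name} must be >= 0")
            object.__setattr__(self, name, v)

    def draw(self, rng: np.random.Generator) -> DistortionParams:
        return DistortionParams(
            end2_translation_um=rng.normal(self.translation_loc_um,
                                           self.translation_scale_um),
            end2_rotation_deg=rng.normal(self.rotation_loc_deg,
                                         self.rotation_scale_deg),
            vertex_noise_sigma_um=self.vertex_noise_sigma_um,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


#: Relative distortion magnitude per segmentation level and movement
#: pattern.  Linear full-jaw scans performed best in practice and zig-zag
#: worst; sextant segmentation adds stitching seams.  These are simulator
#: configuration values, not measured claims.
_SEG_FACTOR = {"F": 1.0, "H": 1.2, "S": 1.5}
_MOV_FACTOR = {"L": 1.0, "Z": 2.5, "C": 1.3}

#: Baseline systematic pose error of end 2 (µm): the bar reads short along
#: X and sags in Z, of the order seen in full-arch scans.
_BASE_T_LOC = np.array([65.0, -35.0, -120.0])
_BASE_T_SCALE = np.array([60.0, 60.0, 75.0])
_BASE_R_SCALE = np.array([0.06, 0.12, 0.15])  # degrees about X, Y, Z


def default_profiles(vertex_noise_sigma_um: float = 5.0
                     ) -> dict[str, StrategyProfile]:
    """The nine default strategy profiles (F/H/S x L/Z/C)."""
    profiles = {}
    for sid in STRATEGY_IDS:
        f = _SEG_FACTOR[sid[0]] * _MOV_FACTOR[sid[1]]
        profiles[sid] = StrategyProfile(
            strategy_id=sid,
            translation_loc_um=_BASE_T_LOC,
            translation_scale_um=_BASE_T_SCALE * f,
            rotation_loc_deg=np.zeros(3),
            rotation_scale_deg=_BASE_R_SCALE * f,
            vertex_noise_sigma_um=vertex_noise_sigma_um,
        )
    return profiles


def null_profiles(vertex_noise_sigma_um: float = 5.0
                  ) -> dict[str, StrategyProfile]:
    """Nine identically-distributed profiles (null configuration)."""
    base = default_profiles(vertex_noise_sigma_um)["FL"]
    return {sid: replace(base, strategy_id=sid) for sid in STRATEGY_IDS}


def simulate_strategy_study(profiles: dict[str, StrategyProfile] | None = None,
                            n_per_group: int = 25, seed: int = 0,
                            spec: SyntheticModelSpec = SyntheticModelSpec(),
                            fast: bool = True) -> list[BarMeasurement]:
    """Simulate the full study: ``n_per_group`` scans per strategy.

    ``fast=True`` propagates each drawn distortion through the exact planes
    (no meshes); ``fast=False`` builds the reference mesh once, distorts it
    per scan and runs the full mesh pipeline.  Reproducible from ``seed``.
    """
    if profiles is None:
        profiles = default_profiles()
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ids = [p.strategy_id for p in profiles.values()]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strategy ids in profiles")
    rng = np.random.default_rng(seed)
    records: list[BarMeasurement] = []
    if fast:
        for sid, prof in profiles.items():
            for i in range(n_per_group):
                params = prof.draw(rng)
                records.append(propagate_distortion(
                    params, spec, scan_id=f"{sid}-{i + 1:03d}", strategy=sid))
        return records
    from .metrology import analyze_scan
    mesh, _, gt = generate_reference_model(spec)
    config = make_scan_config(spec)
    for sid, prof in profiles.items():
        for i in range(n_per_group):
            params = prof.draw(rng)
            distorted = apply_distortion(mesh, gt.end2_vertex_indices, params)
            records.append(analyze_scan(distorted, config,
                                        scan_id=f"{sid}-{i + 1:03d}",
                                        strategy=sid))
    return records
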