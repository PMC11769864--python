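"""Per-scan bar metrology: from six fitted planes to the vectorial error
V_E, the length deviation ΔL, and the angular deviations.

The measurand is the relative pose of the two captured ends of a cross-arch
reference bar of certified length L (default 55.066 mm).  Per end
(quadrant q ∈ {1, 2}) three planes are fitted — anterior APq, posterior PPq
and vestibular (outer end face) VPq.  The chain is:

* V1 = AP1 ∩ PP1 and V2 = AP2 ∩ PP2 — the upper-edge lines of the bar ends;
* P1 = V1 ∩ VP1 and P2 = V2 ∩ VP2 — the measured edge points;
* VP2′ = VP2 parallel-shifted by L toward quadrant 1, and P2′ = V2 ∩ VP2′ —
  where the end-1 edge point *should* sit if the scan were perfect;
* V_E = P1 − P2′ (reported per axis in µm) and ΔL = ‖P2 − P1‖ − L (µm);
* α_overall = angle(V1, V2); α_coronal and α_axial are the same arccos
  formula applied to the (X, Y) and (X, Z) components respectively.

In a distortion-free scan P2′ coincides with P1, so every deviation is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    Line3,
    Plane,
    fit_plane,
    intersect_line_plane,
    intersect_planes,
    translate_plane,
)
from .mesh_io import ScanConfig, TriangleMesh, select_region

MM_TO_UM = 1000.0


class UndefinedProjectionError(ValueError):
    """A projected angle is undefined because a direction projects to ~0."""


@dataclass(frozen=True)
class ReferenceBar:
    """The CMM-certified reference length of the metal bar."""

    length_mm: float = 55.066

    def __post_init__(self):
        if not (self.length_mm > 0 and math.isfinite(self.length_mm)):
            raise ValueError("bar length must be positive and finite")


@dataclass(frozen=True)
class BarEndPlanes:
    """The three fitted planes of one bar end (quadrant 1 or 2)."""

    AP: Plane
    PP: Plane
    VP: Plane
    quadrant: int = 1


@dataclass
class BarMeasurement:
    """Complete per-scan result record."""

    scan_id: str
    strategy: str
    V1: Line3
    V2: Line3
    P1: np.ndarray
    P2: np.ndarray
    P2prime: np.ndarray
    VE: np.ndarray          # (x, y, z) in µm
    VE_norm: float          # µm
    deltaL: float           # µm
    alpha_overall: float    # degrees
    alpha_coronal: float    # degrees
    alpha_axial: float      # degrees

    #: CSV column order for result tables.
    CSV_COLUMNS = ("scan_id", "strategy", "deltaL_um", "VE_um", "VE_x_um",
                   "VE_y_um", "VE_z_um", "alpha_overall_deg",
                   "alpha_coronal_deg", "alpha_axial_deg")

    def to_row(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "strategy": self.strategy,
            "deltaL_um": self.deltaL,
            "VE_um": self.VE_norm,
            "VE_x_um": self.VE[0],
            "VE_y_um": self.VE[1],
            "VE_z_um": self.VE[2],
            "alpha_overall_deg": self.alpha_overall,
            "alpha_coronal_deg": self.alpha_coronal,
            "alpha_axial_deg": self.alpha_axial,
        }


# ---------------------------------------------------------------------------
# Constructions
# ---------------------------------------------------------------------------

def construct_end_geometry(planes: BarEndPlanes) -> tuple[Line3, np.ndarray]:
    """Edge line V = AP ∩ PP and edge point P = V ∩ VP for one bar end."""
    try:
        line = intersect_planes(planes.AP, planes.PP)
        point = intersect_line_plane(line, planes.VP)
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(
            f"quadrant {planes.quadrant}: {exc}") from exc
    return line, point


def construct_P2prime(V2: Line3, VP2: Plane, bar: ReferenceBar,
                      shift_direction) -> np.ndarray:
    """P2′: intersection of V2 with VP2 parallel-shifted by the reference
    length toward the first quadrant."""
    shifted = translate_plane(VP2, shift_direction, bar.length_mm)
    return intersect_line_plane(V2, shifted)


def compute_vector_error(P1, P2prime) -> tuple[np.ndarray, float]:
    """Componentwise vectorial error V_E = P1 − P2′, in µm, plus its
    Euclidean norm."""
    ve = (np.asarray(P1, dtype=float) - np.asarray(P2prime, dtype=float)) \
        * MM_TO_UM
    return ve, float(np.linalg.norm(ve))


def compute_deltaL(P1, P2, bar: ReferenceBar) -> float:
    """Length deviation ΔL = ‖P2 − P1‖ − L, in µm."""
    dist = float(np.linalg.norm(np.asarray(P2, float) - np.asarray(P1, float)))
    return (dist - bar.length_mm) * MM_TO_UM


def _direction(v) -> np.ndarray:
    if isinstance(v, Line3):
        return v.direction
    return np.asarray(v, dtype=float).reshape(3)


def _arccos_angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise UndefinedProjectionError(
            "projected direction has (near-)zero length; angle undefined")
    c = float(a @ b) / (na * nb)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def angle_overall(V1, V2) -> float:
    """Full 3D angle between the two edge directions, degrees in [0, 180]."""
    return _arccos_angle(_direction(V1), _direction(V2))


def angle_coronal(V1, V2) -> float:
    """Angle between the (X, Y) components of the edge directions."""
    return _arccos_angle(_direction(V1)[[0, 1]], _direction(V2)[[0, 1]])


def angle_axial(V1, V2) -> float:
    """Angle between the (X, Z) components of the edge directions."""
    return _arccos_angle(_direction(V1)[[0, 2]], _direction(V2)[[0, 2]])


# ---------------------------------------------------------------------------
# Whole-scan evaluation
# ---------------------------------------------------------------------------

def evaluate_planes(planes: dict, bar: ReferenceBar, scan_id: str = "",
                    strategy: str = "") -> BarMeasurement:
    """Run the full construction chain on six named planes
    (AP1, PP1, VP1, AP2, PP2, VP2) already expressed in the model frame."""
    end1 = BarEndPlanes(planes["AP1"], planes["PP1"], planes["VP1"], 1)
    end2 = BarEndPlanes(planes["AP2"], planes["PP2"], planes["VP2"], 2)
    V1, P1 = construct_end_geometry(end1)
    V2, P2 = construct_end_geometry(end2)
    # Shift VP2 toward the first quadrant: along +/-X with the sign of the
    # end-2 -> end-1 displacement.
    sign = 1.0 if (P1 - P2)[0] >= 0 else -1.0
    shift_dir = np.array([sign, 0.0, 0.0])
    bar = bar if isinstance(bar, ReferenceBar) else ReferenceBar(float(bar))
    P2prime = construct_P2prime(V2, end2.VP, bar, shift_dir)
    VE, VE_norm = compute_vector_error(P1, P2prime)
    return BarMeasurement(
        scan_id=scan_id, strategy=strategy, V1=V1, V2=V2,
        P1=P1, P2=P2, P2prime=P2prime, VE=VE, VE_norm=VE_norm,
        deltaL=compute_deltaL(P1, P2, bar),
        alpha_overall=angle_overall(V1, V2),
        alpha_coronal=angle_coronal(V1, V2),
        alpha_axial=angle_axial(V1, V2),
    )


def analyze_scan(mesh: TriangleMesh, config: ScanConfig, scan_id: str = "",
                 strategy: str = "") -> BarMeasurement:
    """Evaluate one scan mesh against the configuration.

    The mesh is first expressed in the configured reference frame (X along
    the bar toward quadrant 1, Y anterior-posterior, Z vertical); the six
    regions are then selected and fitted, and the construction chain run.
    Geometry errors are re-raised annotated with ``scan_id``.
    """
    verts = config.frame.to_local(np.asarray(mesh.vertices, dtype=float))
    try:
        planes = {
            name: fit_plane(select_region(mesh, spec, vertices=verts),
                            outward_hint=spec.outward_hint)
            for name, spec in config.regions.items()
        }
        return evaluate_planes(planes, ReferenceBar(config.reference_length_mm),
                               scan_id=scan_id, strategy=strategy)
    except (DegenerateGeometryError, ValueError) as exc:
        raise type(exc)(f"scan {scan_id!r}: {exc}") from exc
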