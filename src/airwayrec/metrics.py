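"""Quantification of the reconstructed airway.

Cross-sectional area profile along an axis (default station step 0.2 mm),
the minimal-section site (the narrowest point of the airway, the quantity
of clinical interest for nasal resistance), and the enclosed volume — the
latter with two independent estimators (divergence-theorem mesh volume and
trapezoidal integration of the area profile) for cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely.geometry as sgeom
import trimesh as _trimesh

from .geometry import InvalidInputError
from .reconstruction import TriMesh

__all__ = [
    "AreaProfile",
    "section_contours",
    "area_profile",
    "min_area_site",
    "mesh_volume",
    "profile_volume",
    "write_profile",
]

DEFAULT_STEP = 0.2  # mm between neighbouring section stations


def _as_trimesh(mesh) -> _trimesh.Trimesh:
    if isinstance(mesh, TriMesh):
        return mesh.to_trimesh()
    if isinstance(mesh, _trimesh.Trimesh):
        return mesh
    raise InvalidInputError("expected a TriMesh or trimesh.Trimesh")


@dataclass
class AreaProfile:
    """Sectional lumen area vs. position along an axis.

    ``areas`` sums all lumen components crossed at each station;
    ``per_component`` optionally splits them by connected mesh component.
    """

    axis: np.ndarray
    positions: np.ndarray  # mm along axis, uniform step
    areas: np.ndarray  # mm^2
    per_component: np.ndarray | None = None  # (n_stations, n_components)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, float)
        self.positions = np.asarray(self.positions, float)
        self.areas = np.asarray(self.areas, float)
        if len(self.positions) != len(self.areas):
            raise InvalidInputError("positions/areas length mismatch")
        if len(self.positions) > 1:
            steps = np.diff(self.positions)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-9:
                raise InvalidInputError("positions must increase uniformly")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0]) if len(self.positions) > 1 else 0.0


def _plane_frame(normal: np.ndarray, origin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def section_contours(mesh, plane_origin, plane_normal) -> list[np.ndarray]:
    """Closed planar polylines (world mm, (N, 3) arrays) of the mesh-plane
    intersection, one per lumen component crossed."""
    tm = _as_trimesh(mesh)
    if not tm.is_watertight:
        raise InvalidInputError("section_contours requires a watertight mesh")
    sec = tm.section(plane_origin=np.asarray(plane_origin, float),
                     plane_normal=np.asarray(plane_normal, float))
    if sec is None:
        return []
    out = []
    for poly in sec.discrete:
        p = np.asarray(poly, float)
        if len(p) >= 4 and np.linalg.norm(p[0] - p[-1]) < 1e-9:
            out.append(p[:-1])
        elif len(p) >= 3:
            out.append(p)
    return out


def _loop_area(loop3d: np.ndarray, normal: np.ndarray) -> float:
    u, v = _plane_frame(normal, loop3d[0])
    x = loop3d @ u
    y = loop3d @ v
    return float(abs(sgeom.Polygon(np.stack([x, y], axis=1)).area))


def area_profile(
    mesh,
    axis=(0.0, 1.0, 0.0),
    step: float = DEFAULT_STEP,
    per_component: bool = True,
) -> AreaProfile:
    """Section areas at uniform stations spanning the mesh extent along
    ``axis`` (default 0.2 mm steps).  With ``per_component`` the profile is
    additionally split by connected mesh component (e.g. left/right nasal
    cavity); per-component areas sum exactly to the total."""
    if step <= 0:
        raise InvalidInputError("step must be > 0")
    tm = _as_trimesh(mesh)
    if not tm.is_watertight:
        raise InvalidInputError("area_profile requires a watertight mesh")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    proj = tm.vertices @ axis
    lo, hi = proj.min(), proj.max()
    n = max(int(math.floor((hi - lo) / step)) + 1, 1)
    positions = lo + step * np.arange(n)
    comps = tm.split(only_watertight=True) if per_component else [tm]
    if per_component and not comps:
        comps = [tm]
    per = np.zeros((n, len(comps)))
    for ci, comp in enumerate(comps):
        base = comp.vertices.mean(axis=0)
        for k, pos in enumerate(positions):
            origin = base + (pos - base @ axis) * axis
            try:
                loops = section_contours(comp, origin, axis)
            except InvalidInputError:
                loops = []
            per[k, ci] = sum(_loop_area(l, axis) for l in loops)
    total = per.sum(axis=1)
    return AreaProfile(axis, positions, total, per if per_component else None)


def min_area_site(p: AreaProfile, exclude_ends: float = 2.0) -> tuple[float, float]:
    """Station of minimal total area, excluding ``exclude_ends`` mm at both
    ends (so end caps cannot masquerade as the narrowest section).  Ties
    break toward the smallest position."""
    lo = p.positions[0] + exclude_ends
    hi = p.positions[-1] - exclude_ends
    sel = (p.positions >= lo) & (p.positions <= hi)
    if not np.any(sel):
        raise InvalidInputError("profile empty after excluding ends")
    pos = p.positions[sel]
    areas = p.areas[sel]
    i = int(np.argmin(areas))  # argmin returns the first minimum: tie-break
    return float(pos[i]), float(areas[i])


def mesh_volume(mesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem: sum of signed
    tetrahedra spanned by each face and the origin; origin invariant for a
    closed, consistently wound surface.  The absolute value is returned."""
    tm = _as_trimesh(mesh)
    if not tm.is_watertight:
        raise InvalidInputError("mesh_volume requires a watertight mesh")
    v = tm.vertices
    f = tm.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    signed = np.einsum("ij,ij->i", np.cross(a, b), c).sum() / 6.0
    return abs(float(signed))


def profile_volume(p: AreaProfile) -> float:
    """Trapezoidal integral of the area profile — the slab-wise volume
    estimator cross-checked against :func:`mesh_volume`."""
    if len(p.positions) < 2:
        raise InvalidInputError("profile too short to integrate")
    return float(np.trapezoid(p.areas, p.positions))


def write_profile(p: AreaProfile, path) -> None:
    """Tab-separated profile table: position_mm, total_area_mm2, then one
    column per component."""
    cols = [p.positions, p.areas]
    header = "position_mm\ttotal_area_mm2"
    if p.per_component is not None:
        for i in range(p.per_component.shape[1]):
            cols.append(p.per_component[:, i])
            header += f"\tcomponent_{i}_mm2"
    np.savetxt(path, np.column_stack(cols), delimiter="\t", header=header, comments="")
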