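"""Coordinate frames and planar contour geometry shared by all pipeline stages.

World coordinates follow the DICOM LPS convention (x: left, y: posterior,
z: superior), in millimetres.  A :class:`PlaneFrame` maps 2-D in-plane
millimetre coordinates of one slice stack to 3-D world coordinates; the
pixel (0, 0) centre sits at the frame origin (half-voxel convention, matching
DICOM ``ImagePositionPatient``).

Contours are stored in-plane (2-D mm) together with a frame reference so
that registration corrections remain strictly planar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "PlaneFrame",
    "Contour",
    "ContourSet",
    "standard_frame",
    "plane_to_world",
    "world_to_plane",
    "polygon_area",
    "signed_polygon_area",
    "curvature_profile",
    "resample_contour",
    "arc_lengths",
    "point_at_arclength",
]

ORIENTATIONS = ("axial", "coronal", "sagittal")


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its contract."""


@dataclass(frozen=True)
class PlaneFrame:
    """Geometry of one slice stack.

    ``axis_u``/``axis_v`` are the in-plane unit directions of the first and
    second contour coordinate; ``normal = axis_u x axis_v`` (right handed).
    Slice centres are spaced ``slice_thickness + slice_gap`` apart along the
    normal.
    """

    orientation: str
    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 2.5
    slice_gap: float = 0.5
    matrix: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        for name in ("origin", "axis_u", "axis_v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        u, v = self.axis_u, self.axis_v
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9:
            raise InvalidInputError("axis_u and axis_v must be unit vectors")
        if abs(float(u @ v)) > 1e-9:
            raise InvalidInputError("axis_u and axis_v must be orthogonal")
        if self.orientation not in ORIENTATIONS:
            raise InvalidInputError(f"unknown orientation {self.orientation!r}")
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0 or self.slice_gap < 0:
            raise InvalidInputError("pixel_spacing/slice_thickness must be > 0, gap >= 0")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axis_u, self.axis_v)

    @property
    def slice_spacing(self) -> float:
        """Centre-to-centre slice spacing (mm)."""
        return self.slice_thickness + self.slice_gap

    def slice_origin(self, slice_index: float) -> np.ndarray:
        return self.origin + slice_index * self.slice_spacing * self.normal

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "origin": self.origin.tolist(),
            "axis_u": self.axis_u.tolist(),
            "axis_v": self.axis_v.tolist(),
            "pixel_spacing": list(self.pixel_spacing),
            "slice_thickness": self.slice_thickness,
            "slice_gap": self.slice_gap,
            "matrix": list(self.matrix),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneFrame":
        return cls(
            orientation=d["orientation"],
            origin=np.asarray(d["origin"], float),
            axis_u=np.asarray(d["axis_u"], float),
            axis_v=np.asarray(d["axis_v"], float),
            pixel_spacing=tuple(d["pixel_spacing"]),
            slice_thickness=float(d["slice_thickness"]),
            slice_gap=float(d["slice_gap"]),
            matrix=tuple(int(m) for m in d["matrix"]),
        )


#: canonical LPS in-plane axes per orientation: (axis_u, axis_v)
_STANDARD_AXES = {
    # axial slice: u -> left, v -> posterior; normal +z (superior)
    "axial": ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
    # coronal slice: u -> left, v -> inferior; normal +y (posterior),
    # so increasing slice index runs anterior -> posterior
    "coronal": ((1.0, 0.0, 0.0), (0.0, 0.0, -1.0)),
    # sagittal slice: u -> posterior, v -> superior; normal +x (left)
    "sagittal": ((0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
}


def standard_frame(
    orientation: str,
    *,
    center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    fov: float = 240.0,
    matrix: tuple[int, int] = (512, 512),
    slice_thickness: float = 2.5,
    slice_gap: float = 0.5,
    n_slices: int = 1,
) -> PlaneFrame:
    """Build a stack frame centred on ``center`` with the canonical LPS axes.

    The stack of ``n_slices`` slices is placed symmetrically about ``center``
    along the normal, emulating a centred acquisition.
    """
    if orientation not in _STANDARD_AXES:
        raise InvalidInputError(f"unknown orientation {orientation!r}")
    u, v = (np.asarray(a) for a in _STANDARD_AXES[orientation])
    n = np.cross(u, v)
    rows, cols = matrix
    su, sv = fov / cols, fov / rows
    spacing = slice_thickness + slice_gap
    center = np.asarray(center, float)
    origin = (
        center
        - u * (cols - 1) / 2.0 * su
        - v * (rows - 1) / 2.0 * sv
        - n * (n_slices - 1) / 2.0 * spacing
    )
    return PlaneFrame(
        orientation=orientation,
        origin=origin,
        axis_u=u,
        axis_v=v,
        pixel_spacing=(su, sv),
        slice_thickness=slice_thickness,
        slice_gap=slice_gap,
        matrix=matrix,
    )


def plane_to_world(p, frame: PlaneFrame, slice_index: float) -> np.ndarray:
    """Map in-plane mm point(s) ``p`` (shape (2,) or (N, 2)) to world mm."""
    p = np.asarray(p, float)
    base = frame.slice_origin(slice_index)
    return base + np.multiply.outer(p[..., 0], frame.axis_u) + np.multiply.outer(
        p[..., 1], frame.axis_v
    )


def world_to_plane(w, frame: PlaneFrame) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`plane_to_world`.

    Returns ``(p, s)`` with ``p`` the in-plane mm coordinates (shape (..., 2))
    and ``s`` the continuous slice coordinate along the stack normal.
    """
    w = np.asarray(w, float)
    d = w - frame.origin
    pu = d @ frame.axis_u
    pv = d @ frame.axis_v
    s = (d @ frame.normal) / frame.slice_spacing
    return np.stack([pu, pv], axis=-1), s


def signed_polygon_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise order."""
    p = np.asarray(points, float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Ordered boundary loop (or open polyline) on one slice, in-plane mm.

    Closed contours are normalised to counter-clockwise orientation in
    (u, v) and must have at least 3 distinct points; consecutive duplicate
    points are dropped at construction.
    """

    points: np.ndarray
    slice_index: int
    frame: PlaneFrame
    closed: bool = True
    label: str | None = None
    region_id: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(pts) > 1:
            keep = np.ones(len(pts), bool)
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
            pts = pts[keep]
        if self.closed:
            if len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= 1e-12:
                pts = pts[:-1]
            if len(pts) < 3:
                raise InvalidInputError("closed contour needs >= 3 distinct points")
            if signed_polygon_area(pts) < 0:
                pts = pts[::-1].copy()
        elif len(pts) < 2:
            raise InvalidInputError("open contour needs >= 2 distinct points")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def world_points(self) -> np.ndarray:
        """Contour vertices in 3-D world mm coordinates, shape (N, 3)."""
        return plane_to_world(self.points, self.frame, self.slice_index)

    def with_points(self, points: np.ndarray) -> "Contour":
        return replace(self, points=np.asarray(points, float))

    @property
    def perimeter(self) -> float:
        return float(arc_lengths(self.points, self.closed)[-1])

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ContourSet:
    """All contours of one orientation, keyed by slice index."""

    orientation: str
    frame: PlaneFrame
    contours: dict[int, list[Contour]] = field(default_factory=dict)
    registered: bool = False

    def __post_init__(self) -> None:
        if self.orientation != self.frame.orientation:
            raise InvalidInputError("set orientation must match its frame")

    def add(self, contour: Contour) -> None:
        if contour.frame.orientation != self.orientation:
            raise InvalidInputError("contour orientation mismatch")
        self.contours.setdefault(contour.slice_index, []).append(contour)

    def slice_indices(self) -> list[int]:
        return sorted(self.contours)

    def slice_position(self, slice_index: int) -> float:
        """World position of a slice centre along the stack normal (mm)."""
        return float(self.frame.slice_origin(slice_index) @ self.frame.normal)

    def __iter__(self) -> Iterator[Contour]:
        for idx in self.slice_indices():
            yield from self.contours[idx]

    def n_contours(self) -> int:
        return sum(len(v) for v in self.contours.values())

    def map_contours(self, fn) -> "ContourSet":
        out = ContourSet(self.orientation, self.frame, registered=self.registered)
        for c in self:
            out.add(fn(c))
        return out


def polygon_area(c: Contour | np.ndarray) -> float:
    """Enclosed area (mm^2) of a closed contour; orientation independent."""
    if isinstance(c, Contour):
        if not c.closed:
            raise InvalidInputError("polygon_area requires a closed contour")
        pts = c.points
    else:
        pts = np.asarray(c, float)
    return abs(signed_polygon_area(pts))


def arc_lengths(points: np.ndarray, closed: bool) -> np.ndarray:
    """Cumulative arc length at each vertex; for closed loops the array has
    one extra entry for the closing edge (total perimeter)."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if closed:
        seg = np.append(seg, np.linalg.norm(pts[0] - pts[-1]))
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at_arclength(c: Contour, s: np.ndarray) -> np.ndarray:
    """Interpolate point(s) on the contour polyline at arc length(s) ``s``."""
    cum = arc_lengths(c.points, c.closed)
    total = cum[-1]
    pts = c.points
    if c.closed:
        pts = np.vstack([pts, pts[:1]])
        s = np.mod(s, total)
    else:
        s = np.clip(s, 0.0, total)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.stack([np.atleast_1d(x), np.atleast_1d(y)], axis=-1)


def curvature_profile(c: Contour, window: int = 5) -> np.ndarray:
    """Discrete signed curvature (1/mm) at each contour vertex.

    Uses the circumscribed circle through three points spaced ``window // 2``
    samples apart (Menger curvature), which is robust to pixel-level
    jaggedness.  Positive where the boundary is convex with respect to the
    counter-clockwise orientation.
    """
    pts = c.points
    n = len(pts)
    if n < 5:
        raise InvalidInputError("curvature_profile needs >= 5 points")
    h = max(1, window // 2)
    if c.closed:
        a = np.roll(pts, h, axis=0)
        b = pts
        d = np.roll(pts, -h, axis=0)
    else:
        idx = np.arange(n)
        ia = np.clip(idx - h, 0, n - 1)
        id_ = np.clip(idx + h, 0, n - 1)
        a, b, d = pts[ia], pts, pts[id_]
    ab = b - a
    bd = d - b
    ad = d - a
    cross = ab[:, 0] * bd[:, 1] - ab[:, 1] * bd[:, 0]
    den = (
        np.linalg.norm(ab, axis=1)
        * np.linalg.norm(bd, axis=1)
        * np.linalg.norm(ad, axis=1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(den > 1e-15, 2.0 * cross / np.maximum(den, 1e-300), 0.0)
    return kappa


def resample_contour(c: Contour, n: int) -> Contour:
    """Resample to ``n`` points uniformly spaced by arc length.

    The first output point coincides with the original start point.  Closed
    contours are sampled at spacing ``perimeter / n`` (no duplicated seam
    point); open polylines span the full length inclusively.
    """
    if n < (3 if c.closed else 2):
        raise InvalidInputError("resample_contour needs n >= 3 (closed) or 2 (open)")
    total = c.perimeter
    if c.closed:
        s = np.arange(n) * total / n
    else:
        s = np.linspace(0.0, total, n)
    pts = point_at_arclength(c, s)
    return replace(c, points=pts)
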