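"""Cross-plane contour registration via shared crossing points.

Head motion between the three stack acquisitions leaves the segmented
boundaries of different orientations mutually inconsistent: where an axial
boundary pierces a coronal slice plane it should meet the coronal boundary,
but generally misses it by up to a few millimetres.  Registration restores
consistency purely on the contour coordinates:

* *target points* — crossing points of the fixed (coronal) boundaries with
  the moving contour's slice plane;
* *matched points* — crossing points of the moving (axial/sagittal)
  boundary with the fixed stack's slice planes;
* each boundary piece between two adjacent matched points is translated,
  rotated and linearly stretched (an in-plane similarity) so its endpoints
  land exactly on the two corresponding target points.

A per-slice rigid displacement of the axial stack relative to the sagittal
one is estimated first (in-plane head motion), and the posterior border of
the nasal septum — where the two nasal passages merge into the nasopharynx
— is localised from the coronal region-count transition and refined with
axial/sagittal boundary points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import (
    Contour,
    ContourSet,
    InvalidInputError,
    PlaneFrame,
    arc_lengths,
    point_at_arclength,
    signed_polygon_area,
    world_to_plane,
)

__all__ = [
    "Correspondence",
    "SegmentTransform",
    "RegistrationError",
    "InsufficientConstraintsError",
    "InvalidOrderingError",
    "SeptumNotFoundError",
    "crossing_points",
    "match_crossings",
    "segment_similarity_transform",
    "piecewise_register_contour",
    "stack_displacement",
    "locate_septum_interval",
    "refine_nasopharynx_wall",
    "register_all",
    "crossing_rms",
]

log = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 4.0  # mm; one coronal slice spacing


class RegistrationError(RuntimeError):
    pass


class InsufficientConstraintsError(RegistrationError):
    pass


class InvalidOrderingError(RegistrationError):
    pass


class SeptumNotFoundError(RegistrationError):
    pass


@dataclass
class Correspondence:
    """A matched (target, moving) crossing-point pair."""

    target: np.ndarray  # 3-D mm, on the fixed boundary, in the moving plane
    matched: np.ndarray  # 3-D mm, on the moving boundary
    distance: float
    arclen: float  # arc-length position of the matched point on its contour

    def __post_init__(self):
        self.target = np.asarray(self.target, float)
        self.matched = np.asarray(self.matched, float)


@dataclass(frozen=True)
class SegmentTransform:
    """In-plane similarity (rotation + uniform scale + translation) applied
    to one boundary piece; maps its two endpoints exactly onto the two
    target points."""

    rotation: float  # radians
    scale: float
    translation: np.ndarray  # (2,)
    span: tuple[float, float] = (0.0, 0.0)  # arc-length span on the contour

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        R = np.array([[c, -s], [s, c]]) * self.scale
        return pts @ R.T + self.translation


def crossing_points(
    c: Contour, cutting_frame: PlaneFrame, cutting_slice: int
) -> tuple[np.ndarray, np.ndarray]:
    """All transversal intersections of the contour polyline (in world
    coordinates) with the given slice plane.

    Returns ``(points, arclens)`` with points of shape (M, 3) and the
    corresponding arc-length positions on the contour.  A vertex lying
    exactly on the plane belongs to its succeeding edge, so it is counted
    once.
    """
    w = c.world_points()
    p0 = cutting_frame.slice_origin(cutting_slice)
    n = cutting_frame.normal
    d = (w - p0) @ n
    if c.closed:
        d2 = np.append(d, d[0])
        w2 = np.vstack([w, w[:1]])
    else:
        d2, w2 = d, w
    pos = d2 >= 0.0  # a vertex on the plane counts with the + side
    flip = pos[:-1] != pos[1:]
    # a vertex exactly on the plane belongs to its succeeding edge: if edge
    # i ends on the plane and edge i+1 also flips, edge i+1 claims the
    # vertex (otherwise a tangential touch would be counted twice)
    n_edges = len(flip)
    for i in np.nonzero(flip)[0]:
        if d2[i + 1] == 0.0:
            j = (i + 1) % n_edges if c.closed else i + 1
            if j < n_edges and flip[j]:
                flip[i] = False
    idx = np.nonzero(flip)[0]
    if len(idx) == 0:
        return np.empty((0, 3)), np.empty(0)
    t = d2[idx] / (d2[idx] - d2[idx + 1])
    pts = w2[idx] + t[:, None] * (w2[idx + 1] - w2[idx])
    cum = arc_lengths(c.points, c.closed)
    seg = np.diff(cum)
    arclens = cum[idx] + t * seg[idx]
    return pts, arclens


def match_crossings(
    targets: np.ndarray, candidates: np.ndarray, max_dist: float = DEFAULT_MAX_DIST
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """One-to-one matching of target and candidate points minimising the
    total matched distance (Hungarian assignment), keeping only pairs
    closer than ``max_dist``.

    Returns ``(pairs, unmatched_targets, unmatched_candidates)`` where each
    pair is ``(target_index, candidate_index, distance)``.
    """
    if max_dist <= 0:
        raise InvalidInputError("max_dist must be > 0")
    T = np.asarray(targets, float).reshape(-1, 3)
    C = np.asarray(candidates, float).reshape(-1, 3)
    if len(T) == 0 or len(C) == 0:
        return [], list(range(len(T))), list(range(len(C)))
    dist = np.linalg.norm(T[:, None, :] - C[None, :, :], axis=2)
    # forbid pairs beyond the gate but keep the matrix feasible
    big = max_dist * 1e6 + dist.max()
    cost = np.where(dist <= max_dist, dist, big)
    ri, ci = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(ri, ci)
        if dist[i, j] <= max_dist
    ]
    mt = {i for i, _, _ in pairs}
    mc = {j for _, j, _ in pairs}
    return (
        pairs,
        [i for i in range(len(T)) if i not in mt],
        [j for j in range(len(C)) if j not in mc],
    )


def segment_similarity_transform(p0, p1, q0, q1) -> SegmentTransform:
    """The unique orientation-preserving in-plane similarity with
    T(p0) = q0 and T(p1) = q1."""
    p0 = complex(*np.asarray(p0, float))
    p1 = complex(*np.asarray(p1, float))
    q0 = complex(*np.asarray(q0, float))
    q1 = complex(*np.asarray(q1, float))
    if abs(p1 - p0) < 1e-12:
        raise InvalidInputError("degenerate segment: p0 == p1")
    alpha = (q1 - q0) / (p1 - p0)
    beta = q0 - alpha * p0
    return SegmentTransform(
        rotation=math.atan2(alpha.imag, alpha.real),
        scale=abs(alpha),
        translation=np.array([beta.real, beta.imag]),
    )


def _target_in_plane(corr: Correspondence, frame: PlaneFrame) -> np.ndarray:
    p, _ = world_to_plane(corr.target, frame)
    return p


def piecewise_register_contour(
    moving: Contour, corrs: list[Correspondence]
) -> Contour:
    """Correct a moving contour piecewise so it passes exactly through all
    target crossing points.

    Each arc between adjacent matched points is mapped by the similarity
    taking its endpoints to the corresponding targets; adjacent arcs share
    their endpoint image, so the corrected contour is continuous, stays in
    its plane, and contains every target point.
    """
    if len(corrs) < 2:
        raise InsufficientConstraintsError(
            f"need >= 2 correspondences, got {len(corrs)}"
        )
    corrs = sorted(corrs, key=lambda c: c.arclen)
    s = np.array([c.arclen for c in corrs])
    if np.any(np.diff(s) < 1e-12):
        raise InvalidOrderingError("coincident matched points")
    frame = moving.frame
    q = np.array([_target_in_plane(c, frame) for c in corrs])
    m = np.vstack([point_at_arclength(moving, np.array([si]))[0] for si in s])
    if len(corrs) >= 3 and moving.closed:
        # order-inversion check: targets must wind the same way as the
        # matched points along the contour
        if signed_polygon_area(q) * signed_polygon_area(m) < 0:
            raise InvalidOrderingError("correspondences invert contour order")
    cum = arc_lengths(moving.points, moving.closed)[: len(moving.points)]
    pts = moving.points
    K = len(corrs)
    new_pts: list[np.ndarray] = []
    if moving.closed:
        for k in range(K):
            k2 = (k + 1) % K
            T = segment_similarity_transform(m[k], m[k2], q[k], q[k2])
            if k2 == 0:  # wrap-around arc: tail vertices then head vertices
                tail = pts[cum > s[k] + 1e-12]
                head = pts[cum < s[0] - 1e-12]
                interior = np.vstack([tail, head]) if len(tail) or len(head) else np.empty((0, 2))
            else:
                mask = (cum > s[k] + 1e-12) & (cum < s[k2] - 1e-12)
                interior = pts[mask]
            new_pts.append(q[k][None, :])
            if len(interior):
                new_pts.append(T.apply(interior))
        out = np.vstack(new_pts)
        # keep the original start point first (pure re-indexing)
        i0 = int(np.argmin(np.linalg.norm(out - moving.points[0], axis=1)))
        out = np.roll(out, -i0, axis=0)
        return replace(moving, points=out)
    # open polyline: head and tail arcs extend the first/last transform
    transforms = [
        segment_similarity_transform(m[k], m[k + 1], q[k], q[k + 1])
        for k in range(K - 1)
    ]
    head = pts[cum < s[0] - 1e-12]
    if len(head):
        new_pts.append(transforms[0].apply(head))
    for k in range(K - 1):
        new_pts.append(q[k][None, :])
        mask = (cum > s[k] + 1e-12) & (cum < s[k + 1] - 1e-12)
        if mask.any():
            new_pts.append(transforms[k].apply(pts[mask]))
    new_pts.append(q[-1][None, :])
    tail = pts[cum > s[-1] + 1e-12]
    if len(tail):
        new_pts.append(transforms[-1].apply(tail))
    return replace(moving, points=np.vstack(new_pts))


def _set_crossings_with_plane(
    cs: ContourSet, frame: PlaneFrame, slice_index: int
) -> np.ndarray:
    """Crossing points of every contour of ``cs`` with one slice plane of
    another stack (world mm)."""
    pts = []
    for c in cs:
        p, _ = crossing_points(c, frame, slice_index)
        if len(p):
            pts.append(p)
    return np.vstack(pts) if pts else np.empty((0, 3))


def stack_displacement(
    axial: ContourSet,
    sagittal: ContourSet,
    max_dist: float = DEFAULT_MAX_DIST,
) -> dict[int, np.ndarray]:
    """Per-axial-slice in-plane offset (mm) evaluated from the gap between
    the axial boundary and the sagittal boundary.

    For each axial slice the crossing points of its contours with every
    sagittal plane are matched to the crossing points of the sagittal
    contours with that axial plane; the offset is the mean matched
    difference projected in-plane (the least-squares in-plane translation).
    Slices without intersections get an offset linearly interpolated from
    their neighbours.
    """
    fr_a = axial.frame
    offsets: dict[int, np.ndarray] = {}
    measured: dict[int, np.ndarray] = {}
    sag_slices = sagittal.slice_indices()
    for ia in axial.slice_indices():
        cand, targ = [], []
        for c in axial.contours[ia]:
            for js in sag_slices:
                p, _ = crossing_points(c, sagittal.frame, js)
                if len(p):
                    cand.append(p)
        for js in sag_slices:
            for c in sagittal.contours[js]:
                p, _ = crossing_points(c, fr_a, ia)
                if len(p):
                    targ.append(p)
        if not cand or not targ:
            continue
        C = np.vstack(cand)
        T = np.vstack(targ)
        pairs, _, _ = match_crossings(T, C, max_dist)
        if not pairs:
            continue
        diff = np.array([T[i] - C[j] for i, j, _ in pairs])
        du = float(np.mean(diff @ fr_a.axis_u))
        dv = float(np.mean(diff @ fr_a.axis_v))
        measured[ia] = np.array([du, dv])
    if not measured:
        raise RegistrationError("no intersecting axial/sagittal slice pairs")
    keys = sorted(measured)
    vals = np.array([measured[k] for k in keys])
    for ia in axial.slice_indices():
        if ia in measured:
            offsets[ia] = measured[ia]
        else:
            offsets[ia] = np.array(
                [np.interp(ia, keys, vals[:, 0]), np.interp(ia, keys, vals[:, 1])]
            )
    return offsets


def locate_septum_interval(coronal: ContourSet) -> tuple[int, int]:
    """First adjacent coronal slice pair (positional indices, anterior ->
    posterior) where the airway component count changes from two to one and
    stays one; the posterior border of the nasal septum lies strictly
    between these slices."""
    slices = coronal.slice_indices()
    counts = [len(coronal.contours[i]) for i in slices]
    for k in range(len(counts) - 1):
        if counts[k] == 2 and counts[k + 1] == 1 and all(c == 1 for c in counts[k + 1 :]):
            return (k, k + 1)
    raise SeptumNotFoundError(f"no persistent 2->1 transition in counts {counts}")


def refine_nasopharynx_wall(
    coronal: ContourSet,
    axial: ContourSet,
    sagittal: ContourSet,
    interval: tuple[int, int],
    facing_threshold: float = 0.7,
) -> np.ndarray:
    """Anterior nasopharynx wall trace from axial and sagittal boundaries.

    Collects boundary vertices of the registered axial/sagittal contours
    that fall between the two coronal slices bracketing the septum's
    posterior border and whose outward normal faces anterior — the wall
    where the merged lumen begins.  Returned ordered inferior -> superior,
    for use as a lofting guide.
    """
    slices = coronal.slice_indices()
    ka, kb = interval
    nrm = coronal.frame.normal  # anterior -> posterior
    ya = coronal.slice_position(slices[ka])
    yb = coronal.slice_position(slices[kb])
    picked = []
    for cs in (axial, sagittal):
        for c in cs:
            if not c.closed:
                continue
            w = c.world_points()
            y = w @ nrm
            # outward vertex normals of the CCW in-plane polygon
            p = c.points
            t = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
            t /= np.maximum(np.linalg.norm(t, axis=1)[:, None], 1e-12)
            n2 = np.stack([t[:, 1], -t[:, 0]], axis=1)  # outward for CCW
            n3 = n2[:, :1] * c.frame.axis_u + n2[:, 1:] * c.frame.axis_v
            facing = (n3 @ nrm) < -facing_threshold
            sel = (y > ya) & (y < yb) & facing
            if sel.any():
                picked.append(w[sel])
    if not picked:
        log.warning(
            "no axial/sagittal boundary points inside the septum interval; "
            "falling back to the interval midpoint"
        )
        mid = 0.5 * (ya + yb)
        ref = coronal.contours[slices[kb]][0]
        cen = ref.world_points().mean(axis=0)
        fallback = cen + (mid - cen @ nrm) * nrm
        return fallback[None, :]
    pts = np.vstack(picked)
    order = np.argsort(pts[:, 2], kind="stable")  # inferior -> superior
    return pts[order]


def _register_set_to_reference(
    moving: ContourSet,
    reference: ContourSet,
    max_dist: float,
) -> ContourSet:
    out = ContourSet(moving.orientation, moving.frame, registered=True)
    ref_slices = reference.slice_indices()
    for ims in moving.slice_indices():
        targets = []
        for jr in ref_slices:
            for rc in reference.contours[jr]:
                p, _ = crossing_points(rc, moving.frame, ims)
                if len(p):
                    targets.append(p)
        T = np.vstack(targets) if targets else np.empty((0, 3))
        # candidates across all contours of this moving slice
        cand_pts, cand_meta = [], []
        for ci, c in enumerate(moving.contours[ims]):
            for jr in ref_slices:
                p, al = crossing_points(c, reference.frame, jr)
                for pt, a in zip(p, al):
                    cand_pts.append(pt)
                    cand_meta.append((ci, a))
        C = np.vstack(cand_pts) if cand_pts else np.empty((0, 3))
        pairs, _, _ = match_crossings(T, C, max_dist) if len(T) and len(C) else ([], [], [])
        per_contour: dict[int, list[Correspondence]] = {}
        for i, j, d in pairs:
            ci, a = cand_meta[j]
            per_contour.setdefault(ci, []).append(
                Correspondence(T[i], C[j], d, a)
            )
        for ci, c in enumerate(moving.contours[ims]):
            corrs = per_contour.get(ci, [])
            if len(corrs) < 2:
                log.warning(
                    "%s slice %d region %d: %d correspondence(s); passed "
                    "through unregistered",
                    moving.orientation,
                    ims,
                    c.region_id,
                    len(corrs),
                )
                out.add(replace(c))
                continue
            try:
                out.add(piecewise_register_contour(c, corrs))
            except RegistrationError as exc:
                log.warning(
                    "%s slice %d region %d: %s; passed through",
                    moving.orientation,
                    ims,
                    c.region_id,
                    exc,
                )
                out.add(replace(c))
    return out


def register_all(
    coronal: ContourSet,
    axial: ContourSet,
    sagittal: ContourSet,
    max_dist: float = DEFAULT_MAX_DIST,
    displacement_correction: bool = True,
) -> tuple[ContourSet, ContourSet, ContourSet]:
    """Unify the three contour sets into one frame.

    Pipeline order: (1) per-slice displacement correction of the axial
    stack against the sagittal boundaries; (2) piecewise registration of
    axial contours onto coronal targets; (3) piecewise registration of
    sagittal contours onto the coronal reference.  The coronal set is the
    fixed reference and is returned unmodified.
    """
    ax = axial
    if displacement_correction:
        try:
            offs = stack_displacement(axial, sagittal, max_dist)
            ax = ContourSet(axial.orientation, axial.frame, registered=axial.registered)
            for c in axial:
                ax.add(replace(c, points=c.points + offs[c.slice_index]))
        except RegistrationError as exc:
            log.warning("displacement correction skipped: %s", exc)
    ax_reg = _register_set_to_reference(ax, coronal, max_dist)
    sa_reg = _register_set_to_reference(sagittal, coronal, max_dist)
    return coronal, ax_reg, sa_reg


def crossing_rms(
    moving: ContourSet, reference: ContourSet, max_dist: float = DEFAULT_MAX_DIST
) -> float:
    """RMS distance between matched crossing points of a moving set and the
    reference set (the residual the registration minimises)."""
    d2, n = 0.0, 0
    for ims in moving.slice_indices():
        targets, cands = [], []
        for jr in reference.slice_indices():
            for rc in reference.contours[jr]:
                p, _ = crossing_points(rc, moving.frame, ims)
                if len(p):
                    targets.append(p)
        for c in moving.contours[ims]:
            for jr in reference.slice_indices():
                p, _ = crossing_points(c, reference.frame, jr)
                if len(p):
                    cands.append(p)
        if not targets or not cands:
            continue
        T, C = np.vstack(targets), np.vstack(cands)
        pairs, _, _ = match_crossings(T, C, max_dist)
        for _, _, d in pairs:
            d2 += d * d
            n += 1
    if n == 0:
        raise RegistrationError("no matched crossing points")
    return math.sqrt(d2 / n)
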