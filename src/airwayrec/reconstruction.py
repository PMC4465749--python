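"""From registered contours to a smooth 3-D airway surface.

Stages: (1) curvature landmarks ("characteristic points") per contour;
(2) partition of each coronal contour into anatomical arcs (the study
splits the nasal boundary into inferior / middle / superior turbinate
parts), propagated slice to slice; (3) anatomically consistent resampling
so sample j on one slice corresponds to sample j on the next; (4) NURBS
section-curve interpolation and surface lofting (optionally constrained by
guide traces such as the anterior nasopharynx wall); (5) tessellation to a
watertight triangle mesh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .geometry import (
    Contour,
    ContourSet,
    InvalidInputError,
    arc_lengths,
    curvature_profile,
    point_at_arclength,
    plane_to_world,
)
from .nurbs import (  # noqa: F401  (re-exported: the reconstruction surface API)
    NurbsCurve,
    NurbsSurface,
    evaluate_surface,
    interpolate_curves_common_knots,
    interpolate_nurbs_curve,
    loft_surface,
)

__all__ = [
    "TriMesh",
    "characteristic_points",
    "partition_by_landmarks",
    "correspond_across_slices",
    "align_sample_grid",
    "contour_chains",
    "tessellate",
    "reconstruct_stack",
    "NurbsCurve",
    "NurbsSurface",
    "interpolate_nurbs_curve",
    "loft_surface",
    "evaluate_surface",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# landmarks and partitioning


def characteristic_points(
    c: Contour,
    min_prominence: float = 0.05,
    min_abs_curvature: float = 0.05,
    window_mm: float = 2.0,
) -> list[int]:
    """Indices of curvature landmarks: local extrema of the signed
    curvature with prominence >= ``min_prominence`` (1/mm) and
    |curvature| >= ``min_abs_curvature``, non-maximum-suppressed within a
    ``window_mm`` arc-length window.  Ordered along the contour; may be
    empty (a circle has no landmarks)."""
    kappa = curvature_profile(c)
    n = len(kappa)
    cum = arc_lengths(c.points, c.closed)[:n]
    cands: list[tuple[int, float]] = []
    for sign in (1.0, -1.0):
        sig = sign * kappa
        if c.closed:
            ext = np.concatenate([sig, sig, sig])
            peaks, props = find_peaks(ext, prominence=min_prominence)
            sel = [(p - n, props["prominences"][k]) for k, p in enumerate(peaks)
                   if n <= p < 2 * n]
        else:
            peaks, props = find_peaks(sig, prominence=min_prominence)
            sel = list(zip(peaks, props["prominences"]))
        for i, prom in sel:
            if abs(kappa[int(i)]) >= min_abs_curvature:
                cands.append((int(i), float(prom)))
    # non-maximum suppression within the arc-length window, strongest first
    cands.sort(key=lambda t: -t[1])
    total = c.perimeter
    kept: list[int] = []
    for i, _ in cands:
        ok = True
        for j in kept:
            d = abs(cum[i] - cum[j])
            if c.closed:
                d = min(d, total - d)
            if d < window_mm:
                ok = False
                break
        if ok:
            kept.append(i)
    return sorted(kept)


@dataclass
class PartitionedContourSet:
    """A contour set whose contours carry labelled arc partitions."""

    base: ContourSet
    #: per (slice_index, position-in-slice): arc-length cut positions (sorted)
    cuts: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)


def partition_by_landmarks(
    cset: ContourSet,
    n_parts: int,
    seed_labels: dict | None = None,
    reference_slice: int | None = None,
    **landmark_kw,
) -> PartitionedContourSet:
    """Split every contour into ``n_parts`` labelled arcs at landmark
    positions, propagating cut positions from a reference slice.

    ``seed_labels``: {"labels": [names...], "cut_points": (n_parts, 2) mm
    positions on the reference contour}.  On each subsequent slice the cut
    moves to the landmark nearest (in-plane) to the previous slice's cut;
    contours with fewer than ``n_parts`` landmarks fall back to an equal
    arc-length split anchored at the previous cuts (logged).
    """
    slices = cset.slice_indices()
    if not slices:
        raise InvalidInputError("empty contour set")
    labels = (
        list(seed_labels["labels"])
        if seed_labels and "labels" in seed_labels
        else [f"part_{i}" for i in range(n_parts)]
    )
    if len(labels) != n_parts:
        raise InvalidInputError("need one label per part")
    ref = reference_slice if reference_slice is not None else slices[0]
    out = PartitionedContourSet(cset, labels=labels)
    # propagate forward from the reference, then backward for earlier slices
    forward = slices[slices.index(ref) :]
    backward = slices[: slices.index(ref)][::-1]
    for sweep in (forward, backward):
        prev: np.ndarray | None = None
        for k in sweep:
            for pos, c in enumerate(cset.contours[k]):
                if prev is None and seed_labels and "cut_points" in seed_labels:
                    target = np.asarray(seed_labels["cut_points"], float)
                elif prev is None:
                    # default: equal arc-length anchored at the start point
                    s = np.arange(n_parts) * c.perimeter / n_parts
                    target = point_at_arclength(c, s)
                else:
                    target = prev
                cum = arc_lengths(c.points, c.closed)[: len(c.points)]
                lm = characteristic_points(c, **landmark_kw)
                if len(lm) >= n_parts:
                    lm_pts = c.points[lm]
                    cuts = []
                    used: set[int] = set()
                    for t in target:
                        d = np.linalg.norm(lm_pts - t, axis=1)
                        for i in np.argsort(d):
                            if i not in used:
                                used.add(int(i))
                                cuts.append(cum[lm[int(i)]])
                                break
                    cuts = np.sort(np.array(cuts))
                else:
                    log.warning(
                        "slice %d region %d: %d landmark(s) < %d parts; "
                        "equal arc-length fallback",
                        k,
                        c.region_id,
                        len(lm),
                        n_parts,
                    )
                    s0 = 0.0
                    if prev is not None:
                        # anchor at the arc position nearest the first
                        # previous cut to keep continuity
                        d = np.linalg.norm(c.points - target[0], axis=1)
                        s0 = cum[int(np.argmin(d))]
                    cuts = np.sort(
                        np.mod(s0 + np.arange(n_parts) * c.perimeter / n_parts,
                               c.perimeter)
                    )
                out.cuts[(k, pos)] = cuts
                prev = point_at_arclength(c, cuts)
    return out


def correspond_across_slices(
    pset: PartitionedContourSet, n_samples: int = 120
) -> np.ndarray:
    """Resample every partitioned contour so that sample j on slice i
    corresponds anatomically (same part, same relative arc position) to
    sample j on slice i+1.

    Samples are divided among the parts proportionally to the parts' mean
    arc length (largest-remainder rounding; every slice gets exactly
    ``n_samples``).  Returns a (n_slices, n_samples, 3) world-mm grid for
    the first contour of each slice.
    """
    cset = pset.base
    slices = cset.slice_indices()
    n_parts = len(pset.labels)
    # mean arc length per part
    lengths = np.zeros(n_parts)
    count = 0
    for k in slices:
        c = cset.contours[k][0]
        cuts = pset.cuts[(k, 0)]
        arcs = np.diff(np.append(cuts, cuts[0] + c.perimeter))
        lengths += arcs
        count += 1
    lengths /= max(count, 1)
    frac = lengths / lengths.sum()
    alloc = np.floor(frac * n_samples).astype(int)
    rem = n_samples - alloc.sum()
    for i in np.argsort(-(frac * n_samples - alloc))[:rem]:
        alloc[i] += 1
    alloc = np.maximum(alloc, 1)
    while alloc.sum() > n_samples:
        alloc[np.argmax(alloc)] -= 1
    grid = np.empty((len(slices), n_samples, 3))
    for si, k in enumerate(slices):
        c = cset.contours[k][0]
        cuts = pset.cuts[(k, 0)]
        rows = []
        for p in range(n_parts):
            s0 = cuts[p]
            s1 = cuts[(p + 1) % n_parts]
            if p == n_parts - 1:
                s1 = cuts[0] + c.perimeter
            ss = s0 + (s1 - s0) * np.arange(alloc[p]) / alloc[p]
            rows.append(point_at_arclength(c, np.mod(ss, c.perimeter)))
        pts2 = np.vstack(rows)
        grid[si] = plane_to_world(pts2, c.frame, c.slice_index)
    return grid


# ---------------------------------------------------------------------------
# smooth stacks without landmarks: start-point alignment


def align_sample_grid(chain: list[Contour], n_samples: int = 120) -> np.ndarray:
    """Resample a chain of closed contours into an (n_slices, n_samples, 3)
    grid, rotating each slice's start sample to minimise the summed
    distance to the previous slice's samples (prevents twist in the loft)."""
    rows = []
    prev = None
    for c in chain:
        cum = np.arange(n_samples) * c.perimeter / n_samples
        pts2 = point_at_arclength(c, cum)
        w = plane_to_world(pts2, c.frame, c.slice_index)
        if prev is not None:
            # try all cyclic shifts (and both directions are unnecessary:
            # orientation is normalised CCW in-plane)
            best, best_d = 0, np.inf
            for sh in range(n_samples):
                d = np.sum(np.linalg.norm(np.roll(w, -sh, axis=0) - prev, axis=1))
                if d < best_d:
                    best, best_d = sh, d
            w = np.roll(w, -best, axis=0)
        rows.append(w)
        prev = w
    return np.stack(rows)


def contour_chains(cset: ContourSet) -> list[list[Contour]]:
    """Group contours into chains across slices by centroid continuity
    (greedy nearest-centroid tracking).  Each chain is one lumen component
    followed through the stack."""
    slices = cset.slice_indices()
    chains: list[list[Contour]] = []
    open_chains: list[list[Contour]] = []
    for k in slices:
        cs = list(cset.contours[k])
        used = [False] * len(cs)
        next_open: list[list[Contour]] = []
        for ch in open_chains:
            prev_c = ch[-1]
            pw = prev_c.world_points().mean(axis=0)
            best, bd = -1, np.inf
            for i, c in enumerate(cs):
                if used[i]:
                    continue
                d = np.linalg.norm(c.world_points().mean(axis=0) - pw)
                if d < bd:
                    best, bd = i, d
            if best >= 0 and bd < 3.0 * cset.frame.slice_spacing:
                ch.append(cs[best])
                used[best] = True
                next_open.append(ch)
            else:
                chains.append(ch)
        for i, c in enumerate(cs):
            if not used[i]:
                next_open.append([c])
        open_chains = next_open
    chains.extend(open_chains)
    return chains


# ---------------------------------------------------------------------------
# tessellation


@dataclass
class TriMesh:
    """Indexed triangle mesh (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


def tessellate(
    s: NurbsSurface, nu: int = 128, nv: int = 64, cap_ends: bool = True
) -> TriMesh:
    """Triangulate the surface on a regular parameter grid.

    Closed-u seams are stitched (the duplicate seam column is dropped);
    with ``cap_ends`` planar triangle fans close the two end sections so
    the mesh is watertight.
    """
    if nu < 2 or nv < 2:
        raise InvalidInputError("nu and nv must be >= 2")
    (ulo, uhi), (vlo, vhi) = s.domain
    if s.closed_u:
        us = ulo + (uhi - ulo) * np.arange(nu) / nu  # seam column once
    else:
        us = np.linspace(ulo, uhi, nu)
    vs = np.linspace(vlo, vhi, nv)
    G = s.evaluate_grid(us, vs)  # (nu, nv, 3)
    verts = G.transpose(1, 0, 2).reshape(-1, 3)  # ring-major: v rows of nu

    def vid(i_v: int, i_u: int) -> int:
        return i_v * nu + (i_u % nu if s.closed_u else i_u)

    faces = []
    n_u_quads = nu if s.closed_u else nu - 1
    for iv in range(nv - 1):
        for iu in range(n_u_quads):
            a = vid(iv, iu)
            b = vid(iv, iu + 1)
            c = vid(iv + 1, iu + 1)
            d = vid(iv + 1, iu)
            faces.append((a, b, c))
            faces.append((a, c, d))
    verts_list = [verts]
    if cap_ends and s.closed_u:
        for iv, flip in ((0, True), (nv - 1, False)):
            ring = G[:, iv, :]
            centre = ring.mean(axis=0)
            ci = len(np.vstack(verts_list))
            verts_list.append(centre[None, :])
            for iu in range(nu):
                a = vid(iv, iu)
                b = vid(iv, iu + 1)
                # start cap faces -v (outward), end cap +v
                tri = (a, ci, b) if flip else (a, b, ci)
                faces.append(tri)
    V = np.vstack(verts_list)
    F = np.array(faces, int)
    if cap_ends and s.closed_u:
        # normalise to outward winding (positive enclosed volume)
        a, b, c = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
        if np.einsum("ij,ij->i", np.cross(a, b), c).sum() < 0:
            F = F[:, ::-1]
    return TriMesh(V, F)


# ---------------------------------------------------------------------------
# high-level driver


def reconstruct_stack(
    chain: list[Contour],
    n_samples: int = 120,
    degree_u: int = 3,
    degree_v: int = 3,
    guides: np.ndarray | None = None,
    guide_direction: np.ndarray | None = None,
    extend_ends: float | tuple[float, float] | None = None,
    partition: PartitionedContourSet | None = None,
) -> NurbsSurface:
    """Loft one lumen component from its contour chain.

    Each section represents a slab of one slice spacing, so by default the
    loft is extended by half a slice spacing beyond the terminal sections
    (constant cross-section), making slab-wise volume integration
    consistent.  ``extend_ends`` may be a scalar, a (start, end) pair, or 0
    to loft strictly between slice centres.
    """
    if len(chain) < 2:
        raise InvalidInputError("need >= 2 contours to loft")
    if partition is not None:
        grid = correspond_across_slices(partition, n_samples)
    else:
        grid = align_sample_grid(chain, n_samples)
    if extend_ends is None:
        extend_ends = chain[0].frame.slice_spacing / 2.0
    e0, e1 = (
        extend_ends if isinstance(extend_ends, tuple) else (extend_ends, extend_ends)
    )
    nrm = chain[0].frame.normal
    if e0 > 1e-9:
        grid = np.concatenate([(grid[0] - e0 * nrm)[None], grid], axis=0)
    if e1 > 1e-9:
        grid = np.concatenate([grid, (grid[-1] + e1 * nrm)[None]], axis=0)
    curves = interpolate_curves_common_knots(grid, degree_u, closed=True)
    nrm = chain[0].frame.normal
    return loft_surface(
        curves,
        degree_v=degree_v,
        guides=guides,
        guide_axis=nrm,
        guide_direction=guide_direction,
    )
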