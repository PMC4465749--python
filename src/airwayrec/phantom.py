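"""Analytic airway phantoms and simulated orthogonal-stack MRI acquisition.

The generator stands in for a head-and-neck scan: an analytic solid with a
known (closed-form or high-resolution) volume and cross-sectional area
profile is sampled into three orthogonal slice stacks with the acquisition
geometry of a T2 upper-airway protocol — 512x512 matrix, 2.5 mm slice
thickness, 0.5 mm inter-slice gap for the axial and sagittal stacks and
1.5 mm gap for the coronal stack — including partial-volume slab averaging,
Rician magnitude noise, and optional per-stack rigid head motion.

Phantom axes: every solid has a long axis along world +y (anterior ->
posterior), the direction a coronal stack sections, matching the lofting
direction used for the nasal cavity.  The ``bichannel`` phantom emulates the
two nasal passages merging into a single nasopharyngeal lumen at a known
merge plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import (
    Contour,
    ContourSet,
    InvalidInputError,
    PlaneFrame,
    polygon_area,
    standard_frame,
)

__all__ = [
    "PhantomSpec",
    "CylinderSpec",
    "EllipticalTubeSpec",
    "HourglassSpec",
    "BichannelSpec",
    "AcquisitionSpec",
    "RigidMotion",
    "ImageStack",
    "indicator",
    "ground_truth",
    "voxelize",
    "apply_motion",
    "add_noise",
    "analytic_contours",
    "paper_protocol",
    "acquire",
]


# ---------------------------------------------------------------------------
# phantom solids


@dataclass(frozen=True)
class PhantomSpec:
    """Base class: an analytic solid of axial extent ``length`` centred at
    ``center`` with its long axis along +y."""

    length: float = 60.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_lumen: float = 0.05
    intensity_background: float = 0.80

    kind = "abstract"

    def _local(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) - np.asarray(self.center, float)

    @property
    def y_extent(self) -> tuple[float, float]:
        cy = self.center[1]
        return (cy - self.length / 2.0, cy + self.length / 2.0)

    # subclasses implement cross-section membership at local (x, z) given
    # local axial coordinate s in [-L/2, L/2]
    def _inside_local(self, x, s, z):  # pragma: no cover - abstract
        raise NotImplementedError

    def cross_section_area(self, y: float) -> float:
        """Closed-form lumen area (mm^2) of the section at world y."""
        raise NotImplementedError

    def volume(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class CylinderSpec(PhantomSpec):
    radius: float = 10.0
    kind = "cylinder"

    def _inside_local(self, x, s, z):
        in_len = np.abs(s) <= self.length / 2.0
        return in_len & (x * x + z * z <= self.radius**2)

    def cross_section_area(self, y: float) -> float:
        lo, hi = self.y_extent
        return math.pi * self.radius**2 if lo <= y <= hi else 0.0

    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class EllipticalTubeSpec(PhantomSpec):
    """Tube with elliptical cross section: semi-axis ``a`` along x, ``b``
    along z.  Volume pi*a*b*L."""

    a: float = 8.0
    b: float = 5.0
    kind = "elliptical_tube"

    def _inside_local(self, x, s, z):
        in_len = np.abs(s) <= self.length / 2.0
        return in_len & ((x / self.a) ** 2 + (z / self.b) ** 2 <= 1.0)

    def cross_section_area(self, y: float) -> float:
        lo, hi = self.y_extent
        return math.pi * self.a * self.b if lo <= y <= hi else 0.0

    def volume(self) -> float:
        return math.pi * self.a * self.b * self.length


@dataclass(frozen=True)
class HourglassSpec(PhantomSpec):
    """Solid of revolution with radius r(t) = r0 - amp*sin(pi*t/L), where t
    runs from 0 at the anterior end to L at the posterior end, so the waist
    (radius r0 - amp) sits at mid-length."""

    r0: float = 6.0
    amp: float = 3.0
    kind = "hourglass"

    def _radius_at(self, s):
        t = np.asarray(s) + self.length / 2.0
        return self.r0 - self.amp * np.sin(math.pi * t / self.length)

    def _inside_local(self, x, s, z):
        in_len = np.abs(s) <= self.length / 2.0
        r = self._radius_at(s)
        return in_len & (x * x + z * z <= r * r)

    def cross_section_area(self, y: float) -> float:
        lo, hi = self.y_extent
        if not (lo <= y <= hi):
            return 0.0
        r = float(self._radius_at(y - self.center[1]))
        return math.pi * r * r

    def volume(self) -> float:
        # pi * integral r(t)^2 dt has a closed form:
        # r^2 = r0^2 - 2 r0 a sin(pi t/L) + a^2 sin^2(pi t/L)
        L, r0, a = self.length, self.r0, self.amp
        return math.pi * (r0**2 * L - 2 * r0 * a * (2 * L / math.pi) + a**2 * L / 2)


@dataclass(frozen=True)
class BichannelSpec(PhantomSpec):
    """Two parallel channels merging into one lumen — nasal cavities joining
    the nasopharynx.

    Anterior of the merge plane (local s < merge_s) the lumen is two
    elliptic channels of semi-axes (rx, rz) centred at x = +-separation;
    posterior of it the lumen is the stadium-like hull of the two channels
    (rectangle 2*separation x 2*rz with two half-ellipse caps).  The merge
    plane y* = center_y + merge_s marks the posterior border of the septum.
    """

    rx: float = 4.0
    rz: float = 6.0
    separation: float = 7.0
    merge_s: float = 10.0
    kind = "bichannel"

    def __post_init__(self):
        if self.separation <= self.rx:
            raise InvalidInputError("channels must not overlap (separation > rx)")
        if not (-self.length / 2 < self.merge_s < self.length / 2):
            raise InvalidInputError("merge position must lie inside the solid")

    @property
    def merge_y(self) -> float:
        return self.center[1] + self.merge_s

    def _inside_local(self, x, s, z):
        x = np.asarray(x, float)
        s = np.asarray(s, float)
        z = np.asarray(z, float)
        in_len = np.abs(s) <= self.length / 2.0
        two = (((np.abs(x) - self.separation) / self.rx) ** 2 + (z / self.rz) ** 2) <= 1.0
        xc = np.clip(x, -self.separation, self.separation)
        one = (((x - xc) / self.rx) ** 2 + (z / self.rz) ** 2) <= 1.0
        return in_len & np.where(s < self.merge_s, two, one)

    def channel_area(self) -> float:
        return math.pi * self.rx * self.rz

    def merged_area(self) -> float:
        return math.pi * self.rx * self.rz + 4.0 * self.separation * self.rz

    def cross_section_area(self, y: float) -> float:
        lo, hi = self.y_extent
        if not (lo <= y <= hi):
            return 0.0
        return 2 * self.channel_area() if y < self.merge_y else self.merged_area()

    def volume(self) -> float:
        lo, hi = self.y_extent
        la = self.merge_y - lo
        lp = hi - self.merge_y
        return 2 * self.channel_area() * la + self.merged_area() * lp


def indicator(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """1 where world point(s) lie inside the lumen, else 0 (vectorised)."""
    p = spec._local(np.asarray(pts, float))
    return spec._inside_local(p[..., 0], p[..., 1], p[..., 2]).astype(np.uint8)


def ground_truth(spec: PhantomSpec):
    """Return ``(volume_mm3, area_fn)`` with ``area_fn(y)`` the lumen
    cross-sectional area at world position y along the long axis."""
    return spec.volume(), np.vectorize(spec.cross_section_area)


# ---------------------------------------------------------------------------
# acquisition


@dataclass(frozen=True)
class RigidMotion:
    """Rigid head motion applied to the subject before one stack is acquired.

    ``rotation_deg`` is a rotation about ``axis`` through ``pivot``;
    ``translation`` is a world-mm offset.  The acquisition samples the moved
    object, i.e. voxel intensities are evaluated at the inverse-transformed
    sample points.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        ax = np.asarray(self.axis, float)
        ax = ax / np.linalg.norm(ax)
        K = np.array(
            [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
        )
        return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        R = self.matrix()
        piv = np.asarray(self.pivot, float)
        return (np.asarray(pts, float) - piv) @ R.T + piv + np.asarray(self.translation)

    def inverse_apply(self, pts: np.ndarray) -> np.ndarray:
        R = self.matrix()
        piv = np.asarray(self.pivot, float)
        return (np.asarray(pts, float) - np.asarray(self.translation) - piv) @ R + piv

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and not any(self.translation)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and degradation parameters of one simulated stack."""

    orientation: str
    fov: float = 240.0
    matrix: tuple[int, int] = (512, 512)
    slice_thickness: float = 2.5
    slice_gap: float = 0.5
    n_slices: int = 16
    stack_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    motion: RigidMotion | None = None
    rng_seed: int = 0

    def frame(self) -> PlaneFrame:
        return standard_frame(
            self.orientation,
            center=self.stack_center,
            fov=self.fov,
            matrix=self.matrix,
            slice_thickness=self.slice_thickness,
            slice_gap=self.slice_gap,
            n_slices=self.n_slices,
        )


def paper_protocol(
    orientation: str,
    *,
    extent: float = 64.0,
    stack_center=(0.0, 0.0, 0.0),
    matrix=(512, 512),
    **kw,
) -> AcquisitionSpec:
    """Acquisition parameters of the study protocol for one orientation.

    Axial: FOV 220 mm, 2.5 mm thickness, 0.5 mm gap (3 mm spacing).
    Sagittal: FOV 280 mm, 2.5/0.5 (3 mm spacing).
    Coronal: FOV 240 mm, 2.5 mm thickness, 1.5 mm gap (4 mm spacing).
    All stacks 512x512.  ``extent`` is the stack coverage along its normal;
    the number of slices is the largest odd count fitting symmetric centres.
    """
    fov = {"axial": 220.0, "sagittal": 280.0, "coronal": 240.0}[orientation]
    gap = 1.5 if orientation == "coronal" else 0.5
    spacing = 2.5 + gap
    n = int(math.floor(extent / spacing)) // 2 * 2 + 1
    return AcquisitionSpec(
        orientation=orientation,
        fov=fov,
        matrix=matrix,
        slice_thickness=2.5,
        slice_gap=gap,
        n_slices=n,
        stack_center=tuple(stack_center),
        **kw,
    )


@dataclass
class ImageStack:
    """Ordered 2-D intensity slices plus the stack's plane frame."""

    data: np.ndarray  # (n_slices, rows, cols) float32
    frame: PlaneFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, np.float32)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise InvalidInputError("stack needs >= 1 slice of 2-D data")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def _slice_grid(frame: PlaneFrame):
    rows, cols = frame.matrix
    su, sv = frame.pixel_spacing
    u = np.arange(cols) * su
    v = np.arange(rows) * sv
    return u, v


def voxelize(
    spec: PhantomSpec,
    acq: AcquisitionSpec,
    *,
    supersample: int = 4,
) -> ImageStack:
    """Sample the phantom into one stack with partial-volume slab averaging.

    Voxel intensity = background + (lumen - background) * occupancy, where
    occupancy is the lumen volume fraction of the voxel slab, estimated with
    ``supersample`` offsets through the slab thickness and, on mixed voxels,
    ``supersample``^2 in-plane sub-samples.  Slice centres are spaced
    thickness + gap apart.
    """
    frame = acq.frame()
    rows, cols = frame.matrix
    su, sv = frame.pixel_spacing
    u, v = _slice_grid(frame)
    uu, vv = np.meshgrid(u, v)  # (rows, cols): vv varies with row
    motion = acq.motion

    def inside(points):  # world points -> bool
        if motion is not None and not motion.is_identity:
            points = motion.inverse_apply(points)
        return indicator(spec, points).astype(bool)

    ss = supersample
    slab_off = (np.arange(ss) + 0.5) / ss - 0.5  # fractions of thickness
    sub = (np.arange(ss) + 0.5) / ss - 0.5  # fractions of pixel
    data = np.empty((acq.n_slices, rows, cols), np.float32)
    for k in range(acq.n_slices):
        base = frame.slice_origin(k)
        occ = np.zeros((rows, cols), np.float64)
        layers = []
        for f in slab_off:
            origin = base + f * frame.slice_thickness * frame.normal
            pts = (
                origin
                + uu[..., None] * frame.axis_u
                + vv[..., None] * frame.axis_v
            )
            m = inside(pts.reshape(-1, 3)).reshape(rows, cols)
            layers.append(m)
            occ += m
        occ /= ss
        # refine voxels whose slab layers disagree or that sit on an
        # in-plane boundary (any 4-neighbour differs in some layer)
        mixed = np.zeros((rows, cols), bool)
        stackm = np.array(layers)
        mixed |= stackm.any(axis=0) & ~stackm.all(axis=0)
        any_l = stackm.any(axis=0)
        all_l = stackm.all(axis=0)
        grown = ndimage.binary_dilation(any_l)
        shrunk = ndimage.binary_erosion(all_l, border_value=0)
        mixed |= grown & ~shrunk
        ridx, cidx = np.nonzero(mixed)
        if len(ridx):
            du, dv, df = np.meshgrid(sub, sub, slab_off, indexing="ij")
            offs = (
                du.ravel()[:, None] * su * frame.axis_u
                + dv.ravel()[:, None] * sv * frame.axis_v
                + df.ravel()[:, None] * frame.slice_thickness * frame.normal
            )  # (ss^3, 3)
            centers = (
                base
                + u[cidx][:, None] * frame.axis_u
                + v[ridx][:, None] * frame.axis_v
            )
            pts = centers[:, None, :] + offs[None, :, :]
            m = inside(pts.reshape(-1, 3)).reshape(len(ridx), -1)
            occ[ridx, cidx] = m.mean(axis=1)
        data[k] = (
            spec.intensity_background
            + (spec.intensity_lumen - spec.intensity_background) * occ
        )
    prov = {"phantom": spec.kind, "acquisition": acq.orientation}
    stack = ImageStack(data, frame, prov)
    if acq.noise_sigma > 0:
        stack = add_noise(stack, acq.noise_sigma, acq.rng_seed)
    return stack


def add_noise(stack: ImageStack, sigma: float, seed: int) -> ImageStack:
    """Rician magnitude noise: |I + n1 + i*n2| with n1, n2 ~ N(0, sigma)."""
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    if sigma == 0:
        return replace(stack, data=stack.data.copy())
    rng = np.random.default_rng(seed)
    re = stack.data + rng.normal(0.0, sigma, stack.data.shape)
    im = rng.normal(0.0, sigma, stack.data.shape)
    return replace(stack, data=np.hypot(re, im).astype(np.float32))


def apply_motion(
    stack: ImageStack,
    transform: RigidMotion,
    mode: str = "whole-stack",
    seed: int = 0,
    jitter_mm: float = 0.5,
) -> ImageStack:
    """Resample a stack as if the object had moved.

    ``whole-stack``: one rigid transform before the stack's acquisition —
    voxel (k, r, c) takes the intensity of the original volume at the
    inverse-transformed sample point (trilinear interpolation across the
    slice direction at the centre-to-centre spacing).
    ``per-slice-jitter``: independent in-plane translations per slice drawn
    from N(0, jitter_mm), seeded.
    """
    if mode == "whole-stack":
        if transform.is_identity:
            return replace(stack, data=stack.data.copy())
        frame = stack.frame
        rows, cols = frame.matrix
        su, sv = frame.pixel_spacing
        u, v = _slice_grid(frame)
        out = np.empty_like(stack.data)
        for k in range(stack.n_slices):
            base = frame.slice_origin(k)
            pts = (
                base
                + u[None, :, None] * frame.axis_u
                + v[:, None, None] * frame.axis_v
            )
            q = transform.inverse_apply(pts.reshape(-1, 3))
            d = q - frame.origin
            ci = (d @ frame.axis_u) / su
            ri = (d @ frame.axis_v) / sv
            ki = (d @ frame.normal) / frame.slice_spacing
            coords = np.stack([ki, ri, ci])
            out[k] = ndimage.map_coordinates(
                stack.data, coords, order=1, mode="nearest"
            ).reshape(rows, cols)
        return replace(stack, data=out)
    if mode == "per-slice-jitter":
        rng = np.random.default_rng(seed)
        su, sv = stack.frame.pixel_spacing
        out = np.empty_like(stack.data)
        for k in range(stack.n_slices):
            dx, dy = rng.normal(0.0, jitter_mm, 2)
            out[k] = ndimage.shift(
                stack.data[k], (dy / sv, dx / su), order=1, mode="nearest"
            )
        return replace(stack, data=out)
    raise InvalidInputError(f"unknown motion mode {mode!r}")


# ---------------------------------------------------------------------------
# analytic section contours (ground-truth boundaries, no imaging chain)


def phantom_bbox(spec: PhantomSpec, margin: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned world bounding box of the solid, inflated by ``margin``."""
    cx, cy, cz = spec.center
    if isinstance(spec, CylinderSpec):
        hx = hz = spec.radius
    elif isinstance(spec, EllipticalTubeSpec):
        hx, hz = spec.a, spec.b
    elif isinstance(spec, HourglassSpec):
        hx = hz = spec.r0
    elif isinstance(spec, BichannelSpec):
        hx, hz = spec.separation + spec.rx, spec.rz
    else:  # pragma: no cover
        hx = hz = spec.length
    hy = spec.length / 2.0
    lo = np.array([cx - hx, cy - hy, cz - hz]) - margin
    hi = np.array([cx + hx, cy + hy, cz + hz]) + margin
    return lo, hi


def analytic_contours(
    spec: PhantomSpec,
    acq: AcquisitionSpec,
    *,
    resolution: float = 0.1,
    min_area: float = 1.0,
    motion: RigidMotion | None = None,
) -> ContourSet:
    """Exact slice-centre cross-section boundaries of the (optionally moved)
    phantom: sub-pixel marching squares on a fine in-plane grid, bypassing
    the imaging chain.  Used as ground truth and as a fast contour source
    for registration experiments."""
    frame = acq.frame()
    lo, hi = phantom_bbox(spec)
    # in-plane extents of the bbox corners, in slice mm coordinates
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    d = corners - frame.origin
    pu = d @ frame.axis_u
    pv = d @ frame.axis_v
    gu = np.arange(pu.min(), pu.max() + resolution, resolution)
    gv = np.arange(pv.min(), pv.max() + resolution, resolution)
    cs = ContourSet(acq.orientation, frame)
    mot = motion if motion is not None else acq.motion
    uu, vv = np.meshgrid(gu, gv)  # (nv, nu)
    for k in range(acq.n_slices):
        base = frame.slice_origin(k)
        pts = base + uu[..., None] * frame.axis_u + vv[..., None] * frame.axis_v
        pw = pts.reshape(-1, 3)
        if mot is not None and not mot.is_identity:
            pw = mot.inverse_apply(pw)
        mask = indicator(spec, pw).reshape(uu.shape).astype(float)
        if mask.max() == 0:
            continue
        region = 0
        for poly in measure.find_contours(mask, 0.5):
            if np.linalg.norm(poly[0] - poly[-1]) > 1e-9:
                continue  # clipped by grid edge
            um = gu[0] + poly[:, 1] * resolution
            vm = gv[0] + poly[:, 0] * resolution
            c = Contour(np.stack([um, vm], axis=1), k, frame, closed=True)
            if polygon_area(c) < min_area:
                continue
            c.region_id = region
            cs.add(c)
            region += 1
    return cs


def acquire(
    spec: PhantomSpec,
    *,
    extent: float | None = None,
    noise_sigma: float = 0.0,
    motions: dict[str, RigidMotion] | None = None,
    seed: int = 0,
    matrix=(512, 512),
    stack_center=(0.0, 0.0, 0.0),
) -> dict[str, ImageStack]:
    """Acquire all three orthogonal stacks of a phantom under the study
    protocol.  Returns ``{orientation: ImageStack}``."""
    if extent is None:
        extent = spec.length + 8.0
    stacks = {}
    motions = motions or {}
    for i, orient in enumerate(("coronal", "axial", "sagittal")):
        ext = extent if orient == "coronal" else _cross_extent(spec, orient)
        acq = paper_protocol(
            orient,
            extent=ext,
            stack_center=stack_center,
            matrix=matrix,
            noise_sigma=noise_sigma,
            motion=motions.get(orient),
            rng_seed=seed + 101 * (i + 1),
        )
        stacks[orient] = voxelize(spec, acq)
    return stacks


def _cross_extent(spec: PhantomSpec, orientation: str) -> float:
    """Stack coverage along the normal for stacks sectioning the phantom's
    cross-section (axial: z extent; sagittal: x extent), with margin."""
    if isinstance(spec, CylinderSpec):
        half = spec.radius
    elif isinstance(spec, EllipticalTubeSpec):
        half = spec.b if orientation == "axial" else spec.a
    elif isinstance(spec, HourglassSpec):
        half = spec.r0
    elif isinstance(spec, BichannelSpec):
        half = spec.rz if orientation == "axial" else spec.separation + spec.rx
    else:  # pragma: no cover
        half = spec.length / 2
    return 2 * half + 6.0
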