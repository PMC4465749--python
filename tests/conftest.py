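import numpy as np
import pytest

from airwayrec import phantom as ph
from airwayrec.geometry import Contour, polygon_area, standard_frame


@pytest.fixture(scope="session")
def tube_spec():
    return ph.EllipticalTubeSpec()


@pytest.fixture(scope="session")
def tube_sets(tube_spec):
    """Analytic (ground-truth) contour sets of the elliptical tube for all
    three orientations under the study protocol."""
    cor = ph.analytic_contours(tube_spec, ph.paper_protocol("coronal", extent=64))
    axi = ph.analytic_contours(
        tube_spec, ph.paper_protocol("axial", extent=ph._cross_extent(tube_spec, "axial"))
    )
    sag = ph.analytic_contours(
        tube_spec,
        ph.paper_protocol("sagittal", extent=ph._cross_extent(tube_spec, "sagittal")),
    )
    return cor, axi, sag


@pytest.fixture(scope="session")
def coronal_stack(tube_spec):
    """Voxelized coronal stack of the elliptical tube (512x512, 4 mm
    spacing), noiseless."""
    return ph.voxelize(tube_spec, ph.paper_protocol("coronal", extent=64))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exact_tube_sets(tube_spec):
    """Elliptical-tube contour sets whose cross-plane crossing points
    coincide *exactly*: polygon vertices are placed on every other stack's
    slice planes, so the three sets are perfectly consistent."""
    from airwayrec.geometry import Contour, ContourSet, world_to_plane

    spec = tube_spec
    a, b = spec.a, spec.b
    y0, y1 = spec.y_extent
    acq_c = ph.paper_protocol("coronal", extent=64)
    acq_a = ph.paper_protocol("axial", extent=ph._cross_extent(spec, "axial"))
    acq_s = ph.paper_protocol("sagittal", extent=ph._cross_extent(spec, "sagittal"))
    fc, fa, fs = acq_c.frame(), acq_a.frame(), acq_s.frame()
    zas = [float(fa.slice_origin(k) @ fa.normal) for k in range(acq_a.n_slices)]
    xss = [float(fs.slice_origin(k) @ fs.normal) for k in range(acq_s.n_slices)]
    ts = set(np.linspace(0, 2 * np.pi, 720, endpoint=False))
    for za in zas:
        if abs(za) < b:
            t = float(np.arcsin(za / b))
            ts |= {t % (2 * np.pi), (np.pi - t) % (2 * np.pi)}
    for xs in xss:
        if abs(xs) < a:
            t = float(np.arccos(xs / a))
            ts |= {t, (2 * np.pi - t) % (2 * np.pi)}
    t = np.array(sorted(ts))
    cor = ContourSet("coronal", fc)
    for k in range(acq_c.n_slices):
        yc = float(fc.slice_origin(k) @ fc.normal)
        if not (y0 < yc < y1):
            continue
        w = np.stack([a * np.cos(t), np.full_like(t, yc), b * np.sin(t)], 1)
        p, _ = world_to_plane(w, fc)
        cor.add(Contour(p, k, fc))
    ycs = [
        float(fc.slice_origin(k) @ fc.normal)
        for k in range(acq_c.n_slices)
        if y0 < float(fc.slice_origin(k) @ fc.normal) < y1
    ]

    def rect(long_vals, a0, a1, cross_long, cross_short):
        """Rectangle [a0,a1] x [min(long),max(long)] traversed CCW, with
        extra vertices at the given crossing coordinates on each edge."""
        lo, hi = min(long_vals), max(long_vals)
        cl = sorted(v for v in cross_long if lo < v < hi)
        cs_ = sorted(v for v in cross_short if a0 < v < a1)
        bottom = [(v, lo) for v in [a0] + cs_ + [a1]]
        right = [(a1, v) for v in cl]
        top = [(v, hi) for v in [a1] + cs_[::-1] + [a0]]
        left = [(a0, v) for v in cl[::-1]]
        return np.array(bottom + right + top + left, float)

    axi = ContourSet("axial", fa)
    for k, za in enumerate(zas):
        if abs(za) >= b:
            continue
        xa = a * np.sqrt(1 - (za / b) ** 2)
        # (x, y) rectangle: x edges crossed by sagittal planes, y edges by
        # coronal planes
        xy = rect((y0, y1), -xa, xa, ycs, xss)
        w = np.stack([xy[:, 0], xy[:, 1], np.full(len(xy), za)], 1)
        p, _ = world_to_plane(w, fa)
        axi.add(Contour(p, k, fa))
    sag = ContourSet("sagittal", fs)
    for k, xs in enumerate(xss):
        if abs(xs) >= a:
            continue
        zs = b * np.sqrt(1 - (xs / a) ** 2)
        # (y, z) rectangle: y edges crossed by axial planes, z edges by
        # coronal planes
        yz = rect((-zs, zs), y0, y1, zas, ycs)
        w = np.stack([np.full(len(yz), xs), yz[:, 0], yz[:, 1]], 1)
        p, _ = world_to_plane(w, fs)
        sag.add(Contour(p, k, fs))
    return cor, axi, sag


def circle_contour(r=5.0, n=200, center=(0.0, 0.0), frame=None, slice_index=0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)], axis=1)
    frame = frame or standard_frame("axial")
    return Contour(pts, slice_index, frame, closed=True)


def dice_against_phantom(contour, spec, resolution=0.1):
    """Dice overlap between a contour's interior and the analytic phantom
    cross-section on the contour's slice plane, rasterised at
    ``resolution`` mm."""
    from matplotlib.path import Path as MplPath

    from airwayrec.geometry import plane_to_world

    pts = contour.points
    lo = pts.min(axis=0) - 2.0
    hi = pts.max(axis=0) + 2.0
    gu = np.arange(lo[0], hi[0], resolution)
    gv = np.arange(lo[1], hi[1], resolution)
    uu, vv = np.meshgrid(gu, gv)
    grid2 = np.stack([uu.ravel(), vv.ravel()], axis=1)
    in_poly = MplPath(pts).contains_points(grid2)
    w = plane_to_world(grid2, contour.frame, contour.slice_index)
    in_true = ph.indicator(spec, w).astype(bool)
    inter = np.sum(in_poly & in_true)
    return 2.0 * inter / (in_poly.sum() + in_true.sum())
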