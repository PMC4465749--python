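"""Landmarks, partitioning, cross-slice correspondence, tessellation and
the lofting driver."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from airwayrec import phantom as ph
from airwayrec import reconstruction as rec
from airwayrec.geometry import Contour, ContourSet, InvalidInputError, standard_frame
from airwayrec.nurbs import interpolate_curves_common_knots, loft_surface

from .conftest import circle_contour


def ellipse_contour(a=2.0, b=1.0, n=600):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fr = standard_frame("axial")
    return Contour(np.stack([a * np.cos(t), b * np.sin(t)], 1), 0, fr)


def rounded_rectangle(w=12.0, h=8.0, r=1.5, n=600):
    """Rectangle with rounded corners, CCW, arc-length-ish sampling."""
    fr = standard_frame("axial")
    segs = []
    cx, cy = w / 2 - r, h / 2 - r
    corners = [(cx, cy, 0), (-cx, cy, np.pi / 2), (-cx, -cy, np.pi), (cx, -cy, 3 * np.pi / 2)]
    for x0, y0, a0 in corners:
        t = np.linspace(a0, a0 + np.pi / 2, n // 8, endpoint=False)
        segs.append(np.stack([x0 + r * np.cos(t), y0 + r * np.sin(t)], 1))
        # straight edge to the next corner start
    pts = []
    for i, arc in enumerate(segs):
        pts.append(arc)
        nxt = segs[(i + 1) % 4][0]
        line = np.linspace(arc[-1], nxt, n // 8, endpoint=False)[1:]
        pts.append(line)
    return Contour(np.vstack(pts), 0, fr)


class TestCharacteristicPoints:
    def test_ellipse_four_vertices(self):
        c = ellipse_contour(2.0, 1.0)
        idx = rec.characteristic_points(c, min_prominence=0.1)
        assert len(idx) == 4
        # landmarks at (+-a, 0), (0, +-b) within one sample
        got = c.points[idx]
        expected = np.array([[2, 0], [0, 1], [-2, 0], [0, -1]], float)
        for e in expected:
            assert np.min(np.linalg.norm(got - e, axis=1)) < 0.05

    def test_circle_has_none(self):
        c = circle_contour(r=5.0, n=400)
        assert rec.characteristic_points(c, min_prominence=0.01) == []

    def test_rounded_rectangle_four_corners(self):
        c = rounded_rectangle()
        idx = rec.characteristic_points(c, min_prominence=0.2)
        assert len(idx) == 4


class TestPartition:
    def _stack_of_ellipses(self, n_slices=4):
        fr = standard_frame("coronal", slice_gap=1.5)
        cs = ContourSet("coronal", fr)
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        for k in range(n_slices):
            pts = np.stack([3 * np.cos(t), 1.5 * np.sin(t)], 1) + [100, 100]
            cs.add(Contour(pts, k, fr))
        return cs

    def test_three_arcs_cover_contour(self):
        cs = self._stack_of_ellipses()
        pset = rec.partition_by_landmarks(cs, 3, min_prominence=0.05)
        for k in cs.slice_indices():
            c = cs.contours[k][0]
            cuts = pset.cuts[(k, 0)]
            assert len(cuts) == 3
            arcs = np.diff(np.append(cuts, cuts[0] + c.perimeter))
            assert arcs.sum() == pytest.approx(c.perimeter, abs=1e-9)
            assert np.all(arcs > 0)

    def test_identical_contours_identical_cuts(self):
        cs = self._stack_of_ellipses(5)
        pset = rec.partition_by_landmarks(cs, 3, min_prominence=0.05)
        base = pset.cuts[(0, 0)]
        for k in range(1, 5):
            assert np.allclose(pset.cuts[(k, 0)], base, atol=1e-9)

    def test_fallback_equal_arcs_on_circle(self):
        fr = standard_frame("coronal", slice_gap=1.5)
        cs = ContourSet("coronal", fr)
        for k in range(3):
            cs.add(circle_contour(r=4.0, n=300, center=(50, 50), frame=fr, slice_index=k))
        pset = rec.partition_by_landmarks(cs, 3, min_prominence=0.1)
        for k in range(3):
            cuts = pset.cuts[(k, 0)]
            arcs = np.diff(np.append(cuts, cuts[0] + cs.contours[k][0].perimeter))
            assert np.allclose(arcs, arcs[0], atol=1e-6)


class TestCorrespondence:
    def test_identical_stack_straight_columns(self):
        fr = standard_frame("coronal", slice_gap=1.5)
        cs = ContourSet("coronal", fr)
        for k in range(4):
            cs.add(circle_contour(5.0, 300, (80, 80), fr, k))
        pset = rec.partition_by_landmarks(cs, 3)
        grid = rec.correspond_across_slices(pset, n_samples=60)
        assert grid.shape == (4, 60, 3)
        # columns run parallel to the stack normal
        nrm = fr.normal
        for j in range(0, 60, 7):
            col = grid[:, j, :]
            d = np.diff(col, axis=0)
            lateral = d - np.outer(d @ nrm, nrm)
            assert np.abs(lateral).max() < 1e-9

    def test_varying_radius_constant_angle(self):
        fr = standard_frame("coronal", slice_gap=1.5)
        cs = ContourSet("coronal", fr)
        radii = [4.0, 5.0, 6.5, 8.0]
        for k, r in enumerate(radii):
            cs.add(circle_contour(r, 400, (80, 80), fr, k))
        pset = rec.partition_by_landmarks(cs, 3)
        grid = rec.correspond_across_slices(pset, n_samples=90)
        # in-plane angular position of column j is constant across slices
        for j in range(0, 90, 11):
            col = grid[:, j, :]
            u = col @ fr.axis_u - 80
            v = col @ fr.axis_v - 80
            ang = np.unwrap(np.arctan2(v, u))
            assert np.abs(np.diff(ang)).max() < np.deg2rad(2.0)

    def test_exact_sample_count(self):
        fr = standard_frame("coronal", slice_gap=1.5)
        cs = ContourSet("coronal", fr)
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.stack([2 * np.cos(t), np.sin(t)], 1) + [60, 60]
        for k in range(3):
            cs.add(Contour(pts, k, fr))
        pset = rec.partition_by_landmarks(cs, 3, min_prominence=0.05)
        for n in (57, 120):
            grid = rec.correspond_across_slices(pset, n_samples=n)
            assert grid.shape[1] == n


@pytest.fixture(scope="module")
def cyl_surface():
    t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    ring = np.stack([10 * np.cos(t), np.zeros(48), 10 * np.sin(t)], 1)
    rows = np.stack([ring + [0, y, 0] for y in (0.0, 50.0)])
    return loft_surface(interpolate_curves_common_knots(rows, 3, True), degree_v=1)


class TestTessellate:
    def test_capped_cylinder_watertight(self, cyl_surface):
        mesh = rec.tessellate(cyl_surface, 64, 8, cap_ends=True)
        assert mesh.is_watertight

    def test_uncapped_vertex_count(self, cyl_surface):
        mesh = rec.tessellate(cyl_surface, 64, 9, cap_ends=False)
        assert len(mesh.vertices) == 64 * 9

    def test_hausdorff_halves_with_refinement(self, cyl_surface):
        """Mesh-to-surface distance scales ~quadratically with the grid, so
        doubling nu,nv roughly quarters it; assert at least halving."""
        rng = np.random.default_rng(5)
        (ul, uh), (vl, vh) = cyl_surface.domain
        us = rng.uniform(ul, uh, 100)
        vs = rng.uniform(vl, vh, 100)
        dense = np.array(
            [rec.evaluate_surface(cyl_surface, u, v) for u, v in zip(us, vs)]
        )

        def hausdorff(nu, nv):
            mesh = rec.tessellate(cyl_surface, nu, nv, cap_ends=False)
            d, _ = cKDTree(mesh.vertices).query(dense)
            return d.max()

        h1 = hausdorff(16, 4)
        h2 = hausdorff(32, 8)
        assert h2 < 0.6 * h1

    def test_invalid_grid_rejected(self, cyl_surface):
        with pytest.raises(InvalidInputError):
            rec.tessellate(cyl_surface, 1, 8)


class TestGuidedLoft:
    def test_guide_trace_pulls_surface(self):
        """Sections at guide stations are synthesised so the surface passes
        within tolerance of the guide points (merge-region constraint)."""
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring = np.stack([10 * np.cos(t), np.zeros(64), 10 * np.sin(t)], 1)
        rows = np.stack([ring + [0, y, 0] for y in (0.0, 12.0)])
        curves = interpolate_curves_common_knots(rows, 3, closed=True)
        # guide: the wall bulges to x = 11.5 at y = 6
        guides = np.array([[11.5, 6.0, 0.0]])
        s = loft_surface(curves, degree_v=3, guides=guides, guide_axis=(0, 1, 0))
        us = np.linspace(*s.domain[0], 400)
        vs = np.linspace(*s.domain[1], 200)
        pts = s.evaluate_grid(us, vs).reshape(-1, 3)
        d = np.linalg.norm(pts - guides[0], axis=1).min()
        assert d < 0.5

    def test_bichannel_merge_guide(self, bichannel_sets=None):
        spec = ph.BichannelSpec()
        cor = ph.analytic_contours(spec, ph.paper_protocol("coronal", extent=68))
        from airwayrec import registration as reg

        axi = ph.analytic_contours(
            spec, ph.paper_protocol("axial", extent=ph._cross_extent(spec, "axial"))
        )
        sag = ph.analytic_contours(
            spec, ph.paper_protocol("sagittal", extent=ph._cross_extent(spec, "sagittal"))
        )
        interval = reg.locate_septum_interval(cor)
        trace = reg.refine_nasopharynx_wall(cor, axi, sag, interval)
        slices = cor.slice_indices()
        ka, kb = interval
        chain = [cor.contours[k][0] for k in slices[kb:]]
        y0 = chain[0].frame.slice_origin(chain[0].slice_index) @ cor.frame.normal
        guides = trace[:: max(len(trace) // 12, 1)]
        surf = rec.reconstruct_stack(
            chain,
            n_samples=100,
            guides=guides,
            extend_ends=(float(y0 - spec.merge_y), 2.0),
        )
        # the guided solid boundary (including the anterior end cap, which
        # carries the nasopharynx wall) passes within tolerance of the trace
        mesh = rec.tessellate(surf, 256, 128, cap_ends=True)
        tm = mesh.to_trimesh()
        import trimesh

        samples, _ = trimesh.sample.sample_surface(tm, 300_000, seed=0)
        d, _ = cKDTree(samples).query(guides)
        assert d.max() < 0.5


class TestReconstructStack:
    def test_tube_volume_recovery(self, tube_sets, tube_spec):
        """Analytic sections -> loft -> mesh volume within 3% of pi*a*b*L."""
        from airwayrec import metrics as met

        cor, _, _ = tube_sets
        chain = rec.contour_chains(cor)[0]
        surf = rec.reconstruct_stack(chain, n_samples=120)
        mesh = rec.tessellate(surf, 160, 80)
        vol = met.mesh_volume(mesh)
        assert vol == pytest.approx(tube_spec.volume(), rel=0.03)

    def test_surface_interpolates_sections(self, tube_sets):
        cor, _, _ = tube_sets
        chain = rec.contour_chains(cor)[0]
        surf = rec.reconstruct_stack(chain, n_samples=80, extend_ends=0.0)
        # iso-curves at section parameters reproduce the section curves
        grid = rec.align_sample_grid(chain, 80)
        curves = interpolate_curves_common_knots(grid, 3, closed=True)
        assert surf.section_params is not None
        for j in (0, len(chain) // 2, len(chain) - 1):
            iso = surf.iso_curve_v(float(surf.section_params[j]))
            u = np.linspace(*curves[j].domain, 500)
            assert np.abs(iso.evaluate(u) - curves[j].evaluate(u)).max() < 1e-6

    def test_determinism(self, tube_sets):
        cor, _, _ = tube_sets
        chain = rec.contour_chains(cor)[0]
        s1 = rec.reconstruct_stack(chain, n_samples=64)
        s2 = rec.reconstruct_stack(chain, n_samples=64)
        assert np.array_equal(s1.control_points, s2.control_points)

    def test_too_short_chain_rejected(self, tube_sets):
        cor, _, _ = tube_sets
        chain = rec.contour_chains(cor)[0]
        with pytest.raises(InvalidInputError):
            rec.reconstruct_stack(chain[:1])
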