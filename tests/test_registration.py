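"""Cross-plane registration: crossing points, matching, piecewise
correction, displacement, septum localisation."""

import itertools

import numpy as np
import pytest

from airwayrec import phantom as ph
from airwayrec import registration as reg
from airwayrec.geometry import (
    Contour,
    ContourSet,
    point_at_arclength,
    standard_frame,
    world_to_plane,
)


def _axial_frame():
    return standard_frame("axial", slice_thickness=0.5, slice_gap=0.5)


class TestCrossingPoints:
    def test_square_cut_by_plane(self):
        # square in the y=0 plane (axial contour lives in z = const planes;
        # use a sagittal contour crossing axial planes)
        fr = standard_frame("sagittal", center=(0, 1, 1), fov=240, n_slices=1)
        # contour in (u=y, v=z) mm coords of that slice: corners in world
        # (0,0,0),(0,2,0),(0,2,2),(0,0,2)
        p, _ = world_to_plane(np.array([[0, 0, 0], [0, 2, 0], [0, 2, 2], [0, 0, 2]], float), fr)
        c = Contour(p, 0, fr)
        cut = standard_frame("axial", center=(0, 0, 1), slice_thickness=0.5, slice_gap=0.5)
        pts, _ = reg.crossing_points(c, cut, 0)  # plane z = 1
        got = {tuple(np.round(q, 9)) for q in pts}
        assert got == {(0.0, 0.0, 1.0), (0.0, 2.0, 1.0)}

    def test_no_intersection(self):
        fr = standard_frame("sagittal", center=(0, 1, 1), n_slices=1)
        p, _ = world_to_plane(np.array([[0, 0, 0], [0, 2, 0], [0, 2, 2], [0, 0, 2]], float), fr)
        c = Contour(p, 0, fr)
        cut = standard_frame("axial", center=(0, 0, 5), slice_thickness=0.5, slice_gap=0.5)
        pts, _ = reg.crossing_points(c, cut, 0)
        assert len(pts) == 0

    def test_vertex_on_plane_counted_once(self):
        fr = standard_frame("sagittal", center=(0, 1, 1), n_slices=1)
        # diamond with one vertex exactly on the cutting plane z = 2
        w = np.array([[0, 1, 0], [0, 2, 1], [0, 1, 2], [0, 0, 1]], float)
        p, _ = world_to_plane(w, fr)
        c = Contour(p, 0, fr)
        cut = standard_frame("axial", center=(0, 0, 2), slice_thickness=0.5, slice_gap=0.5)
        pts, _ = reg.crossing_points(c, cut, 0)
        assert len(pts) == 1
        assert np.allclose(pts[0], [0, 1, 2])


class TestMatchCrossings:
    def test_identity(self, rng):
        pts = rng.uniform(-10, 10, (6, 3))
        pairs, ut, uc = reg.match_crossings(pts, pts, 1.0)
        assert uc == [] and ut == []
        assert all(i == j and d == 0 for i, j, d in pairs)

    def test_far_candidate_unmatched(self):
        targets = np.array([[0.0, 0, 0]])
        cands = np.array([[10.0, 0, 0]])
        pairs, ut, uc = reg.match_crossings(targets, cands, 4.0)
        assert pairs == [] and ut == [0] and uc == [0]

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_minimal_assignment(self, n, rng):
        targets = rng.uniform(-5, 5, (n, 3))
        cands = targets[rng.permutation(n)] + rng.normal(0, 0.3, (n, 3))
        pairs, _, _ = reg.match_crossings(targets, cands, 100.0)
        total = sum(d for _, _, d in pairs)
        best = min(
            sum(np.linalg.norm(targets[i] - cands[p[i]]) for i in range(n))
            for p in itertools.permutations(range(n))
        )
        assert total == pytest.approx(best, abs=1e-9)


class TestSimilarityTransform:
    def test_identity(self):
        T = reg.segment_similarity_transform((0, 0), (1, 0), (0, 0), (1, 0))
        assert T.rotation == pytest.approx(0.0)
        assert T.scale == pytest.approx(1.0)
        assert np.allclose(T.translation, 0)

    def test_rotate_and_stretch(self):
        T = reg.segment_similarity_transform((0, 0), (1, 0), (0, 0), (0, 2))
        assert T.rotation == pytest.approx(np.pi / 2)
        assert T.scale == pytest.approx(2.0)
        assert np.allclose(T.translation, 0)

    def test_random_pairs_pinned_exactly(self, rng):
        for _ in range(200):
            p0, p1, q0, q1 = rng.uniform(-20, 20, (4, 2))
            if np.linalg.norm(p1 - p0) < 1e-6:
                continue
            T = reg.segment_similarity_transform(p0, p1, q0, q1)
            assert np.linalg.norm(T.apply(p0) - q0) < 1e-12 * 40
            assert np.linalg.norm(T.apply(p1) - q1) < 1e-12 * 40

    def test_degenerate_rejected(self):
        with pytest.raises(Exception):
            reg.segment_similarity_transform((1, 1), (1, 1), (0, 0), (1, 0))


def _circle_contour_with_corrs(shift=(0.0, 0.0), n_corr=4):
    fr = standard_frame("axial")
    t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    pts = np.stack([10 * np.cos(t), 10 * np.sin(t)], 1) + shift
    c = Contour(pts, 0, fr)
    # correspondences at quarter arcs: targets on the unshifted circle
    corrs = []
    for k in range(n_corr):
        s = k * c.perimeter / n_corr + 1.3
        m2 = point_at_arclength(c, np.array([s]))[0]
        target2 = m2 - shift
        from airwayrec.geometry import plane_to_world

        corrs.append(
            reg.Correspondence(
                plane_to_world(target2, fr, 0),
                plane_to_world(m2, fr, 0),
                float(np.linalg.norm(np.asarray(shift))),
                s,
            )
        )
    return c, corrs


class TestPiecewiseRegister:
    def test_identity_correspondences_keep_geometry(self):
        c, corrs = _circle_contour_with_corrs(shift=(0.0, 0.0))
        out = reg.piecewise_register_contour(c, corrs)
        # all original vertices are preserved exactly
        from scipy.spatial import cKDTree

        d, _ = cKDTree(out.points).query(c.points)
        assert d.max() < 1e-9

    def test_translation_recovered(self):
        c, corrs = _circle_contour_with_corrs(shift=(1.2, -0.8))
        out = reg.piecewise_register_contour(c, corrs)
        # corrected contour matches the unshifted circle
        r = np.linalg.norm(out.points, axis=1)
        assert np.abs(r - 10).max() < 0.05

    def test_targets_on_corrected_contour(self):
        c, corrs = _circle_contour_with_corrs(shift=(1.5, 0.7))
        out = reg.piecewise_register_contour(c, corrs)
        from scipy.spatial import cKDTree

        targets2 = np.array([world_to_plane(cc.target, c.frame)[0] for cc in corrs])
        d, _ = cKDTree(out.points).query(targets2)
        assert d.max() < 1e-6

    def test_topology_preserved(self):
        import shapely.geometry as sg

        c, corrs = _circle_contour_with_corrs(shift=(1.9, -1.9))
        out = reg.piecewise_register_contour(c, corrs)
        assert sg.Polygon(out.points).is_valid  # simple closed stays simple

    def test_insufficient_constraints(self):
        c, corrs = _circle_contour_with_corrs()
        with pytest.raises(reg.InsufficientConstraintsError):
            reg.piecewise_register_contour(c, corrs[:1])

    def test_order_inversion_rejected(self):
        c, corrs = _circle_contour_with_corrs(n_corr=4)
        # swap two targets: winding of targets now opposes the contour
        corrs[1].target, corrs[3].target = corrs[3].target.copy(), corrs[1].target.copy()
        with pytest.raises(reg.InvalidOrderingError):
            reg.piecewise_register_contour(c, corrs)


@pytest.fixture(scope="module")
def tube_acqs(tube_spec=None):
    spec = ph.EllipticalTubeSpec()
    return spec, {
        "coronal": ph.paper_protocol("coronal", extent=64),
        "axial": ph.paper_protocol("axial", extent=ph._cross_extent(spec, "axial")),
        "sagittal": ph.paper_protocol("sagittal", extent=ph._cross_extent(spec, "sagittal")),
    }


class TestStackDisplacement:
    def test_aligned_stacks_near_zero(self, tube_sets):
        _, axi, sag = tube_sets
        offs = reg.stack_displacement(axi, sag)
        for v in offs.values():
            assert np.linalg.norm(v) < 0.05

    def test_shifted_slice_recovered(self, tube_sets):
        """A 1.5 mm anterior-posterior shift of one axial slice is read off
        the axial-sagittal crossing gap (the visible in-plane component)."""
        _, axi, sag = tube_sets
        shifted = ContourSet(axi.orientation, axi.frame)
        target_slice = axi.slice_indices()[1]
        for c in axi:
            pts = c.points + ([0.0, 1.5] if c.slice_index == target_slice else [0, 0])
            shifted.add(c.with_points(pts))
        offs = reg.stack_displacement(shifted, sag)
        # recovered offset moves the shifted slice back: -1.5 along v (= y)
        assert np.linalg.norm(offs[target_slice] - [0.0, -1.5]) < 0.1

    def test_uncovered_slice_interpolated(self):
        """An axial slice whose contour crosses no sagittal plane gets the
        mean of its neighbours' offsets (linear interpolation)."""
        fa = standard_frame("axial", center=(0, 0, 0), slice_thickness=2.5,
                            slice_gap=0.5, n_slices=3)
        fs = standard_frame("sagittal", center=(0, 0, 0), slice_thickness=2.5,
                            slice_gap=0.5, n_slices=3)
        axi = ContourSet("axial", fa)
        sag = ContourSet("sagittal", fs)
        wide = np.array([[-8, -10], [8, -10], [8, 10], [-8, 10]], float)
        for k, duv in ((0, [0.0, 0.4]), (2, [0.0, 0.8])):
            p, _ = world_to_plane(
                np.stack([wide[:, 0], wide[:, 1], np.full(4, fa.slice_origin(k) @ fa.normal)], 1),
                fa,
            )
            axi.add(Contour(p + duv, k, fa))
        # middle slice: small contour between the sagittal planes (x = 0, +-3)
        small = np.array([[1.2, -5], [2.4, -5], [2.4, 5], [1.2, 5]], float)
        p, _ = world_to_plane(
            np.stack([small[:, 0], small[:, 1], np.full(4, fa.slice_origin(1) @ fa.normal)], 1),
            fa,
        )
        axi.add(Contour(p, 1, fa))
        for k in range(3):
            xs = fs.slice_origin(k) @ fs.normal
            w = np.array([[xs, -10, -12], [xs, 10, -12], [xs, 10, 12], [xs, -10, 12]])
            p, _ = world_to_plane(w, fs)
            sag.add(Contour(p, k, fs))
        offs = reg.stack_displacement(axi, sag)
        assert offs[1][1] == pytest.approx(0.5 * (offs[0][1] + offs[2][1]), abs=1e-9)
        assert offs[0][1] == pytest.approx(-0.4, abs=1e-9)

    def test_no_overlap_is_error(self, tube_sets):
        _, axi, _ = tube_sets
        far = ph.analytic_contours(
            ph.EllipticalTubeSpec(center=(0, 500, 0)),
            ph.paper_protocol("sagittal", extent=20, stack_center=(0, 500, 0)),
        )
        with pytest.raises(reg.RegistrationError):
            reg.stack_displacement(axi, far)


class TestSeptum:
    def _counts_set(self, counts):
        fr = standard_frame("coronal", slice_gap=1.5)
        cs = ContourSet("coronal", fr)
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        ring = np.stack([3 * np.cos(t), 3 * np.sin(t)], 1)
        for k, n in enumerate(counts):
            for r in range(n):
                cs.add(Contour(ring + [20 * r, 0], k, fr, region_id=r))
        return cs

    def test_basic_transition(self):
        assert reg.locate_septum_interval(self._counts_set([2, 2, 2, 1, 1])) == (2, 3)

    def test_no_transition_error(self):
        with pytest.raises(reg.SeptumNotFoundError):
            reg.locate_septum_interval(self._counts_set([2, 2, 2, 2]))

    def test_persistence_rule(self):
        assert reg.locate_septum_interval(self._counts_set([2, 1, 2, 1, 1])) == (2, 3)

    def test_bichannel_bracket(self):
        spec = ph.BichannelSpec()
        cor = ph.analytic_contours(spec, ph.paper_protocol("coronal", extent=68))
        ka, kb = reg.locate_septum_interval(cor)
        slices = cor.slice_indices()
        ya = cor.slice_position(slices[ka])
        yb = cor.slice_position(slices[kb])
        assert ya < spec.merge_y < yb


@pytest.fixture(scope="module")
def bichannel_sets():
    spec = ph.BichannelSpec()
    cor = ph.analytic_contours(spec, ph.paper_protocol("coronal", extent=68))
    axi = ph.analytic_contours(
        spec, ph.paper_protocol("axial", extent=ph._cross_extent(spec, "axial"))
    )
    sag = ph.analytic_contours(
        spec, ph.paper_protocol("sagittal", extent=ph._cross_extent(spec, "sagittal"))
    )
    return spec, cor, axi, sag


class TestNasopharynxWall:
    def test_wall_position(self, bichannel_sets):
        spec, cor, axi, sag = bichannel_sets
        interval = reg.locate_septum_interval(cor)
        trace = reg.refine_nasopharynx_wall(cor, axi, sag, interval)
        assert len(trace) >= 3
        mean_y = float(np.mean(trace @ cor.frame.normal))
        assert abs(mean_y - spec.merge_y) <= 0.5

    def test_rigid_shift_equivariance(self, bichannel_sets):
        """Shifting the whole registered scene rigidly shifts the wall
        trace identically."""
        from dataclasses import replace as dc_replace

        spec, cor, axi, sag = bichannel_sets
        interval = reg.locate_septum_interval(cor)
        t0 = reg.refine_nasopharynx_wall(cor, axi, sag, interval)
        shift = np.array([0.7, 1.3, -0.4])

        def shifted(cs):
            fr = dc_replace(cs.frame, origin=cs.frame.origin + shift)
            out = ContourSet(cs.orientation, fr)
            for c in cs:
                out.add(dc_replace(c, frame=fr))
            return out

        t1 = reg.refine_nasopharynx_wall(
            shifted(cor), shifted(axi), shifted(sag), interval
        )
        assert t1.shape == t0.shape

        def canon(pts):  # order-free comparison (z-sort ties are fp-jittery)
            r = np.round(pts, 6)
            return r[np.lexsort((r[:, 1], r[:, 0], r[:, 2]))]

        assert np.abs(canon(t1 - shift) - canon(t0)).max() < 1e-9


class TestRegisterAll:
    def test_consistent_sets_unchanged(self, exact_tube_sets):
        """Perfectly consistent sets pass through register_all unchanged
        (all crossing points already coincide)."""
        cor, axi, sag = exact_tube_sets
        c2, a2, s2 = reg.register_all(cor, axi, sag)
        for orig, out in ((axi, a2), (sag, s2)):
            for x, y in zip(list(orig), list(out)):
                assert x.points.shape == y.points.shape
                assert np.abs(x.points - y.points).max() < 1e-6

    def test_segmented_sets_residuals_pinned(self, tube_sets):
        cor, axi, sag = tube_sets
        c2, a2, s2 = reg.register_all(cor, axi, sag)
        # residuals vanish: every matched crossing is pinned
        assert reg.crossing_rms(a2, c2) < 1e-9
        assert reg.crossing_rms(s2, c2) < 1e-9

    def test_coronal_bit_identical(self, tube_sets):
        cor, axi, sag = tube_sets
        c2, _, _ = reg.register_all(cor, axi, sag)
        assert c2 is cor

    def test_motion_recovery_rms(self, tube_sets):
        spec = ph.EllipticalTubeSpec()
        cor, _, sag = tube_sets
        mot = ph.RigidMotion(translation=(1.8, -1.2, 0.6), rotation_deg=2.0, axis=(0, 0, 1))
        axi_m = ph.analytic_contours(
            spec,
            ph.paper_protocol("axial", extent=ph._cross_extent(spec, "axial")),
            motion=mot,
        )
        assert reg.crossing_rms(axi_m, cor) > 0.5  # motion clearly visible
        _, a2, _ = reg.register_all(cor, axi_m, sag)
        assert reg.crossing_rms(a2, cor) < 0.2

    def test_idempotent_piecewise_stage(self, tube_sets):
        cor, axi, sag = tube_sets
        c2, a2, s2 = reg.register_all(cor, axi, sag, displacement_correction=False)
        c3, a3, s3 = reg.register_all(c2, a2, s2, displacement_correction=False)
        for x, y in zip(list(a2), list(a3)):
            assert x.points.shape == y.points.shape
            assert np.abs(x.points - y.points).max() < 1e-6
        for x, y in zip(list(s2), list(s3)):
            assert np.abs(x.points - y.points).max() < 1e-6

    def test_rerun_with_displacement_small_change(self, tube_sets):
        from scipy.spatial import cKDTree

        cor, axi, sag = tube_sets
        c2, a2, s2 = reg.register_all(cor, axi, sag)
        c3, a3, s3 = reg.register_all(c2, a2, s2)
        for x, y in zip(list(a2), list(a3)):
            d, _ = cKDTree(x.points).query(y.points)
            assert d.max() < 0.05
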