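"""Non-uniform rational B-spline curves and skinned surfaces.

The reconstructed airway is carried by NURBS geometry: each registered
section polygon is interpolated by a clamped rational B-spline curve
(chord-length parameterisation, knot averaging), and a family of
compatible section curves is skinned into a surface that interpolates
every section as an iso-parameter curve.

Conventions: degree-``p`` clamped knot vectors on [0, 1] with end-knot
multiplicity ``p + 1``; all weights default to 1 (non-rational), but the
data model and the evaluators are fully rational.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .geometry import InvalidInputError

__all__ = [
    "NurbsCurve",
    "NurbsSurface",
    "find_span",
    "basis_functions",
    "basis_matrix",
    "chord_length_params",
    "average_knots",
    "interpolate_nurbs_curve",
    "interpolate_curves_common_knots",
    "loft_surface",
    "evaluate_surface",
]


def find_span(knots: np.ndarray, degree: int, u: float) -> int:
    """Index i with knots[i] <= u < knots[i+1] (clamped-domain convention:
    u at the right end maps into the last non-empty span)."""
    n = len(knots) - degree - 2  # last control index
    if u >= knots[n + 1]:
        return n
    if u <= knots[degree]:
        return degree
    return int(np.searchsorted(knots, u, side="right") - 1)


def basis_functions(knots: np.ndarray, degree: int, span: int, u: float) -> np.ndarray:
    """The degree+1 non-zero B-spline basis values N_{span-degree..span}(u)
    (Cox-de Boor triangular scheme)."""
    left = np.empty(degree + 1)
    right = np.empty(degree + 1)
    N = np.empty(degree + 1)
    N[0] = 1.0
    for j in range(1, degree + 1):
        left[j] = u - knots[span + 1 - j]
        right[j] = knots[span + j] - u
        saved = 0.0
        for r in range(j):
            tmp = N[r] / (right[r + 1] + left[j - r])
            N[r] = saved + right[r + 1] * tmp
            saved = left[j - r] * tmp
        N[j] = saved
    return N


def basis_matrix(knots: np.ndarray, degree: int, params: np.ndarray) -> np.ndarray:
    """Collocation matrix A[k, i] = N_i(params[k]) (dense; systems here are
    small)."""
    n_ctrl = len(knots) - degree - 1
    A = np.zeros((len(params), n_ctrl))
    for k, u in enumerate(np.asarray(params, float)):
        sp = find_span(knots, degree, u)
        A[k, sp - degree : sp + 1] = basis_functions(knots, degree, sp, u)
    return A


def chord_length_params(points: np.ndarray) -> np.ndarray:
    """Normalised chord-length parameters of an ordered point sequence."""
    pts = np.asarray(points, float)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(d < 1e-12):
        raise InvalidInputError("coincident consecutive points")
    cum = np.concatenate([[0.0], np.cumsum(d)])
    return cum / cum[-1]


def average_knots(params: np.ndarray, degree: int) -> np.ndarray:
    """Clamped knot vector by knot averaging over the parameters."""
    n = len(params)
    if n < degree + 1:
        raise InvalidInputError("need at least degree+1 parameters")
    interior = [params[j : j + degree].mean() for j in range(1, n - degree)]
    return np.concatenate(
        [np.zeros(degree + 1), interior, np.ones(degree + 1)]
    )


@dataclass
class NurbsCurve:
    """Clamped rational B-spline curve in 3-D mm."""

    degree: int
    control_points: np.ndarray  # (n, 3)
    weights: np.ndarray  # (n,)
    knots: np.ndarray
    closed: bool = False  # periodic seam (first data point == last)
    data_params: np.ndarray | None = None  # parameters of interpolated data

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, float)
        self.weights = np.asarray(self.weights, float)
        self.knots = np.asarray(self.knots, float)
        n = len(self.control_points)
        if len(self.knots) != n + self.degree + 1:
            raise InvalidInputError("|knots| must equal |control points| + degree + 1")
        if np.any(np.diff(self.knots) < -1e-12):
            raise InvalidInputError("knots must be nondecreasing")
        p = self.degree
        if not (
            np.allclose(self.knots[: p + 1], self.knots[0])
            and np.allclose(self.knots[-p - 1 :], self.knots[-1])
        ):
            raise InvalidInputError("knot vector must be clamped")
        if np.any(self.weights <= 0):
            raise InvalidInputError("weights must be > 0")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    def evaluate(self, u) -> np.ndarray:
        """Rational curve point(s) at parameter(s) ``u``."""
        u = np.atleast_1d(np.asarray(u, float))
        lo, hi = self.domain
        if np.any(u < lo - 1e-12) or np.any(u > hi + 1e-12):
            raise InvalidInputError("parameter outside knot domain")
        A = basis_matrix(self.knots, self.degree, u)
        wA = A * self.weights[None, :]
        num = wA @ self.control_points
        den = wA.sum(axis=1)
        return num / den[:, None]


@dataclass
class NurbsSurface:
    """Clamped rational B-spline surface; u runs around each section, v
    along the stack."""

    degree_u: int
    degree_v: int
    control_points: np.ndarray  # (nu, nv, 3)
    weights: np.ndarray  # (nu, nv)
    knots_u: np.ndarray
    knots_v: np.ndarray
    closed_u: bool = False
    section_params: np.ndarray | None = None  # v of the input sections

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, float)
        self.weights = np.asarray(self.weights, float)
        self.knots_u = np.asarray(self.knots_u, float)
        self.knots_v = np.asarray(self.knots_v, float)
        nu, nv, _ = self.control_points.shape
        if len(self.knots_u) != nu + self.degree_u + 1:
            raise InvalidInputError("knots_u inconsistent with control net")
        if len(self.knots_v) != nv + self.degree_v + 1:
            raise InvalidInputError("knots_v inconsistent with control net")
        if np.any(self.weights <= 0):
            raise InvalidInputError("weights must be > 0")

    @property
    def domain(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (
            (float(self.knots_u[self.degree_u]), float(self.knots_u[-self.degree_u - 1])),
            (float(self.knots_v[self.degree_v]), float(self.knots_v[-self.degree_v - 1])),
        )

    def evaluate(self, u, v) -> np.ndarray:
        return evaluate_surface(self, u, v)

    def evaluate_grid(self, us: np.ndarray, vs: np.ndarray) -> np.ndarray:
        """Tensor-product evaluation on a parameter grid -> (len(us),
        len(vs), 3)."""
        Au = basis_matrix(self.knots_u, self.degree_u, np.asarray(us, float))
        Av = basis_matrix(self.knots_v, self.degree_v, np.asarray(vs, float))
        hw = self.weights[..., None]
        hom = np.concatenate([self.control_points * hw, hw], axis=2)  # (nu,nv,4)
        res = np.einsum("ai,ijk,bj->abk", Au, hom, Av)
        return res[..., :3] / res[..., 3:4]

    def iso_curve_v(self, v: float) -> NurbsCurve:
        """The u-direction iso-parameter curve at fixed v."""
        Av = basis_matrix(self.knots_v, self.degree_v, np.array([v]))[0]
        hw = self.weights[..., None]
        hom = np.concatenate([self.control_points * hw, hw], axis=2)
        row = np.tensordot(hom, Av, axes=(1, 0))  # (nu, 4)
        w = row[:, 3]
        return NurbsCurve(
            self.degree_u, row[:, :3] / w[:, None], w, self.knots_u, self.closed_u
        )


def evaluate_surface(s: NurbsSurface, u: float, v: float) -> np.ndarray:
    """Rational surface point by tensor-product de Boor evaluation; the
    rational basis values form a partition of unity."""
    (ulo, uhi), (vlo, vhi) = s.domain
    if not (ulo - 1e-12 <= u <= uhi + 1e-12 and vlo - 1e-12 <= v <= vhi + 1e-12):
        raise InvalidInputError("surface parameters outside knot domain")
    return s.evaluate_grid([u], [v])[0, 0]


def interpolate_nurbs_curve(
    points: np.ndarray,
    degree: int = 3,
    closed: bool = False,
    params: np.ndarray | None = None,
    knots: np.ndarray | None = None,
) -> NurbsCurve:
    """Global interpolation: the returned curve passes through every input
    point (chord-length parameterisation + knot averaging).

    For ``closed`` the first point is appended as the final data point so
    the curve returns to its start (C0-periodic seam).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise InvalidInputError("points must be (n, 2) or (n, 3)")
    if pts.shape[1] == 2:
        pts = np.hstack([pts, np.zeros((len(pts), 1))])
    if closed and np.linalg.norm(pts[0] - pts[-1]) > 1e-12:
        pts = np.vstack([pts, pts[:1]])
    n = len(pts)
    if n < degree + 1:
        raise InvalidInputError("need at least degree+1 points")
    if params is None:
        params = chord_length_params(pts)
    else:
        params = np.asarray(params, float)
        if len(params) != n:
            raise InvalidInputError("params length mismatch")
    if knots is None:
        knots = average_knots(params, degree)
    A = basis_matrix(knots, degree, params)
    ctrl = linalg.solve(A, pts)
    return NurbsCurve(
        degree, ctrl, np.ones(n), knots, closed=closed, data_params=params
    )


def interpolate_curves_common_knots(
    point_rows: np.ndarray, degree: int = 3, closed: bool = True
) -> list[NurbsCurve]:
    """Interpolate one curve per row of a (slices x samples x 3) grid on a
    single shared knot vector (parameters averaged across rows), so the
    curves are directly compatible for skinning."""
    rows = np.asarray(point_rows, float)
    if rows.ndim != 3:
        raise InvalidInputError("point_rows must be (n_sections, n_samples, 3)")
    work = rows
    if closed:
        work = np.concatenate([rows, rows[:, :1]], axis=1)
    params = np.mean([chord_length_params(r) for r in work], axis=0)
    knots = average_knots(params, degree)
    return [
        interpolate_nurbs_curve(r, degree, closed=False, params=params, knots=knots)
        for r in work
    ]


def _compatible(curves: list[NurbsCurve]) -> None:
    c0 = curves[0]
    for c in curves[1:]:
        if c.degree != c0.degree or len(c.control_points) != len(c0.control_points):
            raise InvalidInputError("section curves must share degree and size")
        if not np.allclose(c.knots, c0.knots, atol=1e-12):
            raise InvalidInputError("section curves must share one knot vector")
        if np.any(np.abs(c.weights - c0.weights) > 1e-12):
            raise InvalidInputError("section weights must agree for skinning")


def _section_stations(curves: list[NurbsCurve]) -> np.ndarray:
    cents = np.array([c.control_points.mean(axis=0) for c in curves])
    d = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    if np.any(d < 1e-12):
        raise InvalidInputError("coincident section curves")
    return np.concatenate([[0.0], np.cumsum(d)])


def loft_surface(
    curves: list[NurbsCurve],
    degree_v: int = 3,
    guides: np.ndarray | list | None = None,
    guide_axis: np.ndarray | None = None,
    guide_direction: np.ndarray | None = None,
) -> NurbsSurface:
    """Skin a surface through compatible section curves.

    The surface interpolates every section curve as an iso-parameter curve
    (v-direction global interpolation of the control net, chord-length
    stations + knot averaging).  ``degree_v`` is capped at the number of
    sections minus one.

    ``guides``: optional (m, 3) trace of constraint points (e.g. the
    anterior nasopharynx wall).  For each guide point an extra section is
    synthesised at its station along ``guide_axis`` (default: the mean
    section-centroid direction) by blending the neighbouring sections and
    locally warping the blend — a cosine-squared falloff in arc length —
    so the surface passes through the guide point.  ``guide_direction`` is
    the facing direction of the guided wall (default: anterior, from the
    guide points' offset relative to the section centroids).
    """
    if len(curves) < 2:
        raise InvalidInputError("loft needs >= 2 section curves")
    closures = {c.closed for c in curves}
    if len(closures) != 1:
        raise InvalidInputError("cannot loft mixed open/closed sections")
    _compatible(curves)
    closed_u = curves[0].closed or bool(
        np.allclose(curves[0].evaluate(curves[0].domain[0]),
                    curves[0].evaluate(curves[0].domain[1]), atol=1e-9)
    )
    curves = list(curves)
    if guides is not None and len(guides):
        curves = _insert_guide_sections(
            curves, np.asarray(guides, float), guide_axis, guide_direction
        )
    degree_v = min(degree_v, len(curves) - 1)
    stations = _section_stations(curves)
    vparams = stations / stations[-1]
    knots_v = average_knots(vparams, degree_v)
    Av = basis_matrix(knots_v, degree_v, vparams)
    P = np.stack([c.control_points for c in curves], axis=1)  # (nu, nsec, 3)
    nu = P.shape[0]
    ctrl = np.empty((nu, len(curves), 3))
    lu, piv = linalg.lu_factor(Av)
    for i in range(nu):
        ctrl[i] = linalg.lu_solve((lu, piv), P[i])
    c0 = curves[0]
    return NurbsSurface(
        degree_u=c0.degree,
        degree_v=degree_v,
        control_points=ctrl,
        weights=np.ones((nu, len(curves))),
        knots_u=c0.knots.copy(),
        knots_v=knots_v,
        closed_u=closed_u,
        section_params=vparams,
    )


def _insert_guide_sections(
    curves: list[NurbsCurve],
    guides: np.ndarray,
    guide_axis: np.ndarray | None,
    guide_direction: np.ndarray | None,
) -> list[NurbsCurve]:
    cents = np.array([c.control_points.mean(axis=0) for c in curves])
    if guide_axis is None:
        guide_axis = cents[-1] - cents[0]
    axis = np.asarray(guide_axis, float)
    axis = axis / np.linalg.norm(axis)
    t_sec = cents @ axis
    order = np.argsort(t_sec)
    curves = [curves[i] for i in order]
    t_sec = t_sec[order]
    c0 = curves[0]
    # collocation parameters shared by all sections
    tpar = (
        c0.data_params
        if c0.data_params is not None
        else np.linspace(*c0.domain, len(c0.control_points))
    )
    out = list(curves)
    out_t = list(t_sec)
    min_sep = 0.25  # mm between section stations: keeps skinning well posed
    for g in guides:
        tg = float(g @ axis)
        if tg <= t_sec[0] + 1e-9 or tg >= t_sec[-1] - 1e-9:
            continue  # guide outside the lofted span
        if any(abs(t - tg) < min_sep for t in out_t):
            continue
        j = int(np.searchsorted(t_sec, tg)) - 1
        f = (tg - t_sec[j]) / (t_sec[j + 1] - t_sec[j])
        row = (1 - f) * curves[j].evaluate(tpar) + f * curves[j + 1].evaluate(tpar)
        row = _warp_row_to_point(row, g, guide_direction)
        sec = interpolate_nurbs_curve(
            row, c0.degree, closed=False, params=tpar, knots=c0.knots
        )
        out.append(sec)
        out_t.append(tg)
    idx = np.argsort(out_t)
    return [out[i] for i in idx]


def _warp_row_to_point(
    row: np.ndarray, g: np.ndarray, direction: np.ndarray | None
) -> np.ndarray:
    """Move the sample of ``row`` facing ``direction`` (or nearest to g)
    onto g, blending the displacement smoothly to zero with arc length."""
    if direction is not None:
        dirv = np.asarray(direction, float)
        dirv = dirv / np.linalg.norm(dirv)
        i0 = int(np.argmax(row @ dirv))
    else:
        i0 = int(np.argmin(np.linalg.norm(row - g, axis=1)))
    disp = g - row[i0]
    # arc-length distance from i0 (row may repeat the seam point at the end)
    seg = np.linalg.norm(np.diff(row, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    ds = np.abs(cum - cum[i0])
    ds = np.minimum(ds, total - ds)  # periodic distance
    W = max(total / 4.0, 1e-9)
    w = np.where(ds < W, np.cos(0.5 * np.pi * ds / W) ** 2, 0.0)
    out = row + w[:, None] * disp
    out[-1] = out[0]  # keep the seam closed
    return out
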