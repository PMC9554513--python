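"""Elastic shape geometry of planar curves via square-root velocity functions.

A curve ``c(t)`` is represented by its square-root velocity function (SRVF)

    q(t) = c'(t) / sqrt(||c'(t)||),

which removes translation by construction; scaling is removed by
normalizing q to unit L2 norm, after which every shape is a point on the
unit sphere in L2 and the geodesic distance between two shapes is

    d = arccos( <q1, q2> ),

minimized over rotation, reparametrization and (for closed curves) the
cyclic start point.  The reparametrization search is a dynamic program on a
monotone lattice (see :mod:`elasticshapes._dp`); rotations are solved in
closed form; start points are scanned exhaustively or with a stride.

Open curves follow the landmark-constrained convention: their endpoints are
homologous points fixed in advance, so rotation is *not* searched and the
warp pins the endpoints, unless explicitly requested otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate as _integrate

from . import _dp
from .outlines import (
    Outline,
    ResampleConfig,
    canonicalize,
    resample_arclength,
    resample_with_tangents,
)

__all__ = [
    "SRVFCurve",
    "ElasticMatch",
    "GeodesicPath",
    "KarcherMean",
    "srvf_transform",
    "inverse_srvf",
    "align_open",
    "align_closed",
    "elastic_distance",
    "pairwise_elastic_distances",
    "geodesic_path",
    "karcher_mean",
    "path_energy",
    "symmetric_transform",
]


# ---------------------------------------------------------------------------
# representation
# ---------------------------------------------------------------------------


@dataclass
class SRVFCurve:
    """Unit-norm square-root velocity representation of an outline.

    ``q`` holds M planar vectors on the uniform parameter grid of [0, 1]
    (periodic for closed curves).  After normalization the curve is a point
    on the L2 unit sphere: sum ||q_i||^2 dt = 1.
    """

    q: np.ndarray
    closed: bool
    norm_normalized: bool = True
    source_id: str = ""

    @property
    def grid_size(self) -> int:
        return int(self.q.shape[0])


def _weights(m: int, closed: bool) -> np.ndarray:
    if closed:
        return np.full(m, 1.0 / m)
    w = np.full(m, 1.0 / (m - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


def _inner(q1: np.ndarray, q2: np.ndarray, closed: bool) -> float:
    w = _weights(q1.shape[0], closed)
    return float(np.sum(w * np.sum(q1 * q2, axis=1)))


def _normalize_q(q: np.ndarray, closed: bool) -> np.ndarray:
    nrm = np.sqrt(_inner(q, q, closed))
    if nrm <= 0:
        raise ValueError("zero-norm SRVF")
    return q / nrm


def srvf_transform(outline: Outline, grid_size: int = 100) -> SRVFCurve:
    """Map an outline to its unit-norm SRVF on a uniform grid.

    The outline is first resampled to equal arc-length spacing on the grid
    (``grid_size`` points; the periodic grid for closed curves).  At
    constant speed the normalized SRVF reduces to the unit tangent field,
    which is evaluated analytically on the fitted spline.
    """
    if outline.n_points < 4:
        raise ValueError("need at least 4 distinct points")
    _, tang = resample_with_tangents(
        outline, ResampleConfig(n_points=grid_size, periodic=outline.closed)
    )
    q = _normalize_q(tang, outline.closed)
    return SRVFCurve(q=q, closed=outline.closed, source_id=outline.object_id)


def inverse_srvf(q: SRVFCurve | np.ndarray, closed: bool | None = None) -> Outline:
    """Reconstruct an outline from an SRVF by cumulative integration.

    c(t) = integral of q ||q||; the result is centred at the origin with
    unit centroid size.  For closed SRVFs the small closure defect left by
    discretization is removed by subtracting the linear drift.
    """
    if isinstance(q, SRVFCurve):
        arr, closed = q.q, q.closed
    else:
        arr = np.asarray(q, dtype=float)
        if closed is None:
            raise ValueError("closed flag required for raw arrays")
    m = arr.shape[0]
    dt = 1.0 / m if closed else 1.0 / (m - 1)
    v = arr * np.linalg.norm(arr, axis=1)[:, None]
    if closed:
        ve = np.vstack([v, v[:1]])
        c = _integrate.cumulative_trapezoid(ve, dx=dt, axis=0, initial=0.0)
        drift = c[-1]
        t = np.linspace(0.0, 1.0, m + 1)
        c = c - t[:, None] * drift
        c = c[:-1]
    else:
        c = _integrate.cumulative_trapezoid(v, dx=dt, axis=0, initial=0.0)
    c = c - c.mean(axis=0)
    size = np.sqrt((c**2).sum())
    if size <= 0:
        raise ValueError("degenerate reconstruction")
    return Outline(c / size, closed=bool(closed))


def _srvf_of_polygon(pts: np.ndarray, closed: bool) -> np.ndarray:
    """SRVF of an already uniformly sampled polygon (no resampling)."""
    m = pts.shape[0]
    if closed:
        dt = 1.0 / m
        dc = (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)) / (2 * dt)
    else:
        dt = 1.0 / (m - 1)
        dc = np.gradient(pts, dt, axis=0)
    speed = np.linalg.norm(dc, axis=1)
    q = dc / np.sqrt(np.maximum(speed, 1e-12))[:, None]
    return _normalize_q(q, closed)


def project_to_closed(q: np.ndarray) -> np.ndarray:
    """Project an SRVF array onto the closed-curve constraint set.

    The curve is reconstructed, its closure defect removed in the
    coordinate domain, and the SRVF recomputed from the closed polygon.
    """
    out = inverse_srvf(q, closed=True)
    return _srvf_of_polygon(out.points, closed=True)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@dataclass
class ElasticMatch:
    """Optimal alignment of one SRVF onto another.

    ``gamma`` samples the monotone reparametrization on [0, 1];
    ``seed_shift`` is the cyclic start shift in vertex units (closed curves
    only; fractional after sub-vertex refinement); ``distance`` = arccos of
    the optimized inner product.
    """

    rotation: np.ndarray
    seed_shift: float  # cyclic start shift in vertex units (sub-vertex after refinement)
    gamma: np.ndarray
    inner_product: float
    distance: float


def _rotmat(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _warp_q(q: np.ndarray, gamma_pos: np.ndarray) -> np.ndarray:
    """Apply the warp (fractional grid positions) by the group action
    (q o gamma) sqrt(gamma')."""
    n = q.shape[0]
    idx = np.arange(n)
    qx = np.interp(gamma_pos, idx, q[:, 0])
    qy = np.interp(gamma_pos, idx, q[:, 1])
    out = np.column_stack([qx, qy])
    # restore the magnitude lost to chord shrinkage of the turning field
    mag = np.linalg.norm(q, axis=1)
    lam = np.interp(gamma_pos, idx, mag)
    nv = np.linalg.norm(out, axis=1)
    out *= np.where(nv > 1e-12, lam / np.maximum(nv, 1e-12), 1.0)[:, None]
    dg = np.gradient(gamma_pos)
    dg = np.maximum(dg, 1e-12)
    return out * np.sqrt(dg)[:, None]


def _compose_gamma(inner_pos: np.ndarray, outer_pos: np.ndarray) -> np.ndarray:
    """Positions of (inner o outer): outer maps the grid into the inner grid."""
    n = inner_pos.shape[0]
    return np.interp(outer_pos, np.arange(n), inner_pos)


def align_open(
    q1: SRVFCurve,
    q2: SRVFCurve,
    fix_endpoints: bool = True,
    allow_rotation: bool = False,
    refine: int = 1,
) -> ElasticMatch:
    """Elastically match an open SRVF ``q2`` onto ``q1``.

    The warp is found by dynamic programming; with ``fix_endpoints`` (the
    landmark-constrained mode) it pins both endpoints, otherwise the path
    may slide at the boundaries.  Rotation is solved by orthogonal
    Procrustes only when ``allow_rotation`` — by convention open curves are
    presented pre-oriented.  ``refine`` extra DP passes compose near-identity
    corrections onto the first warp.
    """
    if q1.closed or q2.closed:
        raise ValueError("align_open requires open curves")
    if q1.grid_size != q2.grid_size:
        raise ValueError("grid size mismatch")
    a1, a2 = q1.q, q2.q
    n = a1.shape[0]
    dt = 1.0 / (n - 1)
    theta_total = 0.0
    if allow_rotation:
        theta_total = _dp._best_rotation_angle(a1 * _weights(n, False)[:, None], a2)
        a2 = a2 @ _rotmat(theta_total).T
    ip, ei, ej, ptr = _dp._dp_pass_fine(a1, a2, dt, not fix_endpoints)
    gamma_pos = _dp._backtrack_fine(ptr, ei, ej)
    best_ip = ip
    cur = _normalize_q(_warp_q(a2, gamma_pos), False)
    for _ in range(max(0, refine)):
        if allow_rotation:
            th = _dp._best_rotation_angle(a1 * _weights(n, False)[:, None], cur)
            cur = cur @ _rotmat(th).T
            theta_total += th
        ip2, ei2, ej2, ptr2 = _dp._dp_pass_fine(a1, cur, dt, False)
        if ip2 <= best_ip + 1e-14:
            break
        g2 = _dp._backtrack_fine(ptr2, ei2, ej2)
        gamma_pos = _compose_gamma(gamma_pos, g2)
        cur = _normalize_q(_warp_q(q2.q @ _rotmat(theta_total).T, gamma_pos), False)
        best_ip = ip2
    d = float(np.arccos(np.clip(best_ip, -1.0, 1.0)))
    return ElasticMatch(
        rotation=_rotmat(theta_total),
        seed_shift=0,
        gamma=gamma_pos / (n - 1),
        inner_product=float(min(best_ip, 1.0)),
        distance=d,
    )


def _frac_roll(q: np.ndarray, shift: float) -> np.ndarray:
    """Cyclic shift of periodic samples by a possibly fractional number of
    vertices (circular linear interpolation, magnitude-preserving)."""
    m = q.shape[0]
    pos = (np.arange(m) + shift) % m
    i0 = np.floor(pos).astype(int) % m
    fr = (pos - np.floor(pos))[:, None]
    i1 = (i0 + 1) % m
    out = q[i0] * (1.0 - fr) + q[i1] * fr
    # linear interpolation of a turning field shrinks it; restore magnitude
    lam = (1.0 - fr[:, 0]) * np.linalg.norm(q[i0], axis=1) + fr[:, 0] * np.linalg.norm(q[i1], axis=1)
    nv = np.linalg.norm(out, axis=1)
    scale = np.where(nv > 1e-12, lam / np.maximum(nv, 1e-12), 1.0)
    return out * scale[:, None]


def align_closed(
    q1: SRVFCurve,
    q2: SRVFCurve,
    seed_stride: int = 1,
    allow_rotation: bool = True,
    refine: int = 1,
) -> ElasticMatch:
    """Elastically match a closed SRVF ``q2`` onto ``q1``.

    Jointly optimizes the cyclic start vertex (every ``seed_stride``-th
    candidate, rotation solved in closed form per candidate) and the
    reparametrization by dynamic programming on the seam-cut curve.  With
    ``refine > 0`` the start point is then refined to sub-vertex precision
    by a golden-section search around the winning seed (the true shift of a
    resampled curve is rarely a whole vertex), followed by warp-composition
    passes; refinement only ever increases the inner product.  ``refine=0``
    reproduces exactly the single-pass integer seed scan, which is what a
    brute-force oracle enumerates.
    """
    if not (q1.closed and q2.closed):
        raise ValueError("align_closed requires closed curves")
    if q1.grid_size != q2.grid_size:
        raise ValueError("grid size mismatch")
    if seed_stride < 1:
        raise ValueError("seed_stride must be >= 1")
    a1, a2 = np.ascontiguousarray(q1.q), np.ascontiguousarray(q2.q)
    m = a1.shape[0]
    dt = 1.0 / m
    a1e = np.vstack([a1, a1[:1]])

    def dp_at(shift: float):
        q2r = _frac_roll(a2, shift)
        th = _dp._best_rotation_angle(a1, q2r) if allow_rotation else 0.0
        q2r = q2r @ _rotmat(th).T
        q2e = np.vstack([q2r, q2r[:1]])
        ip, ei, ej, ptr = _dp._dp_pass_fine(a1e, q2e, dt, False)
        return ip, th, (ei, ej), ptr, q2e

    def plain_ip_at(shift: float) -> float:
        q2r = _frac_roll(a2, shift)
        th = _dp._best_rotation_angle(a1, q2r) if allow_rotation else 0.0
        return _inner(a1, q2r @ _rotmat(th).T, True)

    _, seed, _ = _dp._closed_scan(a1, a2, seed_stride, allow_rotation)
    shift = float(seed)
    ip, theta, end, ptr, a2e = dp_at(shift)
    if refine > 0:
        # golden-section refinement of the start point around the best seed,
        # scored by the cheap rotation-optimized inner product (exact for
        # congruent curves, where sub-vertex start precision matters most)
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        lo, hi = shift - 1.0 * seed_stride, shift + 1.0 * seed_stride
        x1 = hi - gr * (hi - lo)
        x2 = lo + gr * (hi - lo)
        f1, f2 = plain_ip_at(x1), plain_ip_at(x2)
        for _ in range(20):
            if f1 < f2:
                lo, x1, f1 = x1, x2, f2
                x2 = lo + gr * (hi - lo)
                f2 = plain_ip_at(x2)
            else:
                hi, x2, f2 = x2, x1, f1
                x1 = hi - gr * (hi - lo)
                f1 = plain_ip_at(x1)
        x_best = x1 if f1 >= f2 else x2
        ip_b, th_b, end_b, ptr_b, a2e_b = dp_at(x_best)
        if ip_b > ip:
            ip, theta, end, ptr, a2e, shift = ip_b, th_b, end_b, ptr_b, a2e_b, x_best
    gamma_pos = _dp._backtrack_fine(ptr, end[0], end[1])
    best_ip = ip
    theta_total = theta
    cur = _normalize_q(_warp_q(a2e, gamma_pos)[:-1], True)
    for _ in range(max(0, refine)):
        th = _dp._best_rotation_angle(a1, cur) if allow_rotation else 0.0
        cur = cur @ _rotmat(th).T
        cure = np.vstack([cur, cur[:1]])
        ip2, ei2, ej2, ptr2 = _dp._dp_pass_fine(a1e, cure, dt, False)
        if ip2 <= best_ip + 1e-14:
            break
        theta_total += th
        g2 = _dp._backtrack_fine(ptr2, ei2, ej2)
        gamma_pos = _compose_gamma(gamma_pos, g2)
        base = _frac_roll(a2, shift) @ _rotmat(theta_total).T
        basee = np.vstack([base, base[:1]])
        cur = _normalize_q(_warp_q(basee, gamma_pos)[:-1], True)
        best_ip = ip2
    d = float(np.arccos(np.clip(best_ip, -1.0, 1.0)))
    return ElasticMatch(
        rotation=_rotmat(theta_total),
        seed_shift=shift,
        gamma=gamma_pos / m,
        inner_product=float(min(best_ip, 1.0)),
        distance=d,
    )


def apply_match(q2: SRVFCurve, match: ElasticMatch) -> SRVFCurve:
    """Carry ``q2`` through a match: roll, rotate, warp, renormalize."""
    a2 = q2.q
    if q2.closed:
        m = a2.shape[0]
        rolled = _frac_roll(a2, match.seed_shift) @ match.rotation.T
        ext = np.vstack([rolled, rolled[:1]])
        warped = _warp_q(ext, match.gamma * m)[:-1]
        return SRVFCurve(_normalize_q(warped, True), closed=True, source_id=q2.source_id)
    n = a2.shape[0]
    rotated = a2 @ match.rotation.T
    warped = _warp_q(rotated, match.gamma * (n - 1))
    return SRVFCurve(_normalize_q(warped, False), closed=False, source_id=q2.source_id)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _match(q1: SRVFCurve, q2: SRVFCurve, **options) -> ElasticMatch:
    if q1.closed:
        allowed = {"seed_stride", "allow_rotation", "refine"}
        opts = {k: v for k, v in options.items() if k in allowed}
        return align_closed(q1, q2, **opts)
    allowed = {"fix_endpoints", "allow_rotation", "refine"}
    opts = {k: v for k, v in options.items() if k in allowed}
    return align_open(q1, q2, **opts)


def elastic_distance(
    o1: Outline | SRVFCurve,
    o2: Outline | SRVFCurve,
    mode: str | None = None,
    grid_size: int = 100,
    symmetrize: bool = False,
    **options,
) -> float:
    """Geodesic shape-sphere distance between two outlines.

    ``mode`` is "closed" or "open"; by default it follows the outlines'
    closed flags.  The distance is arccos of the inner product maximized
    over the mode's alignment group, in [0, pi].  ``symmetrize`` averages
    d(a, b) and d(b, a) (the DP lattice is not exactly symmetric).
    """
    closed = {"closed": True, "open": False}.get(mode) if mode else None
    q1 = _as_srvf(o1, closed, grid_size)
    q2 = _as_srvf(o2, closed, grid_size)
    if q1.closed != q2.closed:
        raise ValueError("cannot mix open and closed curves")
    d = _match(q1, q2, **options).distance
    if symmetrize:
        d = 0.5 * (d + _match(q2, q1, **options).distance)
    return d


def _as_srvf(o, closed: bool | None, grid_size: int) -> SRVFCurve:
    if isinstance(o, SRVFCurve):
        return o
    if closed is not None and closed != o.closed:
        o = Outline(o.points, closed=closed, object_id=o.object_id, label=o.label)
    return srvf_transform(o, grid_size=grid_size)


def pairwise_elastic_distances(
    outlines,
    mode: str | None = None,
    grid_size: int = 100,
    progress: bool = False,
    **options,
) -> np.ndarray:
    """Symmetric matrix of elastic distances between all outline pairs."""
    closed = {"closed": True, "open": False}.get(mode) if mode else None
    qs = [_as_srvf(o, closed, grid_size) for o in outlines]
    n = len(qs)
    D = np.zeros((n, n))
    it = range(n)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        it = tqdm(it, desc="elastic distances")
    for i in it:
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _match(qs[i], qs[j], **options).distance
    return D


# ---------------------------------------------------------------------------
# geodesics, means, energies
# ---------------------------------------------------------------------------


@dataclass
class GeodesicPath:
    """Great-circle transformation series between two shapes."""

    steps: list
    kappa: int
    distance: float
    energy: float


def geodesic_path(
    o1: Outline,
    o2: Outline,
    kappa: int = 5,
    mode: str | None = None,
    grid_size: int = 100,
    **options,
) -> GeodesicPath:
    """Geodesic (shortest path) from ``o1`` to ``o2`` in kappa steps.

    After alignment the path follows the great circle on the shape sphere;
    closed-curve intermediates are projected back onto the closed-curve
    constraint set.  ``energy`` is the sum of elastic distances between
    consecutive back-transformed outlines.
    """
    if kappa < 2:
        raise ValueError("kappa must be >= 2")
    closed = {"closed": True, "open": False}.get(mode) if mode else o1.closed
    q1 = _as_srvf(o1, closed, grid_size)
    q2 = _as_srvf(o2, closed, grid_size)
    match = _match(q1, q2, **options)
    q2a = apply_match(q2, match)
    ip = np.clip(_inner(q1.q, q2a.q, closed), -1.0, 1.0)
    theta = float(np.arccos(ip))
    steps: list[Outline] = []
    qsteps: list[np.ndarray] = []
    for j in range(kappa + 1):
        tau = j / kappa
        if theta < 1e-9:
            qj = q1.q.copy()  # degenerate: every step is the source shape
        else:
            qj = (
                np.sin((1 - tau) * theta) * q1.q + np.sin(tau * theta) * q2a.q
            ) / np.sin(theta)
            qj = _normalize_q(qj, closed)
            if closed and 0 < j < kappa:
                qj = project_to_closed(qj)
        qsteps.append(qj)
        out = inverse_srvf(qj, closed=closed)
        out.object_id = f"step_{j}"
        steps.append(out)
    # energy of the series as parametrized: consecutive great-circle angles
    energy = float(
        sum(
            np.arccos(np.clip(_inner(a, b, closed), -1.0, 1.0))
            for a, b in zip(qsteps[:-1], qsteps[1:])
        )
    )
    return GeodesicPath(steps=steps, kappa=kappa, distance=theta, energy=energy)


def path_energy(steps, mode: str | None = None, grid_size: int = 100, **options) -> float:
    """Total deformation energy of a transformation series: the sum of
    elastic distances between consecutive outlines.

    The steps of a series share a sampling scheme by construction, so each
    outline is used at its stored vertex sampling (alignment is still
    re-optimized per consecutive pair); outlines with mismatched vertex
    counts are first resampled to ``grid_size``.
    """
    if len(steps) < 2:
        raise ValueError("need at least 2 steps")
    closed = {"closed": True, "open": False}.get(mode) if mode else steps[0].closed
    common = steps[0].n_points if len({s.n_points for s in steps}) == 1 else None
    qs = []
    for s in steps:
        if common is None:
            s = resample_arclength(s, ResampleConfig(n_points=grid_size, periodic=closed))
        qs.append(SRVFCurve(_srvf_of_polygon(s.points, closed), closed=closed))
    return float(
        sum(_match(a, b, **options).distance for a, b in zip(qs[:-1], qs[1:]))
    )


@dataclass
class KarcherMean:
    """Intrinsic (Frechet) mean on the shape sphere."""

    mean_q: SRVFCurve
    mean_outline: Outline
    iterations: int
    final_gradient_norm: float


def karcher_mean(
    outlines,
    mode: str | None = None,
    grid_size: int = 100,
    tol: float = 1e-4,
    max_iter: int = 50,
    step: float = 0.5,
    **options,
) -> KarcherMean:
    """Karcher mean of a set of outlines under the elastic metric.

    Iteratively aligns every curve to the running estimate, averages the
    log-map (shooting) vectors and updates by the exponential map, starting
    from the renormalized extrinsic average.
    """
    if len(outlines) == 0:
        raise ValueError("no outlines given")
    closed = {"closed": True, "open": False}.get(mode) if mode else outlines[0].closed
    qs = [_as_srvf(o, closed, grid_size) for o in outlines]
    if len(qs) == 1:
        q = qs[0]
        return KarcherMean(q, inverse_srvf(q), 0, 0.0)
    # initial estimate: extrinsic average of curves aligned to the first
    aligned0 = [qs[0].q]
    for qi in qs[1:]:
        aligned0.append(apply_match(qi, _match(qs[0], qi, **options)).q)
    mu = _normalize_q(np.mean(aligned0, axis=0), closed)
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mu_curve = SRVFCurve(mu, closed=closed)
        vs = []
        for qi in qs:
            qa = apply_match(qi, _match(mu_curve, qi, **options)).q
            ip = np.clip(_inner(mu, qa, closed), -1.0, 1.0)
            th = np.arccos(ip)
            if th < 1e-12:
                vs.append(np.zeros_like(mu))
            else:
                vs.append((qa - ip * mu) * th / np.sin(th))
        v = np.mean(vs, axis=0)
        grad_norm = float(np.sqrt(_inner(v, v, closed)))
        if grad_norm < tol:
            break
        w = step * v
        wn = np.sqrt(_inner(w, w, closed))
        mu = np.cos(wn) * mu + (np.sin(wn) / wn) * w if wn > 0 else mu
        mu = _normalize_q(mu, closed)
        if closed:
            mu = project_to_closed(mu)
    mean_q = SRVFCurve(mu, closed=closed, source_id="karcher_mean")
    return KarcherMean(mean_q, inverse_srvf(mean_q), it, grad_norm)


# ---------------------------------------------------------------------------
# symmetric transformations
# ---------------------------------------------------------------------------


def _split_halves(outline: Outline) -> tuple[np.ndarray, np.ndarray]:
    """Split a closed outline at its extreme-y vertices into two sides,
    both running top to bottom."""
    pts = outline.points - outline.centroid()
    n = pts.shape[0]
    i_top = int(np.lexsort((pts[:, 0], -pts[:, 1]))[0])
    i_bot = int(np.lexsort((pts[:, 0], pts[:, 1]))[0])
    rolled = np.roll(pts, -i_top, axis=0)
    j = (i_bot - i_top) % n
    side_a = rolled[: j + 1]
    side_b = np.vstack([rolled[j:], rolled[:1]])[::-1]
    return side_a, side_b


def _asymmetry(outline: Outline, n_check: int = 100) -> float:
    """Relative mismatch between the two sides after reflection."""
    a, b = _split_halves(outline)
    ra = resample_arclength(Outline(a, closed=False), ResampleConfig(n_points=n_check, periodic=False))
    rb = resample_arclength(Outline(b, closed=False), ResampleConfig(n_points=n_check, periodic=False))
    refl = rb.points * [-1.0, 1.0]
    scale = Outline(outline.points - outline.centroid(), closed=True).centroid_size()
    return float(np.sqrt(((ra.points - refl) ** 2).sum()) / scale)


def symmetric_transform(
    o1: Outline, o2: Outline, kappa: int = 5, grid_size: int = 100, tol: float = 0.01
) -> GeodesicPath:
    """Mirror-symmetric geodesic between two mirror-symmetric closed shapes.

    The outlines are split in half at their extreme-y points; the open-curve
    geodesic between right halves is computed, and each intermediate half is
    reflected about the vertical axis and re-attached, so every step of the
    series is itself mirror-symmetric.
    """
    for o in (o1, o2):
        if not o.closed:
            raise ValueError("symmetric_transform needs closed outlines")
        asym = _asymmetry(o)
        if asym > tol:
            raise ValueError(
                f"outline {o.object_id!r} is asymmetric (relative mismatch {asym:.3f})"
            )

    def right_half(o: Outline) -> Outline:
        a, b = _split_halves(o)
        half = a if a[:, 0].mean() >= b[:, 0].mean() else b
        return Outline(half, closed=False)

    h1, h2 = right_half(o1), right_half(o2)
    path = geodesic_path(h1, h2, kappa=kappa, mode="open", grid_size=grid_size)
    steps = []
    for j, half in enumerate(path.steps):
        pts = half.points - half.points[0]
        chord = pts[-1]
        ang = np.arctan2(chord[0], -chord[1])  # rotate chord onto -y axis
        pts = pts @ _rotmat(ang).T
        pts[:, 0] -= 0.5 * (pts[:, 0].max() + pts[:, 0].min()) * 0.0
        pts[:, 0] -= pts[0, 0]
        mirrored = pts[::-1] * [-1.0, 1.0]
        full = np.vstack([pts, mirrored[1:-1]])
        out = Outline(full, closed=True, object_id=f"sym_step_{j}")
        pts_c = out.points - out.centroid()
        size = np.sqrt((pts_c**2).sum())
        steps.append(canonicalize(out.with_points(pts_c / size)))
    energy = path_energy(steps, mode="closed", grid_size=grid_size)
    return GeodesicPath(steps=steps, kappa=kappa, distance=path.distance, energy=energy)
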