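"""Dynamic-programming kernels for elastic curve matching.

The reparametrization search is a shortest-path problem on an M x M lattice:
node (i, j) pairs parameter t_i on the first curve with t_j on the second,
and admissible moves have slopes in {1/3, 1/2, 2/3, 1, 3/2, 2, 3} so the
warp stays strictly monotone with bounded stretching.  Each move scores the
trapezoid-rule integral of <q1(t), q2(gamma(t)) sqrt(gamma'(t))> over the
segment, with q2 linearly interpolated between grid nodes; the optimal path
therefore maximizes the L2 inner product after warping, and the identity
path reproduces the plain trapezoid inner product exactly.

Kernels are numba-compiled; everything here works on raw (n, 2) float
arrays and is wrapped by :mod:`elasticshapes.elastic`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# admissible lattice moves (di, dj): coarse set for the seed scan, fine set
# (all coprime pairs up to 6 with slope in [1/3, 3]) for the final matching —
# the fine slopes near 1 are what make small smooth warps representable
# without paying a spurious sqrt(gamma') penalty.
_STEPS = np.array(
    [[1, 1], [1, 2], [2, 1], [1, 3], [3, 1], [2, 3], [3, 2]], dtype=np.int64
)
_STEPS_FINE = np.array(
    [
        [1, 1], [1, 2], [2, 1], [1, 3], [3, 1], [2, 3], [3, 2],
        [2, 5], [5, 2], [3, 4], [4, 3], [3, 5], [5, 3],
        [4, 5], [5, 4], [5, 6], [6, 5],
    ],
    dtype=np.int64,
)

_NEG = -1.0e18


@njit(cache=True)
def _dp_pass_steps(q1, q2, dt, free_boundary, steps):
    """DP sweep over an arbitrary admissible move set."""
    n = q1.shape[0]
    val = np.full((n, n), _NEG)
    ptr = np.full((n, n), -1, dtype=np.int8)
    val[0, 0] = 0.0
    if free_boundary:
        for j in range(n):
            val[0, j] = 0.0
        for i in range(n):
            val[i, 0] = 0.0
    n2 = q2.shape[0]
    for i in range(1, n):
        for j in range(1, n):
            best = _NEG
            bs = -1
            for sidx in range(steps.shape[0]):
                di = steps[sidx, 0]
                dj = steps[sidx, 1]
                i0 = i - di
                j0 = j - dj
                if i0 < 0 or j0 < 0:
                    continue
                prev = val[i0, j0]
                if prev <= _NEG * 0.5:
                    continue
                s = dj / di
                sq = np.sqrt(s)
                gp = (q1[i0, 0] * q2[j0, 0] + q1[i0, 1] * q2[j0, 1]) * sq
                c = 0.0
                for k in range(1, di + 1):
                    p = j0 + k * s
                    jp = int(np.floor(p))
                    if jp >= n2 - 1:
                        q2x = q2[n2 - 1, 0]
                        q2y = q2[n2 - 1, 1]
                    else:
                        fr = p - jp
                        q2x = q2[jp, 0] * (1.0 - fr) + q2[jp + 1, 0] * fr
                        q2y = q2[jp, 1] * (1.0 - fr) + q2[jp + 1, 1] * fr
                        # chord shrinkage correction: linear interpolation of
                        # a turning q field underestimates its magnitude, so
                        # rescale to the interpolated sample magnitude
                        nv = np.sqrt(q2x * q2x + q2y * q2y)
                        if nv > 1e-12:
                            lam = (1.0 - fr) * np.sqrt(
                                q2[jp, 0] ** 2 + q2[jp, 1] ** 2
                            ) + fr * np.sqrt(
                                q2[jp + 1, 0] ** 2 + q2[jp + 1, 1] ** 2
                            )
                            q2x *= lam / nv
                            q2y *= lam / nv
                    g = (q1[i0 + k, 0] * q2x + q1[i0 + k, 1] * q2y) * sq
                    c += 0.5 * (gp + g) * dt
                    gp = g
                cand = prev + c
                if cand > best:
                    best = cand
                    bs = sidx
            val[i, j] = best
            ptr[i, j] = bs
    ei, ej = n - 1, n - 1
    if free_boundary:
        best_end = val[n - 1, n - 1]
        for j in range(n):
            if val[n - 1, j] > best_end:
                best_end = val[n - 1, j]
                ei, ej = n - 1, j
            if val[j, n - 1] > best_end:
                best_end = val[j, n - 1]
                ei, ej = j, n - 1
    return val[ei, ej], ei, ej, ptr


@njit(cache=True)
def _dp_pass_fine(q1, q2, dt, free_boundary):
    return _dp_pass_steps(q1, q2, dt, free_boundary, _STEPS_FINE)


@njit(cache=True)
def _dp_pass(q1, q2, dt, free_boundary):
    """One DP sweep over the coarse move set (used by the seed scan)."""
    return _dp_pass_steps(q1, q2, dt, free_boundary, _STEPS)


@njit(cache=True)
def _backtrack_steps(ptr, ei, ej, steps):
    """Recover the warp as fractional q2-positions per q1 grid node."""
    n = ptr.shape[0]
    gamma = np.full(n, -1.0)
    i, j = ei, ej
    gamma_i = np.empty(n, dtype=np.int64)
    gamma_j = np.empty(n, dtype=np.int64)
    m = 0
    while True:
        gamma_i[m] = i
        gamma_j[m] = j
        m += 1
        s = ptr[i, j]
        if s < 0:
            break
        i -= steps[s, 0]
        j -= steps[s, 1]
    # nodes are in reverse order; fill gamma by linear interpolation
    for k in range(m - 1, 0, -1):
        i0, j0 = gamma_i[k], gamma_j[k]
        i1, j1 = gamma_i[k - 1], gamma_j[k - 1]
        for ii in range(i0, i1 + 1):
            if i1 == i0:
                gamma[ii] = j1
            else:
                gamma[ii] = j0 + (j1 - j0) * (ii - i0) / (i1 - i0)
    # extend flat outside the matched window (free-boundary case)
    i_first = gamma_i[m - 1]
    i_last = gamma_i[0]
    for ii in range(0, i_first):
        gamma[ii] = gamma[i_first]
    for ii in range(i_last + 1, n):
        gamma[ii] = gamma[i_last]
    return gamma


@njit(cache=True)
def _backtrack(ptr, ei, ej):
    return _backtrack_steps(ptr, ei, ej, _STEPS)


@njit(cache=True)
def _backtrack_fine(ptr, ei, ej):
    return _backtrack_steps(ptr, ei, ej, _STEPS_FINE)


@njit(cache=True)
def _best_rotation_angle(q1, q2):
    """Angle of the planar rotation of q2 maximizing the inner product."""
    a = 0.0
    b = 0.0
    for i in range(q1.shape[0]):
        a += q1[i, 0] * q2[i, 0] + q1[i, 1] * q2[i, 1]
        b += q1[i, 1] * q2[i, 0] - q1[i, 0] * q2[i, 1]
    return np.arctan2(b, a)


@njit(cache=True)
def _rotate(q, theta):
    out = np.empty_like(q)
    c = np.cos(theta)
    s = np.sin(theta)
    for i in range(q.shape[0]):
        out[i, 0] = c * q[i, 0] - s * q[i, 1]
        out[i, 1] = s * q[i, 0] + c * q[i, 1]
    return out


@njit(cache=True)
def _wrap_extend(q):
    """Append the first sample so a periodic curve spans the full grid."""
    n = q.shape[0]
    out = np.empty((n + 1, 2))
    out[:n] = q
    out[n] = q[0]
    return out


@njit(cache=True)
def _closed_scan(q1, q2, stride, use_rotation):
    """Search cyclic seed shifts (every ``stride``-th vertex) of q2.

    For each candidate the optimal rotation is solved in closed form and a
    DP sweep scores the reparametrization; returns the winning seed, its
    rotation angle and inner product.
    """
    m = q1.shape[0]
    dt = 1.0 / m
    q1e = _wrap_extend(q1)
    best_ip = -2.0
    best_seed = 0
    best_theta = 0.0
    for seed in range(0, m, stride):
        q2r = np.empty_like(q2)
        for i in range(m):
            q2r[i] = q2[(i + seed) % m]
        if use_rotation:
            theta = _best_rotation_angle(q1, q2r)
            q2r = _rotate(q2r, theta)
        else:
            theta = 0.0
        q2e = _wrap_extend(q2r)
        ip, _, _, _ = _dp_pass(q1e, q2e, dt, False)
        if ip > best_ip:
            best_ip = ip
            best_seed = seed
            best_theta = theta
    return best_ip, best_seed, best_theta
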