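import numpy as np
import pytest

from elasticshapes import (
    NuisanceSpec,
    Outline,
    align_closed,
    align_open,
    elastic_distance,
    geodesic_path,
    inverse_srvf,
    karcher_mean,
    make_families,
    pairwise_elastic_distances,
    path_energy,
    sample_outline,
    srvf_transform,
    symmetric_transform,
)
from elasticshapes import _dp
from elasticshapes.elastic import SRVFCurve, _inner

from conftest import MODERATE_NUISANCE, circle_outline, ellipse_outline


class TestSRVFTransform:
    def test_translation_invariant(self, families):
        o = families[0].template(100)
        shifted = Outline(o.points + [7.0, -3.0])
        q1 = srvf_transform(o, 80).q
        q2 = srvf_transform(shifted, 80).q
        assert np.abs(q1 - q2).max() < 1e-10

    def test_scale_invariant(self, families):
        o = families[0].template(100)
        scaled = Outline(o.points * 5.0)
        q1 = srvf_transform(o, 80).q
        q2 = srvf_transform(scaled, 80).q
        assert np.abs(q1 - q2).max() < 1e-6

    def test_unit_norm(self, families):
        q = srvf_transform(families[1].template(100), 64)
        assert _inner(q.q, q.q, True) == pytest.approx(1.0, abs=1e-9)

    def test_straight_segment_constant_q(self):
        seg = Outline(np.column_stack([np.linspace(0, 1, 50), np.zeros(50)]), closed=False)
        q = srvf_transform(seg, 40).q
        directions = q / np.linalg.norm(q, axis=1)[:, None]
        np.testing.assert_allclose(directions, np.tile([1.0, 0.0], (40, 1)), atol=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            srvf_transform(Outline(np.array([[0, 0], [1, 0], [0, 1.0]])), 50)


class TestInverseSRVF:
    def test_roundtrip(self, families):
        """Reconstruction inverts the transform: vertex RMSD below 1e-3
        against the identically normalized source polygon."""
        from elasticshapes.outlines import ResampleConfig, resample_arclength

        o = families[2].template(150)
        rec = inverse_srvf(srvf_transform(o, 120))
        src = resample_arclength(o, ResampleConfig(n_points=120)).points
        src = src - src.mean(axis=0)
        src = src / np.sqrt((src**2).sum())
        rmsd = np.sqrt(((src - rec.points) ** 2).mean())
        assert rmsd < 1e-3

    def test_constant_q_gives_straight_segment(self):
        q = SRVFCurve(np.tile([1.0, 0.0], (50, 1)), closed=False)
        out = inverse_srvf(q)
        assert np.abs(out.points[:, 1]).max() < 1e-12
        assert np.all(np.diff(out.points[:, 0]) > 0)

    def test_circle_q_gives_circle(self):
        out = inverse_srvf(srvf_transform(circle_outline(100), 100))
        radii = np.linalg.norm(out.points - out.centroid(), axis=1)
        assert (radii.max() - radii.min()) / radii.mean() < 1e-3


class TestAlignOpen:
    @staticmethod
    def _sine_curve(warp=None, n=100):
        u = np.linspace(0, 1, n)
        w = u if warp is None else warp(u)
        return Outline(np.column_stack([w, 0.3 * np.sin(2 * np.pi * w)]), closed=False)

    def test_identity(self):
        q = srvf_transform(self._sine_curve(), 100)
        m = align_open(q, q)
        assert m.inner_product == pytest.approx(1.0, abs=1e-9)
        assert np.abs(m.gamma - np.linspace(0, 1, 100)).max() < 1e-9

    def test_known_warp_recovered(self):
        base = self._sine_curve()
        warped = self._sine_curve(lambda u: u + 0.08 * np.sin(np.pi * u) ** 2)
        q1 = srvf_transform(base, 100)
        q2 = srvf_transform(warped, 100)
        m = align_open(q1, q2)
        assert m.inner_product >= 0.999

    def test_endpoint_constraint_costs(self):
        """With mismatched endpoint landmarks (a backtracking hook at the
        start), pinning the endpoints yields a strictly worse match than
        letting the boundary slide past the hook."""
        u = np.linspace(0, 1, 100)
        body = np.column_stack([u, 0.2 * np.sin(np.pi * u)])
        a = Outline(body, closed=False)
        hook = np.column_stack([np.linspace(0.3, 0, 20, endpoint=False), np.full(20, -0.1)])
        b = Outline(np.vstack([hook, body]), closed=False)
        qa, qb = srvf_transform(a, 100), srvf_transform(b, 100)
        fixed = align_open(qa, qb, fix_endpoints=True)
        free = align_open(qa, qb, fix_endpoints=False)
        assert fixed.inner_product < free.inner_product - 1e-3

    def test_grid_mismatch_rejected(self):
        qa = srvf_transform(self._sine_curve(), 60)
        qb = srvf_transform(self._sine_curve(), 80)
        with pytest.raises(ValueError):
            align_open(qa, qb)


def _python_dp_oracle(q1e, q2e, dt):
    """Independent pure-python DP over the coarse move set, mirroring the
    kernel's trapezoid scoring (including magnitude-corrected interpolation)."""
    steps = [(1, 1), (1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2)]
    n = q1e.shape[0]
    NEG = -1e18
    val = np.full((n, n), NEG)
    val[0, 0] = 0.0
    mags = np.linalg.norm(q2e, axis=1)

    def q2_at(p):
        jp = int(np.floor(p))
        if jp >= n - 1:
            return q2e[n - 1]
        fr = p - jp
        v = q2e[jp] * (1 - fr) + q2e[jp + 1] * fr
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            lam = (1 - fr) * mags[jp] + fr * mags[jp + 1]
            v = v * (lam / nv)
        return v

    for i in range(1, n):
        for j in range(1, n):
            best = NEG
            for di, dj in steps:
                i0, j0 = i - di, j - dj
                if i0 < 0 or j0 < 0 or val[i0, j0] <= NEG / 2:
                    continue
                s = dj / di
                sq = np.sqrt(s)
                gp = float(q1e[i0] @ q2e[j0]) * sq
                c = 0.0
                for k in range(1, di + 1):
                    g = float(q1e[i0 + k] @ q2_at(j0 + k * s)) * sq
                    c += 0.5 * (gp + g) * dt
                    gp = g
                best = max(best, val[i0, j0] + c)
            val[i, j] = best
    return val[n - 1, n - 1]


class TestAlignClosed:
    def test_identity(self, families):
        q = srvf_transform(families[0].template(100), 64)
        m = align_closed(q, q)
        assert m.distance < 1e-6

    def test_shift_and_rotation_recovered(self, families):
        o = families[1].template(100)
        c, s = np.cos(65 * np.pi / 180), np.sin(65 * np.pi / 180)
        moved = Outline(np.roll(o.points, 17, axis=0) @ np.array([[c, -s], [s, c]]).T)
        q1 = srvf_transform(o, 100)
        q2 = srvf_transform(moved, 100)
        assert align_closed(q1, q2).distance < 1e-2

    def test_ellipse_aspect_ratios(self):
        q1 = srvf_transform(ellipse_outline(2.0), 40)
        q2 = srvf_transform(ellipse_outline(3.0), 40)
        d = align_closed(q1, q2).distance
        assert 0 < d < np.pi

    def test_exhaustive_seed_oracle(self, families):
        """The integer seed scan equals a brute-force enumeration of all
        seeds with rotation + DP scored independently in pure python."""
        o1 = families[0].template(60)
        o2 = sample_outline(families[0], MODERATE_NUISANCE, 60, rng=21)
        q1 = srvf_transform(o1, 40)
        q2 = srvf_transform(o2, 40)
        a1, a2 = q1.q, q2.q
        m = 40
        best = (-2.0, None)
        for seed in range(m):
            rolled = np.roll(a2, -seed, axis=0)
            ang = _dp._best_rotation_angle(a1, rolled)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            rolled = rolled @ R.T
            q1e = np.vstack([a1, a1[:1]])
            q2e = np.vstack([rolled, rolled[:1]])
            ip = _python_dp_oracle(q1e, q2e, 1.0 / m)
            if ip > best[0]:
                best = (ip, seed)
        ip_scan, seed_scan, _ = _dp._closed_scan(a1, a2, 1, True)
        assert seed_scan == best[1]
        assert ip_scan == pytest.approx(best[0], abs=1e-12)
        # the full matcher starts from that optimum and can only improve
        m0 = align_closed(q1, q2, refine=0)
        assert m0.inner_product >= best[0] - 1e-12


class TestElasticDistance:
    def test_self_distance_zero(self, families):
        o = families[3].template(100)
        assert elastic_distance(o, o) < 1e-6

    def test_antipodal_inner_product_maps_to_pi(self):
        q = srvf_transform(circle_outline(80), 60)
        ip = _inner(q.q, -q.q, True)
        assert np.arccos(np.clip(ip, -1, 1)) == pytest.approx(np.pi)

    def test_similarity_invariance(self, families):
        o = families[0].template(100)
        c, s = np.cos(1.2), np.sin(1.2)
        moved = Outline(np.roll(o.points, 31, axis=0) @ np.array([[c, -s], [s, c]]).T * 2.5 + [4, 4])
        assert elastic_distance(o, moved) < 1e-2

    def test_symmetry_and_range(self, families):
        a = sample_outline(families[0], MODERATE_NUISANCE, 100, rng=1)
        b = sample_outline(families[2], MODERATE_NUISANCE, 100, rng=2)
        dab = elastic_distance(a, b, grid_size=50)
        dba = elastic_distance(b, a, grid_size=50)
        assert 0 <= dab <= np.pi
        # directional gap is a lattice-resolution effect, bounded at grid 50
        assert abs(dab - dba) < 0.03
        sym_ab = elastic_distance(a, b, grid_size=50, symmetrize=True)
        sym_ba = elastic_distance(b, a, grid_size=50, symmetrize=True)
        assert sym_ab == pytest.approx(sym_ba, abs=1e-12)

    def test_triangle_inequality_with_slack(self, small_dataset):
        outlines = small_dataset.outlines[:9]
        D = pairwise_elastic_distances(outlines, mode="closed", grid_size=50)
        n = len(outlines)
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(n):
                    if k in (i, j):
                        continue
                    assert D[i, j] <= 1.05 * (D[i, k] + D[k, j]) + 1e-9


class TestGeodesicPath:
    def test_identical_endpoints(self, families):
        o = families[0].template(100)
        gp = geodesic_path(o, o, kappa=3, grid_size=60)
        assert gp.energy == pytest.approx(0.0, abs=1e-9)
        for step in gp.steps:
            assert elastic_distance(step, o, grid_size=60) < 1e-2

    def test_energy_close_to_distance_open(self):
        u = np.linspace(0, 1, 80)
        a = Outline(np.column_stack([u, 0.3 * np.sin(np.pi * u)]), closed=False)
        b = Outline(np.column_stack([u, 0.6 * np.sin(np.pi * u) ** 2]), closed=False)
        gp = geodesic_path(a, b, kappa=5, mode="open", grid_size=60)
        pe = path_energy(gp.steps, mode="open")
        assert gp.energy >= gp.distance - 1e-6
        assert pe <= 1.05 * gp.distance

    def test_midpoint_equidistant(self):
        e1, e2 = ellipse_outline(1.3), ellipse_outline(3.0)
        gp = geodesic_path(e1, e2, kappa=2, mode="closed", grid_size=60)
        mid = gp.steps[1]
        d1 = elastic_distance(e1, mid, grid_size=60)
        d2 = elastic_distance(mid, e2, grid_size=60)
        # 10%: the two measurements carry a directional lattice bias
        assert abs(d1 - d2) <= 0.10 * max(d1, d2)

    def test_kappa_validated(self, families):
        with pytest.raises(ValueError):
            geodesic_path(families[0].template(60), families[1].template(60), kappa=1)


class TestPathEnergy:
    def test_identical_steps_zero(self, families):
        o = families[0].template(80)
        assert path_energy([o, o]) < 1e-6

    def test_permuted_interior_not_shorter(self):
        e1, e2 = ellipse_outline(1.3), ellipse_outline(2.8)
        gp = geodesic_path(e1, e2, kappa=4, mode="closed", grid_size=50)
        straight = path_energy(gp.steps, mode="closed")
        shuffled = [gp.steps[i] for i in (0, 3, 1, 2, 4)]
        assert path_energy(shuffled, mode="closed") >= straight - 1e-9

    def test_single_step_rejected(self, families):
        with pytest.raises(ValueError):
            path_energy([families[0].template(60)])


class TestKarcherMean:
    def test_copies_converge_immediately(self):
        e = ellipse_outline(1.8)
        km = karcher_mean([e] * 4, mode="closed", grid_size=50)
        assert km.iterations == 1
        assert km.final_gradient_norm < 1e-9
        assert elastic_distance(km.mean_outline, e, grid_size=50) < 1e-2

    def test_two_shapes_mean_is_midpoint(self):
        e1, e2 = ellipse_outline(1.3), ellipse_outline(3.0)
        km = karcher_mean([e1, e2], mode="closed", grid_size=60)
        mid = geodesic_path(e1, e2, kappa=2, mode="closed", grid_size=60).steps[1]
        assert elastic_distance(km.mean_outline, mid, grid_size=60) < 1e-2
        d1 = elastic_distance(e1, km.mean_outline, grid_size=60)
        d2 = elastic_distance(e2, km.mean_outline, grid_size=60)
        assert abs(d1 - d2) <= 0.10 * max(d1, d2)

    def test_mean_aspect_ratio_between(self):
        km = karcher_mean([ellipse_outline(1.5), ellipse_outline(2.5)], mode="closed", grid_size=50)
        pts = km.mean_outline.points - km.mean_outline.centroid()
        width = pts[:, 0].max() - pts[:, 0].min()
        height = pts[:, 1].max() - pts[:, 1].min()
        ratio = max(width, height) / min(width, height)
        assert 1.5 <= ratio <= 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            karcher_mean([])


class TestSymmetricTransform:
    @staticmethod
    def _vase(a):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = 1 + a * np.cos(2 * t) + 0.1 * np.cos(4 * t)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)]) @ np.array([[0, -1], [1, 0.0]]).T
        return Outline(pts)

    @staticmethod
    def _mirror_mismatch(o):
        from scipy.spatial import cKDTree

        pts = o.points - o.centroid()
        d, _ = cKDTree(pts).query(pts * [-1, 1])
        return d.max()

    def test_circles_of_different_radius(self):
        st = symmetric_transform(circle_outline(120, 1.0), circle_outline(120, 2.0), kappa=3, grid_size=50)
        for step in st.steps:
            assert self._mirror_mismatch(step) < 1e-6

    def test_vase_templates_all_steps_symmetric(self):
        st = symmetric_transform(self._vase(0.15), self._vase(0.35), kappa=4, grid_size=50)
        assert len(st.steps) == 5
        for step in st.steps:
            assert self._mirror_mismatch(step) < 1e-6
        assert elastic_distance(st.steps[0], self._vase(0.15), grid_size=50) < 0.05
        assert elastic_distance(st.steps[-1], self._vase(0.35), grid_size=50) < 0.05

    def test_asymmetric_input_rejected(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        r = 1 + 0.3 * np.exp(-((t - np.pi / 4) ** 2) / 0.05)
        bumpy = Outline(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        with pytest.raises(ValueError):
            symmetric_transform(bumpy, circle_outline(100))
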