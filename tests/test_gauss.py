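import math

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from swrithe import gauss
from swrithe.curves import DiscreteCurve, make_helix, make_random_walk, make_trefoil

from conftest import passage_curve, random_rotation


# -- independent quadrature oracle for omega --------------------------------

def _composite_nodes(n_cells=8, order=24):
    xg, wg = leggauss(order)
    nodes, weights = [], []
    for k in range(n_cells):
        a, b = k / n_cells, (k + 1) / n_cells
        nodes.append(0.5 * (b - a) * (xg + 1.0) + a)
        weights.append(0.5 * (b - a) * wg)
    return np.concatenate(nodes), np.concatenate(weights)


_XG, _WG = _composite_nodes()


def segment_distance(p1, p2, p3, p4, samples=200):
    """Minimum distance between two segments (dense parameter sampling)."""
    t = np.linspace(0.0, 1.0, samples)
    a = p1 + t[:, None] * (p2 - p1)
    b = p3 + t[:, None] * (p4 - p3)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def omega_quadrature(p1, p2, p3, p4):
    """Composite Gauss-Legendre quadrature of the linking integrand."""
    r12 = p2 - p1
    r34 = p4 - p3
    s = _XG[:, None, None]
    t = _XG[None, :, None]
    x = (p1 + s * r12) - (p3 + t * r34)
    num = np.einsum("k,ijk->ij", np.cross(r12, r34), x)
    den = np.linalg.norm(x, axis=2) ** 3
    return float(np.einsum("i,j,ij->", _WG, _WG, num / den))


class TestOmega:
    def test_shared_endpoint_zero(self):
        p = np.array([0.0, 0, 0])
        assert gauss.omega(p, [1, 0, 0], [1, 0, 0], [1, 1, 0]) == 0.0

    def test_parallel_coplanar_zero(self):
        assert gauss.omega([0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]) == 0.0

    def test_degenerate_edge_rejected(self):
        with pytest.raises(ValueError):
            gauss.omega([0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_matches_quadrature_on_random_pairs(self, rng):
        checked = 0
        while checked < 100:
            p = rng.standard_normal((4, 3)) * 3.0
            p[2:] += np.array([4.0, 0.0, 0.0])
            if segment_distance(p[0], p[1], p[2], p[3]) < 0.5:
                continue  # quadrature cannot resolve near-singular pairs
            assert gauss.omega(*p) == pytest.approx(omega_quadrature(*p), abs=1e-6)
            checked += 1

    def test_antisymmetric_under_mirror(self, rng):
        p = rng.standard_normal((4, 3))
        p[2:] += 2.0
        q = p.copy()
        q[:, 0] *= -1
        assert gauss.omega(*q) == pytest.approx(-gauss.omega(*p), abs=1e-12)


class TestWritheAcn:
    def test_minimum_points(self):
        short = DiscreteCurve(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], float))
        with pytest.raises(ValueError, match="at least 5"):
            gauss.writhe(short)
        with pytest.raises(ValueError, match="at least 5"):
            gauss.acn(short)

    def test_planar_curve_zero(self, rng):
        pts = np.column_stack([rng.standard_normal(20) * 5,
                               rng.standard_normal(20) * 5,
                               np.zeros(20)])
        c = DiscreteCurve(pts)
        assert gauss.writhe(c) == pytest.approx(0.0, abs=1e-10)

    def test_straight_line_acn_zero(self):
        line = DiscreteCurve(np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)]))
        assert gauss.acn(line) == 0.0

    def test_acn_dominates_writhe(self, trefoil, walk30):
        for c in (trefoil, walk30):
            assert gauss.acn(c) >= abs(gauss.writhe(c)) - 1e-12

    def test_uniform_helix_acn_bounds_writhe(self):
        # numerical check shows inter-turn crossings of a discrete helix
        # carry both signs, so acn strictly exceeds |wr|; the unsigned
        # projection oracle (below) confirms the acn value itself.
        h = make_helix(7.58, 5.98, 20, 6)
        assert gauss.acn(h) > abs(gauss.writhe(h))
        est = gauss.mc_projection_estimate(h, 800, seed=6)
        assert abs(est.acn - gauss.acn(h)) <= 3 * est.acn_se

    def test_rigid_motion_invariance(self, walk30, rng):
        q = random_rotation(rng)
        moved = walk30.transformed(rotation=q, translation=[12.0, -3.0, 7.0])
        assert gauss.writhe(moved) == pytest.approx(gauss.writhe(walk30), abs=1e-10)
        assert gauss.acn(moved) == pytest.approx(gauss.acn(walk30), abs=1e-10)

    def test_scale_invariance(self, walk30):
        scaled = walk30.transformed(scale=13.7)
        assert gauss.writhe(scaled) == pytest.approx(gauss.writhe(walk30), abs=1e-10)
        assert gauss.acn(scaled) == pytest.approx(gauss.acn(walk30), abs=1e-10)

    def test_reversal_invariance(self, walk30):
        assert gauss.writhe(walk30.reversed()) == pytest.approx(
            gauss.writhe(walk30), abs=1e-10
        )

    def test_strand_passage_jumps_by_two(self):
        before = gauss.writhe(passage_curve(-8.6))
        after = gauss.writhe(passage_curve(-9.1))
        assert abs(after - before) == pytest.approx(2.0, abs=0.3)


class TestFingerprint:
    def test_too_short(self):
        c = DiscreteCurve(np.column_stack([np.arange(5.0), np.zeros(5), np.arange(5.0) ** 2]))
        with pytest.raises(ValueError):
            gauss.fingerprint(c)

    def test_whole_curve_entry_matches_writhe(self, walk30):
        fp = gauss.fingerprint(walk30)
        assert fp.wr(1, 30) == pytest.approx(gauss.writhe(walk30), abs=1e-10)
        assert fp.acn(1, 30) == pytest.approx(gauss.acn(walk30), abs=1e-10)

    def test_all_entries_match_slice_oracle(self, walk30):
        fp = gauss.fingerprint(walk30)
        j = walk30.n_points
        for i in range(1, j - 4):
            for n in range(i + 5, j + 1):
                sub = walk30.sliced(i - 1, n - 1)
                assert fp.wr(i, n) == pytest.approx(gauss.writhe(sub), abs=1e-10)
                assert fp.acn(i, n) == pytest.approx(gauss.acn(sub), abs=1e-10)

    def test_acn_entry_dominates_writhe_entry(self, walk30):
        fp = gauss.fingerprint(walk30)
        for i, n, wr, ac in fp.items():
            assert ac >= abs(wr) - 1e-12

    def test_undefined_below_min_span(self, walk30):
        fp = gauss.fingerprint(walk30)
        with pytest.raises(KeyError):
            fp.wr(1, 5)

    def test_helix_profile_nearly_linear(self, coarse_helix):
        ns, wr = gauss.fingerprint(coarse_helix).profile()
        slope, intercept = np.polyfit(ns, wr, 1)
        resid = wr - (slope * ns + intercept)
        assert np.abs(resid).max() < 0.15 * abs(wr[-1])

    def test_csv_export(self, walk30):
        text = gauss.fingerprint(walk30).to_csv()
        assert text.splitlines()[0] == "i,n,wr,acn"
        assert len(text.splitlines()) == 1 + sum(1 for _ in gauss.fingerprint(walk30).items())


class TestProjectionOracle:
    def test_straight_line_exact_zero(self):
        line = DiscreteCurve(np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)]))
        est = gauss.mc_projection_estimate(line, 200, seed=0)
        assert est.writhe == 0.0 and est.acn == 0.0

    def test_helix_unsigned_matches_acn(self):
        h = make_helix(7.58, 5.98, 10, 5)
        est = gauss.mc_projection_estimate(h, 800, seed=2)
        assert abs(est.acn - gauss.acn(h)) <= 3 * max(est.acn_se, 1e-12)

    def test_trefoil_signed_matches_writhe(self, trefoil):
        est = gauss.mc_projection_estimate(trefoil, 600, seed=4)
        assert abs(est.writhe - gauss.writhe(trefoil)) <= 3 * est.writhe_se

    def test_walk_agreement(self):
        w = make_random_walk(40, 1.0, seed=17)
        est = gauss.mc_projection_estimate(w, 800, seed=5)
        assert abs(est.writhe - gauss.writhe(w)) <= 3 * max(est.writhe_se, 1e-12)
        assert abs(est.acn - gauss.acn(w)) <= 3 * max(est.acn_se, 1e-12)

    def test_reproducible(self, walk30):
        a = gauss.mc_projection_estimate(walk30, 200, seed=9)
        b = gauss.mc_projection_estimate(walk30, 200, seed=9)
        assert a == b
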