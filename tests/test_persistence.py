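"""Persistence computation: worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from persig import (PersistenceDiagram, compute_diagram,
                    naive_cech_persistence, naive_rips_persistence,
                    read_diagram, select_noise_candidates, write_diagram)
from persig.oracle import miniball_radius


def dist(points):
    return squareform(pdist(points))


def positive_part(dgm, decimals=9):
    """Multiset of features with genuinely positive persistence, plus H0."""
    rows = dgm.as_multiset(decimals)
    return tuple(r for r in rows
                 if r[0] == 0 or (r[2] - r[1]) > 10 ** -decimals)


class TestWorkedExamples:
    def test_unit_square_rips(self, unit_square):
        dgm = compute_diagram(unit_square, "rips", max_degree=1)
        h1 = dgm.of_degree(1)
        real = (h1.deaths - h1.births) > 1e-12
        assert real.sum() == 1
        b, d = h1.births[real][0], h1.deaths[real][0]
        # radius scale: the loop closes at half the side, fills at half
        # the diagonal; pi = sqrt(2) regardless of the scale convention
        assert np.isclose(b, 0.5) and np.isclose(d, np.sqrt(2) / 2)
        assert np.isclose(d / b, np.sqrt(2))

    def test_unit_square_cech(self, unit_square):
        dgm = compute_diagram(unit_square, "cech", max_degree=1)
        h1 = dgm.of_degree(1)
        real = (h1.deaths - h1.births) > 1e-12
        assert real.sum() == 1
        b, d = h1.births[real][0], h1.deaths[real][0]
        assert np.isclose(b, 0.5) and np.isclose(d, np.sqrt(2) / 2)
        assert np.isclose(d / b, np.sqrt(2))

    def test_equilateral_triangle_has_no_persistent_loop(self):
        ang = 2 * np.pi * np.arange(3) / 3
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        dgm = compute_diagram(pts, "rips", max_degree=1)
        h1 = dgm.of_degree(1)
        assert np.all(h1.deaths - h1.births < 1e-12)

    def test_two_points_h0_pair(self):
        dm = np.array([[0.0, 2.0], [2.0, 0.0]])
        dgm = naive_rips_persistence(dm, max_degree=0)
        h0 = dgm.of_degree(0)
        assert sorted(h0.deaths.tolist()) == [1.0, np.inf]
        assert np.all(h0.births == 0.0)

    def test_h0_count_is_n_minus_one_plus_essential(self):
        rng = np.random.default_rng(5)
        pts = rng.random((12, 2))
        dgm = compute_diagram(pts, "rips", max_degree=0)
        h0 = dgm.of_degree(0)
        assert np.isfinite(h0.deaths).sum() == 11
        assert np.isinf(h0.deaths).sum() == 1

    def test_truncated_circle_reports_open_cycle(self, circle_points):
        dgm = compute_diagram(circle_points, "rips", max_degree=1,
                              threshold=0.3)
        h1 = dgm.of_degree(1)
        assert np.isinf(h1.deaths).sum() == 1
        assert h1.births[np.isinf(h1.deaths)][0] < 0.2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_fast_rips_equals_reduction_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 26))
        d = 2 + seed % 2
        pts = rng.random((n, d))
        a = compute_diagram(pts, "rips", max_degree=d - 1)
        b = naive_rips_persistence(dist(pts), max_degree=d - 1)
        assert a.as_multiset() == b.as_multiset()

    @pytest.mark.parametrize("seed", range(6))
    def test_alpha_matches_miniball_cech(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 22))
        d = 2 + seed % 2
        pts = rng.random((n, d))
        a = compute_diagram(pts, "cech", max_degree=d - 1)
        b = naive_cech_persistence(pts, max_degree=d - 1)
        # the alpha complex is a subcomplex of the Cech complex: the
        # positive-persistence content agrees; zero-persistence pairs are
        # construction artifacts and differ
        assert positive_part(a) == positive_part(b)

    def test_thresholded_rips_agrees_with_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.random((15, 2))
        for tau in (0.1, 0.25, 0.5):
            a = compute_diagram(pts, "rips", max_degree=1, threshold=tau)
            b = naive_rips_persistence(dist(pts), 1, threshold=tau)
            assert a.as_multiset() == b.as_multiset()

    def test_distance_matrix_input_equals_point_input(self):
        rng = np.random.default_rng(4)
        pts = rng.random((18, 3))
        a = compute_diagram(pts, "rips", max_degree=1)
        b = compute_diagram(dist(pts), "rips", max_degree=1)
        assert a.as_multiset() == b.as_multiset()


class TestInvariants:
    @pytest.mark.parametrize("filtration", ["rips", "cech"])
    @pytest.mark.parametrize("c", [0.01, 100.0])
    def test_scale_equivariance(self, filtration, c):
        rng = np.random.default_rng(7)
        pts = rng.random((30, 2))
        base = compute_diagram(pts, filtration, max_degree=1)
        scaled = compute_diagram(pts * c, filtration, max_degree=1)
        assert np.allclose(np.sort(base.births) * c,
                           np.sort(scaled.births), rtol=1e-9)
        fin_b = np.sort(base.deaths[base.finite_mask]) * c
        fin_s = np.sort(scaled.deaths[scaled.finite_mask])
        assert np.allclose(fin_b, fin_s, rtol=1e-9)

    def test_monotonicity_in_threshold(self):
        rng = np.random.default_rng(11)
        pts = rng.random((25, 2))
        small = compute_diagram(pts, "rips", max_degree=1, threshold=0.15)
        large = compute_diagram(pts, "rips", max_degree=1, threshold=0.4)

        def finished(dgm, tau):
            return sorted((k, b, d) for k, b, d in zip(
                dgm.degrees, dgm.births, dgm.deaths) if d <= tau)

        sub = finished(small, 0.15)
        sup = finished(large, 0.4)
        for row in sub:
            assert row in sup

    def test_miniball_against_brute_force_circumradius(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pts = rng.random((4, 3))
            r = miniball_radius(pts)
            center_free = pts.mean(axis=0)
            # every point is enclosed
            assert np.all(np.linalg.norm(pts - center_free, axis=1).max()
                          >= r - 1e-9)
            # r is achievable: some point lies on the boundary of any
            # enclosing ball of radius r; verify via direct minimization
            from scipy.optimize import minimize
            res = minimize(lambda c: np.max(
                np.linalg.norm(pts - c, axis=1)), center_free,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
            assert r <= res.fun + 1e-6

    def test_naive_cap(self):
        dm = np.zeros((70, 70))
        with pytest.raises(ValueError, match="capped"):
            naive_rips_persistence(dm, 1)


class TestDiagramIO:
    def test_round_trip(self, tmp_path):
        dgm = PersistenceDiagram([1, 1, 2], [0.2, 0.5, 0.3],
                                 [0.3, np.inf, 0.9], "cech", np.inf, 10)
        path = tmp_path / "dgm.csv"
        write_diagram(dgm, path)
        back = read_diagram(path, "cech")
        assert back.as_multiset() == dgm.as_multiset()

    def test_inf_token(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("degree,birth,death\n1,0.5,inf\n")
        dgm = read_diagram(path)
        assert len(dgm) == 1 and np.isinf(dgm.deaths[0])

    def test_malformed_rows_name_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("degree,birth,death\n1,0.1,0.2\n1,2.0,1.0\n")
        with pytest.raises(ValueError, match="row 2"):
            read_diagram(path)
        path.write_text("degree,birth,death\n1,-0.1,0.2\n")
        with pytest.raises(ValueError, match="row 1"):
            read_diagram(path)

    def test_select_noise_candidates(self):
        dgm = PersistenceDiagram([1, 1, 1, 2], [0.2, 0.4, 0.5, 0.1],
                                 [0.3, 0.4, np.inf, 0.2])
        finite, infinite = select_noise_candidates(dgm, 1)
        assert finite.as_multiset() == (((1, 0.2, 0.3)),)
        assert infinite.as_multiset() == (((1, 0.5, np.inf)),)
        with pytest.raises(ValueError):
            select_noise_candidates(dgm, 0)
        empty_f, empty_i = select_noise_candidates(dgm.of_degree(3), 3)
        assert len(empty_f) == 0 and len(empty_i) == 0


class TestValidation:
    def test_cech_rejects_distance_matrix(self):
        dm = dist(np.random.default_rng(0).random((8, 2)))
        with pytest.raises(ValueError, match="coordinates"):
            compute_diagram(dm, "cech", max_degree=1)

    def test_bad_distance_matrix(self):
        from persig.diagrams import validate_distance_matrix
        with pytest.raises(ValueError):
            validate_distance_matrix(np.ones((3, 3)))      # nonzero diag
        asym = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            validate_distance_matrix(asym)

    def test_nonfinite_coordinates_rejected(self):
        pts = np.array([[0.0, np.inf], [1.0, 1.0]])
        with pytest.raises(ValueError):
            compute_diagram(pts, "rips", max_degree=1)
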