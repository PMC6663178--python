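"""Rips filtration and barcode computation against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import looplight as ll
from looplight.errors import InvalidDistanceError, InvalidFiltrationError
from looplight.persistence import INF, FiltrationSimplex

from oracles import barcode_as_tuples, naive_rips_barcode, single_linkage_merge_heights


def random_dist(rng, n):
    pts = rng.standard_normal((n, 3))
    return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))


class TestFiltration:
    @pytest.mark.parametrize("n, expected", [(3, 7), (12, 298)])
    def test_simplex_counts(self, rng, n, expected):
        filt = ll.rips_filtration(random_dist(rng, n))
        assert len(filt) == expected

    def test_triangle_value_is_max_edge(self, rng):
        d = random_dist(rng, 6)
        filt = ll.rips_filtration(d)
        for s in filt:
            if s.dim == 2:
                i, j, k = s.vertices
                assert s.value == max(d[i, j], d[i, k], d[j, k])

    def test_faces_precede_cofaces(self, rng):
        filt = ll.rips_filtration(random_dist(rng, 7))
        pos = {s.vertices: i for i, s in enumerate(filt)}
        from itertools import combinations

        for s in filt:
            if s.dim > 0:
                for face in combinations(s.vertices, s.dim):
                    assert pos[face] < pos[s.vertices]

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InvalidDistanceError):
            ll.rips_filtration(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(InvalidDistanceError):
            ll.rips_filtration(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_bad_ordering_rejected(self):
        edge = FiltrationSimplex((0, 1), 1, 0.5)
        with pytest.raises(InvalidFiltrationError):
            ll.compute_barcode([edge, FiltrationSimplex((0,), 0, 0.0), FiltrationSimplex((1,), 0, 0.0)])


class TestKnownShapes:
    def test_unit_square_loop(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        loops = ll.rips_barcode(d).in_dim(1)
        assert len(loops) == 1
        assert np.isclose(loops[0].birth, 1.0, atol=1e-9)
        assert np.isclose(loops[0].death, np.sqrt(2), atol=1e-9)

    def test_equilateral_triangle_no_loop(self):
        d = ll.make_circle_points(3).distance_matrix()
        assert ll.rips_barcode(d).n_loops == 0

    @pytest.mark.parametrize("n", [12, 15, 18])
    def test_regular_ngon_single_loop_birth(self, n):
        d = ll.make_circle_points(n).distance_matrix()
        loops = ll.rips_barcode(d).in_dim(1)
        assert len(loops) == 1
        assert np.isclose(loops[0].birth, 2 * np.sin(np.pi / n), atol=1e-9)
        assert loops[0].death > loops[0].birth

    def test_two_points(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        bc = ll.rips_barcode(d)
        deaths = [iv.death for iv in bc.in_dim(0) if np.isfinite(iv.death)]
        assert deaths == [3.0]
        assert ll.h0_mst_oracle(d) == [3.0]

    def test_collinear_points_merge_order(self):
        # points at 0, 1, 3: nearest pair merges first, then distance-2 merge
        x = np.array([0.0, 1.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        assert ll.h0_mst_oracle(d) == [1.0, 2.0]
        deaths = sorted(iv.death for iv in ll.rips_barcode(d).in_dim(0) if np.isfinite(iv.death))
        assert deaths == [1.0, 2.0]


class TestOracleAgreement:
    def test_h0_deaths_match_mst_on_200_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            d = random_dist(rng, 10)
            bc = ll.rips_barcode(d, max_dim=0)
            deaths = sorted(iv.death for iv in bc.in_dim(0) if np.isfinite(iv.death))
            assert np.allclose(deaths, ll.h0_mst_oracle(d), atol=1e-9)

    def test_h0_deaths_match_single_linkage(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = random_dist(rng, 12)
            deaths = sorted(iv.death for iv in ll.rips_barcode(d).in_dim(0) if np.isfinite(iv.death))
            assert np.allclose(deaths, single_linkage_merge_heights(d), atol=1e-9)

    def test_full_barcode_matches_naive_reduction(self):
        rng = np.random.default_rng(11)
        for n in (4, 6, 8, 10):
            for _ in range(10):
                d = random_dist(rng, n)
                ours = barcode_as_tuples(ll.rips_barcode(d))
                oracle = naive_rips_barcode(d)
                assert len(ours) == len(oracle)
                for a, b in zip(ours, oracle):
                    assert a[0] == b[0]
                    assert np.isclose(a[1], b[1], atol=1e-9)
                    assert (a[2] == b[2] == INF) or np.isclose(a[2], b[2], atol=1e-9)

    def test_fast_and_generic_routes_agree(self):
        rng = np.random.default_rng(3)
        for n in (5, 9, 14, 18):
            d = random_dist(rng, n)
            fast = barcode_as_tuples(ll.rips_barcode(d))
            generic = barcode_as_tuples(ll.compute_barcode(ll.rips_filtration(d)))
            assert fast == generic


class TestInvariants:
    def test_exactly_one_essential_component(self, rng):
        d = random_dist(rng, 9)
        bc = ll.rips_barcode(d)
        essential = [iv for iv in bc.intervals if iv.death == INF]
        assert len(essential) == 1 and essential[0].dim == 0

    def test_h0_count_before_filtering(self, rng):
        # n-1 finite deaths + 1 essential = n intervals per vertex
        d = random_dist(rng, 9)
        bc = ll.rips_barcode(d)
        assert len(bc.in_dim(0)) == 9  # generic: no zero-persistence drops

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=50.0),
    )
    def test_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        d = random_dist(rng, 8)
        base = ll.rips_barcode(d)
        scaled = ll.rips_barcode(c * d)
        assert len(base.intervals) == len(scaled.intervals)
        for a, b in zip(base.intervals, scaled.intervals):
            assert a.dim == b.dim
            assert np.isclose(b.birth, c * a.birth, atol=1e-9 * max(1, c))
            if np.isfinite(a.death):
                assert np.isclose(b.death, c * a.death, rtol=1e-9)
            else:
                assert b.death == INF

    def test_permutation_invariance(self, rng):
        d = random_dist(rng, 10)
        perm = rng.permutation(10)
        a = barcode_as_tuples(ll.rips_barcode(d))
        b = barcode_as_tuples(ll.rips_barcode(d[np.ix_(perm, perm)]))
        assert np.allclose(np.array(a), np.array(b), atol=1e-12)

    def test_stability_under_perturbation(self):
        """Bottleneck-type stability: eps-perturbed distances move matched
        interval endpoints by at most eps (checked by optimal matching)."""
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(5)
        eps = 1e-3
        for _ in range(20):
            d = random_dist(rng, 6)
            noise = rng.uniform(-eps, eps, size=d.shape)
            noise = 0.5 * (noise + noise.T)
            np.fill_diagonal(noise, 0.0)
            d2 = np.maximum(d + noise, 0.0)
            for dim in (0, 1):
                a = [(iv.birth, iv.death) for iv in ll.rips_barcode(d).in_dim(dim) if np.isfinite(iv.death)]
                b = [(iv.birth, iv.death) for iv in ll.rips_barcode(d2).in_dim(dim) if np.isfinite(iv.death)]
                # pad with diagonal projections so counts match
                size = len(a) + len(b)
                if size == 0:
                    continue
                cost = np.zeros((size, size))
                big = 1e6
                for i in range(size):
                    for j in range(size):
                        if i < len(a) and j < len(b):
                            cost[i, j] = max(abs(a[i][0] - b[j][0]), abs(a[i][1] - b[j][1]))
                        elif i < len(a):
                            cost[i, j] = (a[i][1] - a[i][0]) / 2 if j == len(b) + i else big
                        elif j < len(b):
                            cost[i, j] = (b[j][1] - b[j][0]) / 2 if i == len(a) + j else big
                        else:
                            cost[i, j] = 0.0
                rows, cols = linear_sum_assignment(cost)
                assert cost[rows, cols].max() <= eps + 1e-9
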