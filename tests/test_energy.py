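"""Gibbs energy terms: data energy ramp, overlap prior, totals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import diffregion as dr
from diffregion import (
    Configuration,
    EnergyParams,
    MarkedPoint,
    contrast_score,
    data_energy,
    pair_penalty,
    point_energy,
    prior_energy,
    region_counts,
    total_energy,
)


def make_pair(counts_a, counts_b, n=10**6):
    a = dr.CountTrack("t", 0, np.asarray(counts_a), n)
    b = dr.CountTrack("t", 0, np.asarray(counts_b), n)
    return dr.TrackPair(a=a, b=b)


@pytest.fixture
def params():
    return EnergyParams()


class TestRegionCounts:
    def test_constant_track(self, params):
        pair = make_pair(np.full(100, 2), np.full(100, 3))
        assert region_counts(pair, MarkedPoint(10, 10)) == (20, 30)

    def test_all_zero(self, params):
        pair = make_pair(np.zeros(50), np.zeros(50))
        assert region_counts(pair, MarkedPoint(0, 50)) == (0, 0)

    def test_partial_sum(self, params):
        pair = make_pair([1, 2, 3], [0, 0, 0])
        assert region_counts(pair, MarkedPoint(0, 2)) == (3, 0)

    def test_out_of_bounds(self, params):
        pair = make_pair(np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            region_counts(pair, MarkedPoint(5, 10))


class TestContrastScore:
    def test_flat_flanks_give_full_region_z(self, params):
        """Strong DE region with identical flanks: d_z ~ |z(region)|."""
        ca = np.full(200, 5)
        cb = np.full(200, 5)
        cb[80:120] = 80
        pair = make_pair(ca, cb)
        point = MarkedPoint(80, 40)
        c1, c2 = region_counts(pair, point)
        z_region = abs(dr.zscore(c1, c2, 10**6, 10**6).z)
        d = contrast_score(pair, point, params)
        assert d == pytest.approx(z_region, rel=0.02)

    def test_equally_de_flanks_scale_by_one_minus_wn(self, params):
        """Region and pooled flanks equally DE with equal z: d_z = (1-w_n)|z|."""
        ca = np.full(300, 5)
        cb = np.full(300, 5)
        cb[100:200] = 40  # region of 50 plus 25-nt flanks on each side all DE
        pair = make_pair(ca, cb)
        point = MarkedPoint(125, 50)  # flanks [100,125) and [175,200): same rates
        c1, c2 = region_counts(pair, point)
        z = abs(dr.zscore(c1, c2, 10**6, 10**6).z)
        d = contrast_score(pair, point, params)
        assert d == pytest.approx((1 - params.w_n) * z, rel=0.02)

    def test_track_edge_uses_right_flank_only(self, params):
        ca = np.full(100, 2)
        cb = np.full(100, 2)
        cb[0:30] = 30
        cb[30:55] = 10  # the only flank
        pair = make_pair(ca, cb)
        point = MarkedPoint(0, 30)
        c1, c2 = region_counts(pair, point)
        z_r = abs(dr.zscore(c1, c2, 10**6, 10**6).z)
        fr1 = int(pair.a.counts[30:55].sum())
        fr2 = int(pair.b.counts[30:55].sum())
        z_n = abs(dr.zscore(fr1, fr2, 10**6, 10**6).z)
        d = contrast_score(pair, point, params)
        assert d == pytest.approx(z_r - params.w_n * z_n, rel=1e-9)


class TestDataEnergy:
    @pytest.mark.parametrize(
        "d_z, expected",
        [(3.0, 1.0), (4.0, 1.0), (40.0, -1.0), (80.0, -1.0), (22.0, -0.5)],
    )
    def test_ramp_values(self, params, d_z, expected):
        assert data_energy(d_z, params) == pytest.approx(expected)

    @given(d=st.floats(-50, 200, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, d):
        p = EnergyParams()
        u = data_energy(d, p)
        assert -1.0 <= u <= 1.0
        assert data_energy(d + 1.0, p) <= u + 1e-12


class TestPairPenalty:
    def test_gap_equal_k_is_zero(self, params):
        p, q = MarkedPoint(0, 100), MarkedPoint(125, 100)  # gap 25 = k
        assert pair_penalty(p, q, params) == 0.0

    def test_identical_regions_full_penalty(self, params):
        p = MarkedPoint(10, 60)
        assert pair_penalty(p, MarkedPoint(10, 60), params) == pytest.approx(1.0)

    def test_known_value(self, params):
        # gap 12, lengths 100/100, k 25: (25-12)/(25+100)
        p, q = MarkedPoint(0, 100), MarkedPoint(112, 100)
        assert pair_penalty(p, q, params) == pytest.approx(13 / 125)

    @given(
        s1=st.integers(0, 500),
        g1=st.integers(5, 200),
        s2=st.integers(0, 500),
        g2=st.integers(5, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, s1, g1, s2, g2):
        p, q = MarkedPoint(s1, g1), MarkedPoint(s2, g2)
        if (s1, g1) == (s2, g2):
            return
        pp = EnergyParams()
        t = pair_penalty(p, q, pp)
        assert t == pair_penalty(q, p, pp)
        assert 0.0 <= t <= 1.0


class TestPriorEnergy:
    def test_single_region_zero(self, params):
        p = MarkedPoint(50, 30)
        assert prior_energy(Configuration([p]), p, params) == 0.0

    def test_stacked_regions_near_full_penalty(self, params):
        p, q = MarkedPoint(50, 30), MarkedPoint(51, 30)
        cfg = Configuration([p, q])
        assert prior_energy(cfg, p, params) == pytest.approx((25 + 29) / (25 + 30))
        assert prior_energy(cfg, q, params) == pytest.approx((25 + 29) / (25 + 30))

    def test_far_neighbour_unpenalized(self, params):
        cfg2 = Configuration([MarkedPoint(50, 30), MarkedPoint(50 + 30 + 30, 30)])
        # gap 30 >= k: unpenalized
        assert prior_energy(cfg2, MarkedPoint(50, 30), params) == 0.0

    def test_max_rule_over_neighbours(self, params):
        p = MarkedPoint(100, 50)
        near = MarkedPoint(160, 50)  # gap 10 -> (25-10)/(25+50) = 0.2
        nearer = MarkedPoint(155, 50)  # gap 5 -> 20/75
        cfg = Configuration([p, near, nearer])
        assert prior_energy(cfg, p, params) == pytest.approx(20 / 75)


class TestTotalEnergy:
    def test_empty_configuration_zero(self, params):
        pair = make_pair(np.ones(100), np.ones(100))
        assert total_energy(pair, Configuration(), params) == 0.0

    def test_good_isolated_region_negative(self, params):
        ca = np.full(400, 2)
        cb = np.full(400, 2)
        cb[100:300] = 40
        pair = make_pair(ca, cb)
        p = MarkedPoint(100, 200)
        cfg = Configuration([p])
        u = total_energy(pair, cfg, params)
        assert u == pytest.approx(-1.0)  # saturated strong region, no neighbours

    def test_additivity_over_points(self, params):
        ca = np.full(600, 2)
        cb = np.full(600, 2)
        cb[50:100] = 30
        cb[300:400] = 30
        pair = make_pair(ca, cb)
        pts = [MarkedPoint(50, 50), MarkedPoint(300, 100)]
        cfg = Configuration(pts)
        total = total_energy(pair, cfg, params)
        parts = sum(point_energy(pair, cfg, p, params) for p in pts)
        assert total == pytest.approx(parts)

    def test_sub_threshold_region_costs_plus_one(self, params):
        pair = make_pair(np.full(200, 3), np.full(200, 3))
        p = MarkedPoint(50, 50)
        cfg = Configuration([p])
        assert total_energy(pair, cfg, params) == pytest.approx(1.0)


class TestDataEnergyTable:
    def test_table_matches_direct_evaluation(self, params):
        rng = np.random.default_rng(7)
        ca = rng.poisson(3, 500)
        cb = rng.poisson(3, 500)
        cb[200:260] += 25
        pair = make_pair(ca, cb)
        starts = np.array([150, 200, 240])
        lengths = {150: np.array([30, 60]), 200: np.array([60]), 240: np.array([20, 100])}
        tab = dr.DataEnergyTable(pair, starts, lengths, params)
        for s, ls in lengths.items():
            for g in ls:
                p = MarkedPoint(int(s), int(g))
                assert tab.d_z(p) == pytest.approx(contrast_score(pair, p, params), rel=1e-9)
                assert tab.u_d(p) == pytest.approx(
                    data_energy(contrast_score(pair, p, params), params), rel=1e-9
                )
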