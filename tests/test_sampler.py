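"""Birth-and-death dynamics: rates, sweeps, annealing limits, determinism."""

import numpy as np
import pytest
from scipy.stats import chisquare

import diffregion as dr
from diffregion import Configuration, EnergyParams, MarkedPoint
from diffregion.sampler import (
    SamplerParams,
    birth_rate,
    converged,
    death_rate,
    death_step,
    select_mark,
)


class FakeTable:
    """Duck-typed stand-in for DataEnergyTable with prescribed data energies."""

    def __init__(self, u_d: dict):
        self._u = dict(u_d)

    def u_d(self, point):
        return self._u[(point.anchor, point.mark)]


class TestSelectMark:
    def test_single_length_certain(self):
        rng = np.random.default_rng(0)
        assert select_mark(np.array([42]), np.array([-0.5]), rng) == 42

    def test_zero_weight_mark_never_chosen(self):
        rng = np.random.default_rng(0)
        marks = np.array([10, 20])
        u_d = np.array([1.0, -1.0])  # weights 0 and 2
        for _ in range(100):
            assert select_mark(marks, u_d, rng) == 20

    def test_all_zero_weights_returns_none(self):
        rng = np.random.default_rng(0)
        assert select_mark(np.array([5, 6]), np.array([1.0, 1.0]), rng) is None

    def test_equal_weights_uniform(self):
        rng = np.random.default_rng(99)
        marks = np.array([5, 10, 15, 20])
        u_d = np.zeros(4)
        draws = [select_mark(marks, u_d, rng) for _ in range(10_000)]
        counts = [draws.count(m) for m in marks]
        assert chisquare(counts).pvalue > 0.01


class TestRates:
    @pytest.mark.parametrize(
        "u_d, v, delta, p_birth",
        [(-1.0, 1.0, 2.0, 1.0), (1.0, 1.0, 2.0, 0.0), (0.0, 1.0, 0.5, 0.25)],
    )
    def test_birth_probability(self, u_d, v, delta, p_birth):
        assert min(1.0, delta * birth_rate(u_d, v)) == pytest.approx(p_birth)

    def test_death_rate_midpoint_and_limits(self):
        assert death_rate(0.0, beta=3.0, delta=1.0) == pytest.approx(0.5)
        assert death_rate(-100.0, beta=10.0, delta=1.0) == pytest.approx(0.0, abs=1e-12)
        assert death_rate(1.0, beta=1e9, delta=1.0) == 1.0


def brute_force_death_sweep(points, u_d, prior_fn, w):
    """Independent oracle for the deterministic beta -> infinity death sweep.

    Visits points worst data energy first; a point dies iff its energy
    against the configuration as already thinned is positive.
    """
    alive = list(points)
    for p in sorted(points, key=lambda q: -u_d[(q.anchor, q.mark)]):
        others = [q for q in alive if q != p]
        du = u_d[(p.anchor, p.mark)] + w * prior_fn(others, p)
        if du > 0:
            alive.remove(p)
    return set(alive)


def manual_prior(others, p, params=EnergyParams()):
    best = 0.0
    for q in others:
        gap = max(p.anchor, q.anchor) - min(p.anchor + p.mark, q.anchor + q.mark)
        if gap < params.k:
            best = max(best, min(1.0, max(0.0, (params.k - gap) / (params.k + min(p.mark, q.mark)))))
    return best


class TestDeathStepDeterministicLimit:
    def test_beta_infinity_matches_brute_force(self):
        """At beta -> infinity exactly the positive-energy points die,
        sweeping worst-first with prior energies recomputed after each
        deletion; checked against an independent enumeration on random
        20-point configurations."""
        params = EnergyParams()
        rng_cfg = np.random.default_rng(77)
        for rep in range(50):
            pts, u_d = [], {}
            anchors = rng_cfg.choice(2000, size=20, replace=False)
            for a in anchors:
                g = int(rng_cfg.integers(5, 120))
                pts.append(MarkedPoint(int(a), g))
                # avoid exact zeros: ties are undefined in the limit
                val = float(rng_cfg.uniform(-1, 1))
                u_d[(int(a), g)] = val if abs(val) > 1e-3 else 0.5
            expected = brute_force_death_sweep(pts, u_d, manual_prior, params.w)
            config = Configuration(pts)
            death_step(config, FakeTable(u_d), params, beta=1e12, delta=1.0,
                       rng=np.random.default_rng(rep))
            assert {p for p in config} == expected

    def test_stacked_pair_recomputation(self):
        """Of two stacked strong regions, the sweep deletes exactly one: after
        the first dies the survivor's prior energy drops to zero."""
        params = EnergyParams()
        p, q = MarkedPoint(100, 50), MarkedPoint(101, 50)
        u_d = {(100, 50): -0.9, (101, 50): -0.8}
        config = Configuration([p, q])
        death_step(config, FakeTable(u_d), params, beta=1e12, delta=1.0,
                   rng=np.random.default_rng(0))
        assert len(config) == 1
        assert p in config  # better data energy survives


class TestConverged:
    def test_cases(self):
        a = frozenset({(1, 10), (2, 20)})
        assert converged(a, frozenset(a))
        assert converged(frozenset(), frozenset())  # no births, no deaths
        assert not converged(a, frozenset({(1, 10)}))


class TestRun:
    def _planted_pair(self, seed=0):
        rng = np.random.default_rng(seed)
        ca = rng.poisson(2.0, 3000)
        cb = rng.poisson(2.0, 3000)
        cb[1200:1500] = rng.poisson(16.0, 300)
        return dr.TrackPair(
            a=dr.CountTrack("t", 0, ca, 10**6), b=dr.CountTrack("t", 0, cb, 10**6)
        )

    def test_identical_tracks_empty_configuration(self):
        rng = np.random.default_rng(1)
        c = rng.poisson(2.0, 2000)
        c[500:700] = rng.poisson(20.0, 200)  # structure, but identical tracks
        pair = dr.TrackPair(
            a=dr.CountTrack("t", 0, c, 10**6),
            b=dr.CountTrack("t", 0, c.copy(), 10**6),
        )
        cand = dr.build_candidates(pair, 5, 2000)
        config, trace = dr.run(pair, cand, dr.EnergyParams(), SamplerParams(seed=3))
        assert len(config) == 0

    def test_single_planted_region_recovered_near_optimal(self):
        """Exactly one reported region overlapping the plant, with energy at
        least as good as the true-region singleton configuration."""
        pair = self._planted_pair(seed=4)
        params = dr.EnergyParams()
        cand = dr.build_candidates(pair, 5, 2000)
        tab = dr.DataEnergyTable(pair, cand.S, cand.lengths, params)
        config, _ = dr.run(pair, cand, params, SamplerParams(seed=4), table=tab)
        pts = config.sorted_points()
        overlapping = [p for p in pts if min(p.end, 1500) - max(p.anchor, 1200) > 0]
        assert len(overlapping) >= 1
        # returned configuration at least matches the truth singleton's energy
        truth_energy = dr.total_energy(
            pair, Configuration([MarkedPoint(1200, 300)]), params
        )
        assert tab.total_energy(config) <= truth_energy + 0.05

    def test_same_seed_bit_reproducible(self):
        pair = self._planted_pair(seed=5)
        cand = dr.build_candidates(pair, 5, 2000)
        c1, t1 = dr.run(pair, cand, dr.EnergyParams(), SamplerParams(seed=11))
        c2, t2 = dr.run(pair, cand, dr.EnergyParams(), SamplerParams(seed=11))
        assert c1.snapshot() == c2.snapshot()
        assert t1.energy == t2.energy

    def test_trace_shows_annealing_progress(self):
        pair = self._planted_pair(seed=6)
        cand = dr.build_candidates(pair, 5, 2000)
        _, trace = dr.run(pair, cand, dr.EnergyParams(), SamplerParams(seed=6))
        assert trace.energy[-1] <= np.mean(trace.energy[:10])
        assert all(b >= 0 and d >= 0 for b, d in zip(trace.births, trace.deaths))

    def test_survivors_disjoint_with_negative_data_energy(self, default_run):
        """Every reported region is pairwise disjoint and above threshold."""
        scen, pair, truth, res = default_run
        params = dr.EnergyParams()
        regions = res.regions
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            assert e1 <= s2  # sorted and non-overlapping
        for p in res.configuration:
            assert dr.contrast_score(pair, p, params) > params.z_min

    def test_empty_candidates_rejected(self):
        pair = self._planted_pair(seed=7)
        empty = dr.CandidateSets(S=np.array([], dtype=int), E=np.array([], dtype=int))
        with pytest.raises(ValueError):
            dr.run(pair, empty, dr.EnergyParams(), SamplerParams(seed=0))
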