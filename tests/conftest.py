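"""Shared fixtures: end-to-end runs are expensive, so run them once per session."""

from __future__ import annotations

import numpy as np
import pytest

import diffregion as dr


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default recovery scenario (three 8-fold regions)."""
    scen = dr.default_scenario(seed=1)
    pair, truth = dr.generate(scen)
    res = dr.detect(pair, sampler_params=dr.SamplerParams(seed=1))
    return scen, pair, truth, res


@pytest.fixture(scope="session")
def proximity_run():
    """Full pipeline on the merge/split scenario with gaps 5, 25, 100 nt."""
    scen = dr.proximity_scenario([5, 25, 100], seed=1)
    pair, truth = dr.generate(scen)
    res = dr.detect(pair, sampler_params=dr.SamplerParams(seed=1))
    return scen, pair, truth, res


@pytest.fixture()
def energy_params():
    return dr.EnergyParams()


def regions_per_pair(res, truth):
    """Number of reported regions overlapping each planted pair's span."""
    ti = truth.intervals()
    out = []
    for i in range(0, len(ti), 2):
        span = (ti[i][0], ti[i + 1][1])
        out.append(
            sum(1 for s, e in res.regions if min(e, span[1]) - max(s, span[0]) > 0)
        )
    return out
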