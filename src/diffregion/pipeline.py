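"""End-to-end detection: smooth, build candidates, sample, score regions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .candidates import CandidateSets, EmptyMarkSpaceError, build_candidates
from .energy import Configuration, DataEnergyTable, EnergyParams, MarkedPoint, region_counts
from .sampler import SamplerParams, SamplerTrace, run
from .stats import RegionStat, zscore
from .tracks import TrackPair

__all__ = ["DetectionResult", "detect"]

logger = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    """Regions surviving the energy minimisation, with their statistics."""

    regions: list[tuple[int, int]] = field(default_factory=list)
    stats: list[RegionStat] = field(default_factory=list)
    configuration: Configuration = field(default_factory=Configuration)
    trace: SamplerTrace = field(default_factory=SamplerTrace)
    candidates: CandidateSets | None = None


def detect(
    pair: TrackPair,
    energy_params: EnergyParams | None = None,
    sampler_params: SamplerParams | None = None,
    n_scales: int = 4,
    edge_threshold: float = 5.0,
    reduce: bool = True,
) -> DetectionResult:
    """Detect differentially expressed regions in a pair of count tracks.

    Runs the full pipeline: wavelet smoothing of both tracks, candidate
    start/end detection (unless ``reduce=False``, which admits every
    position and length), data-energy precomputation, and the annealed
    birth-and-death minimisation.  An empty candidate set — typical when
    the two tracks carry no differential signal strong enough to produce
    sharp smoothed edges — yields an empty result rather than an error.
    """
    eparams = energy_params or EnergyParams()
    sparams = sampler_params or SamplerParams()
    try:
        cand = build_candidates(
            pair,
            eparams.gamma_min,
            eparams.gamma_max,
            n_scales=n_scales,
            t=edge_threshold,
            reduce=reduce,
        )
    except EmptyMarkSpaceError as exc:
        logger.warning("no candidate regions (%s); reporting an empty result", exc)
        return DetectionResult()

    table = DataEnergyTable(pair, cand.S, cand.lengths, eparams)
    config, trace = run(pair, cand, eparams, sparams, table=table)

    points = config.sorted_points()
    regions = [(p.anchor, p.end) for p in points]
    stats = []
    for p in points:
        c1, c2 = region_counts(pair, p)
        stats.append(
            RegionStat(
                c1=c1,
                c2=c2,
                stat=zscore(c1, c2, pair.a.library_total, pair.b.library_total),
            )
        )
    return DetectionResult(
        regions=regions, stats=stats, configuration=config, trace=trace, candidates=cand
    )
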