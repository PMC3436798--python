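"""Multiple birth-and-death dynamics with simulated annealing.

Each iteration alternates a birth sweep and a death sweep over the marked
point configuration.  At every free candidate start a mark is drawn with
probability proportional to ``1 - U_d`` over the allowed lengths, and a
point is born with probability ``min(1, delta * v * b)`` where
``b = (1 - U_d) / 2``.  The death sweep visits points from worst to best
data energy and removes each with probability

    d = delta * a / (1 + delta * a),    a = exp(beta * (U_d + w * U_p)),

recomputing the prior energy against the configuration as deletions
proceed.  The annealing schedule multiplies beta by 1.02 and delta by 0.999
per iteration, so the dynamics becomes deterministic: points with positive
energy die with certainty, points with negative energy survive.  The chain
has converged when an iteration leaves the configuration unchanged — every
birth was undone by a death and vice versa.

Random numbers come from a seeded Mersenne twister (MT19937), making every
run bit-reproducible for a given seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateSets
from .energy import Configuration, DataEnergyTable, EnergyParams, MarkedPoint, prior_energy
from .tracks import TrackPair

__all__ = [
    "SamplerParams",
    "SamplerTrace",
    "select_mark",
    "birth_rate",
    "birth_step",
    "death_rate",
    "death_step",
    "converged",
    "run",
]

logger = logging.getLogger(__name__)

_EXP_CAP = 700.0  # exp() overflow guard; beyond this the death rate is 1


@dataclass(frozen=True)
class SamplerParams:
    """Annealing and discretization parameters.

    ``beta0`` and ``delta0`` initialise the inverse temperature and the
    discretization step; per iteration they are multiplied by
    ``beta_factor`` (1.02) and ``delta_factor`` (0.999).  The birth
    intensity ``v`` is set from the data in the first iteration so that the
    expected number of first-sweep births is ``rho * |S|``; pass
    ``v_override`` to fix it instead.  ``min_gap`` is the reporting gap:
    surviving regions closer than this (or overlapping) are greedily
    resolved, best energy first, before the configuration is returned.

    ``patience`` is the number of consecutive unchanged iterations required
    to declare convergence.  A single unchanged iteration can occur by
    chance during a transient lull while the chain is still reorganising
    (saturated regions tie at the data-energy floor and churn at a
    temperature-independent rate), so demanding a short unchanged streak
    avoids stopping at clearly suboptimal configurations at negligible cost.

    ``restarts`` is the number of independent annealing runs; the final
    configuration with the lowest total energy is returned.  The annealing
    schedule cools quickly, so a single run can freeze into a local
    minimum — typically a long region spanning what is better described by
    several short ones, which ties or nearly ties the short regions'
    energies point-for-point; restarting and keeping the best-energy
    minimum resolves such ties toward the configuration the model actually
    prefers.
    """

    beta0: float = 1.0
    delta0: float = 2.0
    beta_factor: float = 1.02
    delta_factor: float = 0.999
    rho: float = 1.0
    v_override: float | None = None
    max_iter: int = 10_000
    seed: int = 0
    min_gap: int = 0
    patience: int = 10
    restarts: int = 8

    def __post_init__(self) -> None:
        if self.beta0 <= 0 or self.delta0 <= 0:
            raise ValueError("beta0 and delta0 must be positive")
        if self.beta_factor <= 1 or not (0 < self.delta_factor < 1):
            raise ValueError("need beta_factor > 1 and 0 < delta_factor < 1")


@dataclass
class SamplerTrace:
    """Per-iteration diagnostics of one run."""

    iterations: list[int] = field(default_factory=list)
    beta: list[float] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    births: list[int] = field(default_factory=list)
    deaths: list[int] = field(default_factory=list)
    n_points: list[int] = field(default_factory=list)
    energy: list[float] = field(default_factory=list)

    def record(self, it, beta, delta, births, deaths, n_points, energy) -> None:
        self.iterations.append(it)
        self.beta.append(beta)
        self.delta.append(delta)
        self.births.append(births)
        self.deaths.append(deaths)
        self.n_points.append(n_points)
        self.energy.append(energy)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": self.iterations,
                "beta": self.beta,
                "delta": self.delta,
                "births": self.births,
                "deaths": self.deaths,
                "points": self.n_points,
                "energy": self.energy,
            }
        ).to_csv(path, sep="\t", index=False)


def select_mark(
    marks: np.ndarray, u_d: np.ndarray, rng: np.random.Generator
) -> int | None:
    """Draw a mark with probability proportional to ``1 - U_d``.

    Returns ``None`` when every weight is zero (all candidate lengths have
    the worst possible data energy), in which case no birth can happen here.
    """
    if len(marks) == 0:
        raise ValueError("empty allowed-mark list")
    weights = 1.0 - u_d
    total = float(weights.sum())
    if total <= 0.0:
        return None
    idx = int(np.searchsorted(np.cumsum(weights), rng.random() * total, side="right"))
    return int(marks[min(idx, len(marks) - 1)])


def birth_rate(u_d: float, v: float) -> float:
    """Birth rate ``B = v * b`` with ``b = (1 - U_d) / 2 in [0, 1]``."""
    return v * (1.0 - u_d) / 2.0


def death_rate(delta_u: float, beta: float, delta: float) -> float:
    """Death probability ``delta * a / (1 + delta * a)``, ``a = exp(beta * dU)``."""
    x = beta * delta_u
    if x > _EXP_CAP:
        return 1.0
    a = math.exp(x)
    return delta * a / (1.0 + delta * a)


def birth_step(
    config: Configuration,
    table: DataEnergyTable,
    delta: float,
    v: float,
    rng: np.random.Generator,
) -> int:
    """One birth sweep over all free candidate starts; returns birth count."""
    births = 0
    for s in table.starts:
        s = int(s)
        if config.occupied(s):
            continue
        marks, u_d = table.u_d_for_start(s)
        gamma = select_mark(marks, u_d, rng)
        if gamma is None:
            continue
        idx = int(np.searchsorted(marks, gamma))
        p_birth = min(1.0, delta * birth_rate(float(u_d[idx]), v))
        if p_birth > 0.0 and rng.random() < p_birth:
            config.add(MarkedPoint(s, gamma))
            births += 1
    return births


def death_step(
    config: Configuration,
    table: DataEnergyTable,
    params: EnergyParams,
    beta: float,
    delta: float,
    rng: np.random.Generator,
) -> int:
    """One death sweep, worst data energy first; returns death count.

    The prior energy of each visited point is recomputed against the
    configuration as already thinned by earlier deletions in the sweep.
    """
    points = sorted(config, key=lambda p: -table.u_d(p))
    deaths = 0
    for p in points:
        delta_u = table.u_d(p) + params.w * prior_energy(config, p, params)
        if rng.random() < death_rate(delta_u, beta, delta):
            config.remove(p)
            deaths += 1
    return deaths


def converged(before: frozenset, after: frozenset) -> bool:
    """Converged iff the iteration left the configuration unchanged."""
    return before == after


def _resolve_overlaps(
    config: Configuration, table: DataEnergyTable, params: EnergyParams, min_gap: int
) -> Configuration:
    """Greedy reporting-gap resolution: keep best-energy points first."""
    kept: list[MarkedPoint] = []
    for p in sorted(config, key=lambda q: table.u_d(q)):
        ok = True
        for q in kept:
            gap = max(p.anchor, q.anchor) - min(p.end, q.end)
            if gap < min_gap or gap < 0:
                ok = False
                break
        if ok:
            kept.append(p)
    return Configuration(kept)


def _run_chain(
    table: DataEnergyTable,
    eparams: EnergyParams,
    sparams: SamplerParams,
    rng: np.random.Generator,
) -> tuple[Configuration, SamplerTrace, bool]:
    """One annealed birth-and-death chain from the empty configuration."""
    if sparams.v_override is not None:
        v = sparams.v_override
    else:
        # expected rho*|S| births in the first sweep, using each start's best mark
        b_best = [
            (1.0 - float(np.min(table.u_d_for_start(int(s))[1]))) / 2.0
            for s in table.starts
        ]
        denom = sum(b_best)
        v = sparams.rho * len(table.starts) / denom if denom > 0 else 0.0

    beta, delta = sparams.beta0, sparams.delta0
    config = Configuration()
    trace = SamplerTrace()
    did_converge = False
    streak = 0
    for it in range(sparams.max_iter):
        before = config.snapshot()
        births = birth_step(config, table, delta, v, rng)
        deaths = death_step(config, table, eparams, beta, delta, rng)
        trace.record(it, beta, delta, births, deaths, len(config), table.total_energy(config))
        streak = streak + 1 if converged(before, config.snapshot()) else 0
        if streak >= sparams.patience:
            did_converge = True
            break
        beta *= sparams.beta_factor
        delta *= sparams.delta_factor
    return config, trace, did_converge


def run(
    pair: TrackPair,
    candidates: CandidateSets,
    energy_params: EnergyParams | None = None,
    sampler_params: SamplerParams | None = None,
    table: DataEnergyTable | None = None,
) -> tuple[Configuration, SamplerTrace]:
    """Minimize the Gibbs energy by annealed multiple birth-and-death dynamics.

    Runs ``restarts`` independent chains and keeps the final configuration
    with the lowest total energy, overlap-resolved per ``min_gap`` and
    anchor-sorted.  Returns that configuration and the winning chain's
    per-iteration trace.  Bit-reproducible for a fixed seed.
    """
    eparams = energy_params or EnergyParams()
    sparams = sampler_params or SamplerParams()
    if candidates.n_candidates == 0:
        raise ValueError("empty candidate set; build candidates first")
    if table is None:
        table = DataEnergyTable(pair, candidates.S, candidates.lengths, eparams)

    best: tuple[float, Configuration, SamplerTrace] | None = None
    any_converged = False
    for r in range(max(1, sparams.restarts)):
        rng = np.random.Generator(np.random.MT19937([sparams.seed, r]))
        config, trace, ok = _run_chain(table, eparams, sparams, rng)
        any_converged = any_converged or ok
        config = _resolve_overlaps(config, table, eparams, sparams.min_gap)
        energy = table.total_energy(config)
        if best is None or energy < best[0]:
            best = (energy, config, trace)
    if not any_converged:
        logger.warning(
            "no birth-and-death chain converged within %d iterations",
            sparams.max_iter,
        )
    return best[1], best[2]
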