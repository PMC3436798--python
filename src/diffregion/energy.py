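"""Gibbs energy of a configuration of candidate regions.

A candidate region is a marked point: an anchor nucleotide plus a length
mark.  The total energy of a configuration x is

    U(x) = sum_p U_d(p) + w * sum_p U_p(p)

where the data energy U_d rewards a strong differential-expression contrast
of the region over its flanks and the prior energy U_p penalises overlap
with, or proximity (< k nt) to, other regions.  Lower energy is better; the
normalising constant of the underlying Gibbs density is never needed because
the sampler only compares energies.

Data energy.  The contrast score of a point is
``d_z = |z(region)| - w_n * |z(neighbor)|`` where the neighbor statistic
pools the k-nt flanks on both sides (clipped at the track boundary).  It is
mapped to [-1, 1] by a linear ramp: +1 below ``z_min`` (uninteresting
regions are penalised), falling linearly to -1 at ``z_max`` and saturating
there, so regions beyond ``z_max`` are indistinguishable.

Prior energy.  For two regions with signed gap L (negative = overlap) the
pair penalty is ``clamp((k - L) / (k + min(len_p, len_q)), 0, 1)``: zero at
distance k, one for identical stacked regions.  U_p of a point is the
maximum pair penalty over its < k-distance neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .stats import zscore_arrays
from .tracks import TrackPair

__all__ = [
    "MarkedPoint",
    "Configuration",
    "EnergyParams",
    "DataEnergyTable",
    "region_counts",
    "contrast_score",
    "data_energy",
    "pair_penalty",
    "prior_energy",
    "point_energy",
    "total_energy",
]


class MarkedPoint(NamedTuple):
    """A candidate region: anchor nucleotide (0-based) + length mark."""

    anchor: int
    mark: int

    @property
    def end(self) -> int:
        return self.anchor + self.mark


class Configuration:
    """A set of marked points with at most one point anchored per nucleotide."""

    def __init__(self, points: Iterable[MarkedPoint] = ()) -> None:
        self._points: dict[int, int] = {}
        for p in points:
            self.add(p)

    def add(self, point: MarkedPoint) -> None:
        if point.anchor in self._points:
            raise ValueError(f"nucleotide {point.anchor} already holds a marked point")
        self._points[point.anchor] = point.mark

    def remove(self, point: MarkedPoint) -> None:
        if self._points.get(point.anchor) != point.mark:
            raise KeyError(point)
        del self._points[point.anchor]

    def occupied(self, anchor: int) -> bool:
        return anchor in self._points

    def snapshot(self) -> frozenset[tuple[int, int]]:
        return frozenset(self._points.items())

    def sorted_points(self) -> list[MarkedPoint]:
        return [MarkedPoint(a, m) for a, m in sorted(self._points.items())]

    def __iter__(self) -> Iterator[MarkedPoint]:
        return (MarkedPoint(a, m) for a, m in self._points.items())

    def __len__(self) -> int:
        return len(self._points)

    def __contains__(self, point: MarkedPoint) -> bool:
        return self._points.get(point.anchor) == point.mark

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Configuration):
            return NotImplemented
        return self._points == other._points


@dataclass(frozen=True)
class EnergyParams:
    """Model parameters of the energy.

    Defaults are the recommended operating point: region lengths 5–2000 nt,
    z thresholds 4 and 40, neighbourhood criterion k = 25 nt, equal weight
    for the prior (w = 1), neighbour-contrast weight w_n = 0.5.
    """

    gamma_min: int = 5
    gamma_max: int = 2000
    z_min: float = 4.0
    z_max: float = 40.0
    k: int = 25
    w: float = 1.0
    w_n: float = 0.5
    neighbor_mode: str = "pooled"  # "pooled" flanks or per-side "max"

    def __post_init__(self) -> None:
        if not (0 < self.z_min < self.z_max):
            raise ValueError("need 0 < z_min < z_max")
        if self.k < 1 or self.w < 0 or not (0 <= self.w_n <= 1):
            raise ValueError("invalid k, w or w_n")
        if not (0 < self.gamma_min <= self.gamma_max):
            raise ValueError("need 0 < gamma_min <= gamma_max")
        if self.neighbor_mode not in ("pooled", "max"):
            raise ValueError("neighbor_mode must be 'pooled' or 'max'")


def _check_inside(pair: TrackPair, point: MarkedPoint) -> None:
    if point.anchor < 0 or point.end > pair.length or point.mark < 1:
        raise ValueError(f"point {point} outside track of length {pair.length}")


def region_counts(pair: TrackPair, point: MarkedPoint) -> tuple[int, int]:
    """Summed counts of both conditions over ``[anchor, anchor + mark)``."""
    _check_inside(pair, point)
    s, e = point.anchor, point.end
    return int(pair.a.counts[s:e].sum()), int(pair.b.counts[s:e].sum())


def contrast_score(pair: TrackPair, point: MarkedPoint, params: EnergyParams) -> float:
    """Differential contrast ``|z(region)| - w_n * |z(neighbor)|``.

    The neighbour is the k-nt flank on each side, pooled into one count pair
    (``neighbor_mode="pooled"``) or scored per side with the larger |z| taken
    (``"max"``).  Flanks are clipped at the track boundary; if both flanks
    are empty the neighbour z is 0.
    """
    _check_inside(pair, point)
    n1, n2 = pair.a.library_total, pair.b.library_total
    c1, c2 = region_counts(pair, point)
    z_region = float(zscore_arrays(np.array([c1]), np.array([c2]), n1, n2)[0])

    ls, le = max(0, point.anchor - params.k), point.anchor
    rs, re = point.end, min(pair.length, point.end + params.k)
    fl = (int(pair.a.counts[ls:le].sum()), int(pair.b.counts[ls:le].sum()), le - ls)
    fr = (int(pair.a.counts[rs:re].sum()), int(pair.b.counts[rs:re].sum()), re - rs)

    if params.neighbor_mode == "pooled":
        nlen = fl[2] + fr[2]
        if nlen == 0:
            z_nb = 0.0
        else:
            z_nb = float(
                zscore_arrays(
                    np.array([fl[0] + fr[0]]), np.array([fl[1] + fr[1]]), n1, n2
                )[0]
            )
    else:
        sides = [f for f in (fl, fr) if f[2] > 0]
        z_nb = max(
            (
                abs(float(zscore_arrays(np.array([f[0]]), np.array([f[1]]), n1, n2)[0]))
                for f in sides
            ),
            default=0.0,
        )
        return abs(z_region) - params.w_n * z_nb
    return abs(z_region) - params.w_n * abs(z_nb)


def data_energy(d_z: float, params: EnergyParams) -> float:
    """Map a contrast score to the data energy in [-1, 1].

    +1 for ``d_z <= z_min``, then a linear ramp to -1 at ``z_max`` with
    saturation beyond.
    """
    if not np.isfinite(d_z):
        raise ValueError("contrast score must be finite")
    if d_z <= params.z_min:
        return 1.0
    return -(min(d_z, params.z_max) - params.z_min) / (params.z_max - params.z_min)


def _gap(p: MarkedPoint, q: MarkedPoint) -> int:
    """Signed gap between two half-open intervals; negative = overlap length."""
    return max(p.anchor, q.anchor) - min(p.end, q.end)


def pair_penalty(p: MarkedPoint, q: MarkedPoint, params: EnergyParams) -> float:
    """Overlap/proximity penalty in [0, 1] for an unordered region pair.

    Identical intervals (full overlap) score the maximum penalty of 1; a
    configuration can never hold two such points, but the formula is defined
    for them.
    """
    L = _gap(p, q)
    t = (params.k - L) / (params.k + min(p.mark, q.mark))
    return float(np.clip(t, 0.0, 1.0))


def prior_energy(config: Configuration, p: MarkedPoint, params: EnergyParams) -> float:
    """Maximum pair penalty of ``p`` against its < k-distance neighbours."""
    best = 0.0
    for q in config:
        if q == p:
            continue
        if _gap(p, q) < params.k:
            best = max(best, pair_penalty(p, q, params))
    return best


def point_energy(
    pair: TrackPair, config: Configuration, p: MarkedPoint, params: EnergyParams
) -> float:
    """Per-point energy contribution ``U_d(p) + w * U_p(p)``."""
    u_d = data_energy(contrast_score(pair, p, params), params)
    return u_d + params.w * prior_energy(config, p, params)


def total_energy(pair: TrackPair, config: Configuration, params: EnergyParams) -> float:
    """Total Gibbs energy; the empty configuration has energy 0."""
    return sum(point_energy(pair, config, p, params) for p in config)


class DataEnergyTable:
    """Precomputed data energies for a fixed candidate set.

    The data energy of a point depends only on the tracks, never on the
    configuration, so it is computed once, vectorised over all candidate
    (anchor, mark) pairs via cumulative sums, and looked up thereafter.
    """

    def __init__(
        self,
        pair: TrackPair,
        starts: np.ndarray,
        lengths: dict[int, np.ndarray],
        params: EnergyParams,
    ) -> None:
        self.params = params
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = {int(s): np.asarray(v, dtype=np.int64) for s, v in lengths.items()}

        anchors, marks = [], []
        for s in self.starts:
            for g in self.lengths[int(s)]:
                anchors.append(int(s))
                marks.append(int(g))
        anchors = np.asarray(anchors, dtype=np.int64)
        marks = np.asarray(marks, dtype=np.int64)
        if anchors.size and (anchors.min() < 0 or (anchors + marks).max() > pair.length):
            raise ValueError("candidate region outside the track")

        n1, n2 = pair.a.library_total, pair.b.library_total
        cs1 = np.concatenate([[0], np.cumsum(pair.a.counts)])
        cs2 = np.concatenate([[0], np.cumsum(pair.b.counts)])
        ends = anchors + marks
        c1 = cs1[ends] - cs1[anchors]
        c2 = cs2[ends] - cs2[anchors]
        z_region = zscore_arrays(c1, c2, n1, n2)

        k = params.k
        ls = np.maximum(anchors - k, 0)
        re = np.minimum(ends + k, pair.length)
        fl1 = cs1[anchors] - cs1[ls]
        fl2 = cs2[anchors] - cs2[ls]
        fr1 = cs1[re] - cs1[ends]
        fr2 = cs2[re] - cs2[ends]
        flank_len = (anchors - ls) + (re - ends)
        if params.neighbor_mode == "pooled":
            z_nb = np.abs(zscore_arrays(fl1 + fr1, fl2 + fr2, n1, n2))
            z_nb = np.where(flank_len > 0, z_nb, 0.0)
        else:
            zl = np.abs(zscore_arrays(fl1, fl2, n1, n2))
            zr = np.abs(zscore_arrays(fr1, fr2, n1, n2))
            zl = np.where(anchors - ls > 0, zl, 0.0)
            zr = np.where(re - ends > 0, zr, 0.0)
            z_nb = np.maximum(zl, zr)

        d_z = np.abs(z_region) - params.w_n * z_nb
        ramp = -(np.minimum(d_z, params.z_max) - params.z_min) / (
            params.z_max - params.z_min
        )
        u_d = np.where(d_z <= params.z_min, 1.0, ramp)

        self._u_d = {
            (int(a), int(g)): float(u) for a, g, u in zip(anchors, marks, u_d)
        }
        self._d_z = {
            (int(a), int(g)): float(d) for a, g, d in zip(anchors, marks, d_z)
        }
        # per-start views, precomputed for the sampler's inner loop
        self._per_start: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        i = 0
        for s in self.starts:
            n = len(self.lengths[int(s)])
            self._per_start[int(s)] = (self.lengths[int(s)], u_d[i : i + n].copy())
            i += n

    def u_d(self, point: MarkedPoint) -> float:
        return self._u_d[(point.anchor, point.mark)]

    def d_z(self, point: MarkedPoint) -> float:
        return self._d_z[(point.anchor, point.mark)]

    def u_d_for_start(self, anchor: int) -> tuple[np.ndarray, np.ndarray]:
        """(marks, data energies) arrays for one candidate start."""
        return self._per_start[anchor]

    def total_energy(self, config: Configuration) -> float:
        u = 0.0
        for p in config:
            u += self.u_d(p) + self.params.w * prior_energy(config, p, self.params)
        return u
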