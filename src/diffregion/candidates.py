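"""Candidate region starts/ends from smoothed tracks, and the reduced mark space.

Region boundaries are nucleotides where expression changes sharply, so the
sampler only needs to consider starts S (one-step rises >= t of the smoothed
signal) and ends E (one-step falls >= t), unioned over both conditions.  The
mark space at a start s is then restricted to the lengths {e - s : e in E}
within the allowed band, which cuts the candidate count by orders of
magnitude relative to every (position, length) pair.  The reduction is an
optimisation only: ``full_mark_space`` provides the unreduced alternative
for small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import smooth
from .tracks import TrackPair

__all__ = [
    "CandidateSets",
    "EmptyMarkSpaceError",
    "sharpen_ramps",
    "detect_edges",
    "build_mark_space",
    "full_mark_space",
    "build_candidates",
]


def sharpen_ramps(y: np.ndarray, half_window: int = 5) -> np.ndarray:
    """Snap each position to the nearer of its two flanking plateau levels.

    Wavelet denoising reproduces a step as a short monotone ramp (2-4 nt),
    which defeats a one-step edge criterion even though the level shift is
    intact.  Replacing ``y(i)`` by whichever flanking median —
    ``median(y[i-half_window:i])`` or ``median(y[i+1:i+1+half_window])`` —
    lies closer to ``y(i)`` collapses such ramps back to a single step
    while leaving plateaus (and genuine steps) unchanged.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        return y.copy()
    out = np.empty_like(y)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + 1 + half_window)
        m_left = np.median(y[lo:i]) if i > lo else y[i]
        m_right = np.median(y[i + 1 : hi]) if hi > i + 1 else y[i]
        out[i] = m_left if abs(y[i] - m_left) <= abs(y[i] - m_right) else m_right
    return out


class EmptyMarkSpaceError(ValueError):
    """No (start, end) pair yields an allowed region length."""


@dataclass
class CandidateSets:
    """Candidate starts S, ends E, and the allowed lengths per start."""

    S: np.ndarray
    E: np.ndarray
    lengths: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_candidates(self) -> int:
        return sum(len(v) for v in self.lengths.values())


def detect_edges(
    smoothed_a: np.ndarray, smoothed_b: np.ndarray, t: float = 5.0
) -> CandidateSets:
    """Find rise/fall nucleotides of two smoothed tracks.

    A nucleotide i joins S when ``y'(i) - y'(i-1) >= t`` in either condition
    and joins E when ``y'(i) - y'(i+1) >= t``; t is the threshold of the
    drastic change (default 5).
    """
    s_set: set[int] = set()
    e_set: set[int] = set()
    for y in (np.asarray(smoothed_a, float), np.asarray(smoothed_b, float)):
        diff = np.diff(y)
        s_set.update((np.nonzero(diff >= t)[0] + 1).tolist())
        e_set.update(np.nonzero(-diff >= t)[0].tolist())
    return CandidateSets(
        S=np.array(sorted(s_set), dtype=np.int64),
        E=np.array(sorted(e_set), dtype=np.int64),
    )


def build_mark_space(
    cand: CandidateSets, gamma_min: int, gamma_max: int
) -> CandidateSets:
    """Restrict marks to lengths reachable from S to E within [γ_min, γ_max].

    Starts with no admissible end are dropped.  Raises
    :class:`EmptyMarkSpaceError` when nothing survives (the edge threshold t
    is then too high for the data).
    """
    lengths: dict[int, np.ndarray] = {}
    kept = []
    E = np.asarray(cand.E, dtype=np.int64)
    for s in np.asarray(cand.S, dtype=np.int64):
        lam = E[E > s] - s
        lam = lam[(lam >= gamma_min) & (lam <= gamma_max)]
        if lam.size:
            kept.append(int(s))
            lengths[int(s)] = np.unique(lam)
    if not kept:
        raise EmptyMarkSpaceError(
            "no candidate regions: no start/end pair within the length bounds "
            "(lower the edge threshold t or use the unreduced mark space)"
        )
    return CandidateSets(S=np.array(kept, dtype=np.int64), E=E, lengths=lengths)


def full_mark_space(track_length: int, gamma_min: int, gamma_max: int) -> CandidateSets:
    """Unreduced candidates: every anchor, every in-bounds length."""
    if track_length < gamma_min:
        raise EmptyMarkSpaceError("track shorter than gamma_min")
    starts = np.arange(0, track_length - gamma_min + 1, dtype=np.int64)
    lengths = {
        int(s): np.arange(gamma_min, min(gamma_max, track_length - s) + 1, dtype=np.int64)
        for s in starts
    }
    return CandidateSets(S=starts, E=np.arange(track_length, dtype=np.int64), lengths=lengths)


def build_candidates(
    pair: TrackPair,
    gamma_min: int,
    gamma_max: int,
    n_scales: int = 4,
    t: float = 5.0,
    reduce: bool = True,
) -> CandidateSets:
    """Smooth both tracks, detect edges, and build the reduced mark space."""
    if not reduce:
        return full_mark_space(pair.length, gamma_min, gamma_max)
    ya = sharpen_ramps(smooth(pair.a.counts, n_scales=n_scales))
    yb = sharpen_ramps(smooth(pair.b.counts, n_scales=n_scales))
    cand = detect_edges(ya, yb, t=t)
    return build_mark_space(cand, gamma_min, gamma_max)
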