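"""Random-sampling differential expression statistic for a genomic region.

Read counts ``C1`` and ``C2`` observed in one region under two conditions are
modelled as independent binomial draws, ``C_i ~ Binomial(n_i, p_i)``, where
``n_i`` is the total mapped-read count of library *i* and ``p_i`` the
probability that a read originates from the region.  The MA representation

    M = log2 C1 - log2 C2,        A = (log2 C1 + log2 C2) / 2

separates fold change (M) from abundance (A).  Under the null hypothesis
``p1 = p2 = p`` the conditional distribution of M given A = a is
approximately normal; with the delta method applied to ``X = log2 C1`` and
``Y = log2 C2`` (each with variance ``(1-p)/(n_i p ln^2 2)``) and the
geometric-mean estimate ``p_hat = 2^a / sqrt(n1 n2)``,

    E[M | A=a]   = log2(n1 / n2)
    Var[M | A=a] = 4 (1 - p_hat) / (p_hat ln^2 2 (n1 + n2))

which yields the z-score ``z = (m - E[M|a]) / sqrt(Var[M|a])`` and a
two-sided p-value from the standard normal.  With equal library sizes the
conditional-mean correction vanishes, so z is antisymmetric under swapping
the two conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["DiffStat", "RegionStat", "ma_stats", "zscore", "zscore_arrays"]

#: Pseudocount substituted for zero counts inside logarithms.
PSEUDOCOUNT = 0.5

#: Clamp for the estimated sampling probability, keeps the variance finite.
EPS = 1e-12

_LN2_SQ = math.log(2.0) ** 2


@dataclass(frozen=True)
class DiffStat:
    """MA statistics and test result for one region.

    Attributes
    ----------
    M : float
        log2 fold change between conditions (condition 1 over condition 2).
    A : float
        Mean log2 intensity of the two region counts.
    z : float
        Standard-normal score of M under the binomial random-sampling null.
    p : float
        Two-sided p-value, ``2 * (1 - Phi(|z|))``.
    """

    M: float
    A: float
    z: float
    p: float


@dataclass(frozen=True)
class RegionStat:
    """A :class:`DiffStat` together with the raw region counts."""

    c1: float
    c2: float
    stat: DiffStat


def _safe_counts(c1: float, c2: float) -> tuple[float, float]:
    if c1 < 0 or c2 < 0:
        raise ValueError(f"region counts must be non-negative, got ({c1}, {c2})")
    return (c1 if c1 > 0 else PSEUDOCOUNT, c2 if c2 > 0 else PSEUDOCOUNT)


def ma_stats(c1: float, c2: float) -> tuple[float, float]:
    """Return ``(M, A)`` for one pair of region counts.

    Zero counts are replaced by a pseudocount of 0.5 so that zero-count
    regions remain testable; ``ma_stats(0, 0) == (0.0, -1.0)``.
    """
    c1p, c2p = _safe_counts(c1, c2)
    l1, l2 = math.log2(c1p), math.log2(c2p)
    return l1 - l2, 0.5 * (l1 + l2)


def zscore(c1: float, c2: float, n1: float, n2: float) -> DiffStat:
    """Test one region for differential expression under binomial sampling.

    Parameters
    ----------
    c1, c2 : float
        Summed per-nucleotide counts of the region in each condition.
    n1, n2 : float
        Total mapped-read counts (library sizes) of each condition.

    Returns
    -------
    DiffStat
        M, A, the conditional-normal z-score and its two-sided p-value.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library totals must be positive, got ({n1}, {n2})")
    if c1 > n1 or c2 > n2:
        raise ValueError("region count exceeds its library total")
    m, a = ma_stats(c1, c2)
    p_hat = min(1.0 - EPS, max(EPS, 2.0**a / math.sqrt(n1 * n2)))
    var = 4.0 * (1.0 - p_hat) / (p_hat * _LN2_SQ * (n1 + n2))
    z = (m - math.log2(n1 / n2)) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return DiffStat(M=m, A=a, z=z, p=p)


def zscore_arrays(
    c1: np.ndarray, c2: np.ndarray, n1: float, n2: float
) -> np.ndarray:
    """Vectorised z-scores for arrays of region counts (no p-values).

    Used by the data-energy table, where thousands of candidate regions are
    scored at once.  Semantics match :func:`zscore` elementwise.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library totals must be positive, got ({n1}, {n2})")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    c1p = np.where(c1 > 0, c1, PSEUDOCOUNT)
    c2p = np.where(c2 > 0, c2, PSEUDOCOUNT)
    l1, l2 = np.log2(c1p), np.log2(c2p)
    m = l1 - l2
    a = 0.5 * (l1 + l2)
    p_hat = np.clip(2.0**a / math.sqrt(n1 * n2), EPS, 1.0 - EPS)
    var = 4.0 * (1.0 - p_hat) / (p_hat * _LN2_SQ * (n1 + n2))
    return (m - math.log2(n1 / n2)) / np.sqrt(var)
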