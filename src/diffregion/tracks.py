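"""Per-nucleotide count tracks: reading, pairing, and writing results.

Internal coordinates are 0-based, half-open.  Wiggle and two-column TSV
inputs, which are 1-based on disk, are converted on read; bedGraph is already
0-based half-open.  Positions missing inside the covered interval are counts
of zero, not missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import RegionStat

__all__ = ["CountTrack", "TrackPair", "read_track", "pair_tracks", "write_regions"]

logger = logging.getLogger(__name__)


@dataclass
class CountTrack:
    """Dense per-nucleotide counts over one contiguous genomic interval.

    Attributes
    ----------
    contig : str
        Reference sequence name.
    start : int
        0-based coordinate of the first nucleotide covered.
    counts : numpy.ndarray of int64
        One count per nucleotide; length is the interval length.
    library_total : int
        Total mapped-read count of the library the track came from (``n_i``
        of the binomial sampling model), not just the reads in this window.
    """

    contig: str
    start: int
    counts: np.ndarray
    library_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind == "f":
            self.counts = np.rint(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.library_total < int(self.counts.sum()):
            raise ValueError(
                "library_total must be at least the sum of the track counts"
            )

    @property
    def end(self) -> int:
        """0-based exclusive end of the covered interval."""
        return self.start + len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class TrackPair:
    """Two condition tracks over the identical contig and interval."""

    a: CountTrack
    b: CountTrack

    def __post_init__(self) -> None:
        if self.a.contig != self.b.contig:
            raise ValueError("paired tracks must share a contig")
        if self.a.start != self.b.start or len(self.a) != len(self.b):
            raise ValueError("paired tracks must cover the identical interval")

    @property
    def length(self) -> int:
        return len(self.a)


def _records_to_track(
    records: list[tuple[int, int, int]],
    contig: str,
    library_total: int | None,
    path: str,
) -> CountTrack:
    """Turn (start0, end0, count) records into a dense track; gaps become 0."""
    if not records:
        raise ValueError(f"{path}: no count records found")
    records.sort(key=lambda r: r[0])
    prev_end = None
    for s, e, _ in records:
        if e <= s:
            raise ValueError(f"{path}: empty or inverted interval [{s}, {e})")
        if prev_end is not None and s < prev_end:
            raise ValueError(f"{path}: overlapping records at position {s}")
        prev_end = e
    lo, hi = records[0][0], records[-1][1]
    counts = np.zeros(hi - lo, dtype=np.int64)
    for s, e, v in records:
        if v < 0:
            raise ValueError(f"{path}: negative count {v}")
        counts[s - lo : e - lo] = v
    if library_total is None:
        library_total = int(counts.sum())
        logger.warning(
            "%s: no library total supplied; falling back to the window sum %d "
            "(the binomial model expects the library-wide total)",
            path,
            library_total,
        )
    return CountTrack(contig=contig, start=lo, counts=counts, library_total=library_total)


def _parse_bedgraph(lines: Iterable[str], path: str):
    contig = None
    records = []
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed bedGraph line: {ln!r}")
        chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if contig is None:
            contig = chrom
        elif chrom != contig:
            raise ValueError(f"{path}: multiple contigs ({contig}, {chrom})")
        records.append((s, e, int(round(v))))
    return contig, records


def _parse_wig(lines: Iterable[str], path: str):
    contig = None
    records = []
    mode = None  # ("fixed", next_pos0, step, span) | ("variable", span)
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        if ln.startswith("fixedStep"):
            kv = dict(p.split("=", 1) for p in ln.split()[1:])
            chrom = kv["chrom"]
            start0 = int(kv["start"]) - 1  # wiggle is 1-based
            step = int(kv.get("step", 1))
            span = int(kv.get("span", 1))
            if contig is None:
                contig = chrom
            elif chrom != contig:
                raise ValueError(f"{path}: multiple contigs ({contig}, {chrom})")
            mode = ["fixed", start0, step, span]
        elif ln.startswith("variableStep"):
            kv = dict(p.split("=", 1) for p in ln.split()[1:])
            chrom = kv["chrom"]
            span = int(kv.get("span", 1))
            if contig is None:
                contig = chrom
            elif chrom != contig:
                raise ValueError(f"{path}: multiple contigs ({contig}, {chrom})")
            mode = ["variable", span]
        else:
            if mode is None:
                raise ValueError(f"{path}: data line before step declaration")
            if mode[0] == "fixed":
                _, pos, step, span = mode
                records.append((pos, pos + span, int(round(float(ln)))))
                mode[1] = pos + step
            else:
                parts = ln.split()
                pos0 = int(parts[0]) - 1
                records.append((pos0, pos0 + mode[1], int(round(float(parts[1])))))
    return contig, records


def _parse_tsv(lines: Iterable[str], path: str):
    records = []
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed position/count line: {ln!r}")
        pos0 = int(parts[0]) - 1  # positions on disk are 1-based
        records.append((pos0, pos0 + 1, int(round(float(parts[1])))))
    return None, records


_PARSERS = {"bedgraph": _parse_bedgraph, "wig": _parse_wig, "tsv": _parse_tsv}

_SUFFIXES = {
    ".bedgraph": "bedgraph",
    ".bg": "bedgraph",
    ".wig": "wig",
    ".tsv": "tsv",
    ".txt": "tsv",
}


def read_track(
    path: str | Path,
    format: str | None = None,
    library_total: int | None = None,
    contig: str | None = None,
) -> CountTrack:
    """Read a per-nucleotide count track into a dense :class:`CountTrack`.

    Parameters
    ----------
    path : path
        Input file.
    format : {"bedgraph", "wig", "tsv"}, optional
        Dialect; inferred from the file suffix when omitted.
    library_total : int, optional
        Library-wide total read count ``n_i``.  Falls back to the window sum
        with a logged warning when absent.
    contig : str, optional
        Contig name for TSV inputs, which carry none (default ``"track"``).

    Raises
    ------
    ValueError
        Unknown format, overlapping records, negative counts, or empty file.
    """
    path = Path(path)
    if format is None:
        format = _SUFFIXES.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer track format from suffix {path.suffix!r}")
    format = format.lower()
    if format not in _PARSERS:
        raise ValueError(f"unknown track format {format!r}")
    with open(path) as fh:
        parsed_contig, records = _PARSERS[format](fh, str(path))
    name = parsed_contig or contig or "track"
    return _records_to_track(records, name, library_total, str(path))


def pair_tracks(a: CountTrack, b: CountTrack) -> TrackPair:
    """Trim two tracks to their overlapping interval and pair them.

    Raises
    ------
    ValueError
        Different contigs, or no overlap between the covered intervals.
    """
    if a.contig != b.contig:
        raise ValueError(f"cannot pair tracks on {a.contig!r} and {b.contig!r}")
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if hi <= lo:
        raise ValueError("track intervals do not overlap")

    def clip(t: CountTrack) -> CountTrack:
        if t.start == lo and t.end == hi:
            return t
        return CountTrack(
            contig=t.contig,
            start=lo,
            counts=t.counts[lo - t.start : hi - t.start],
            library_total=t.library_total,
        )

    return TrackPair(a=clip(a), b=clip(b))


TSV_COLUMNS = ["start", "end", "length", "C1", "C2", "M", "A", "z", "p", "q_bh"]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone)."""
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def write_regions(
    regions: Sequence[tuple[int, int]],
    stats: Sequence[RegionStat],
    path: str | Path,
    contig: str = "track",
    offset: int = 0,
) -> None:
    """Write detected regions as BED6 plus a sidecar statistics TSV.

    ``regions`` are 0-based half-open ``(start, end)`` intervals relative to
    the analysed track; ``offset`` (the track's genomic start) is added on
    output.  The BED score is ``min(1000, round(25 * |z|))``; the sidecar TSV
    (same path with a ``.tsv`` suffix) holds start, end, length, counts, M,
    A, the signed z, p, and a post-hoc Benjamini–Hochberg column.
    """
    if len(regions) != len(stats):
        raise ValueError("regions and stats must align")
    path = Path(path)
    tsv_path = path.with_suffix(".tsv") if path.suffix == ".bed" else Path(str(path) + ".tsv")

    with open(path, "w") as bed:
        for i, ((s, e), rs) in enumerate(zip(regions, stats)):
            score = int(min(1000, round(25 * abs(rs.stat.z))))
            bed.write(
                f"{contig}\t{offset + s}\t{offset + e}\tregion_{i + 1}\t{score}\t.\n"
            )

    rows = [
        {
            "start": offset + s,
            "end": offset + e,
            "length": e - s,
            "C1": rs.c1,
            "C2": rs.c2,
            "M": rs.stat.M,
            "A": rs.stat.A,
            "z": rs.stat.z,
            "p": rs.stat.p,
        }
        for (s, e), rs in zip(regions, stats)
    ]
    df = pd.DataFrame(rows, columns=TSV_COLUMNS[:-1])
    df["q_bh"] = _bh_adjust(df["p"].to_numpy()) if len(df) else []
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
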