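"""Genomic interval data model, BED I/O, consensus peaks and overlap matrices.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
"Overlap" always means shared bases >= some minimum (default 1 bp), so two
intervals that merely touch (``[0,10)`` and ``[10,20)``) do NOT overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "OverlapMatrix",
    "ClusterResult",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "intersect_sets",
    "consensus_peaks",
    "pairwise_overlap_matrix",
    "cluster_matrix",
]


class BedParseError(ValueError):
    """Raised for malformed BED input; message carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval centre."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakSet:
    """Named, sorted collection of intervals from one experiment.

    Intervals are stored sorted by ``(chrom, start, end)``.  Duplicate
    intervals are tolerated (with a log message) but are counted once in
    overlap numerators/denominators.
    """

    name: str
    intervals: tuple[GenomicInterval, ...]
    source: str = ""

    def __init__(
        self,
        name: str,
        intervals: Iterable[GenomicInterval],
        source: str = "",
    ) -> None:
        ivs = tuple(sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)))
        n_unique = len({(iv.chrom, iv.start, iv.end) for iv in ivs})
        if n_unique < len(ivs):
            logger.info(
                "PeakSet %r contains %d duplicate interval(s); duplicates are "
                "counted once in overlap statistics",
                name,
                len(ivs) - n_unique,
            )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "intervals", ivs)
        object.__setattr__(self, "source", source)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return len(self.intervals) > 0

    def n_unique(self) -> int:
        return len({(iv.chrom, iv.start, iv.end) for iv in self.intervals})

    def unique(self) -> "PeakSet":
        """Copy with exact duplicate intervals dropped."""
        seen: dict[tuple, GenomicInterval] = {}
        for iv in self.intervals:
            seen.setdefault((iv.chrom, iv.start, iv.end), iv)
        return PeakSet(self.name, seen.values(), self.source)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` arrays, in sorted order."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, ([], []))
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def total_bases(self) -> int:
        """Covered bases, counting overlapping intervals once."""
        return sum(len(iv) for iv in merge_intervals(self).intervals)


@dataclass
class OverlapMatrix:
    """Square matrix of pairwise overlap percentages between peak sets.

    ``values[i, j]`` is the percentage of set *i* (row) whose intervals
    overlap set *j* (column); the matrix is generally not symmetric.
    """

    set_names: list[str]
    values: np.ndarray
    orientation: str = "rows are percentage of row set overlapping column set"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.set_names)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match set_names")
        if np.any(self.values < -1e-9) or np.any(self.values > 100 + 1e-9):
            raise ValueError("overlap percentages must lie in [0, 100]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.set_names, columns=self.set_names)


@dataclass
class ClusterResult:
    """Average-linkage clustering of an :class:`OverlapMatrix`'s rows."""

    linkage: np.ndarray
    leaf_order: list[int]
    ordered_names: list[str]
    ordered_values: np.ndarray


# ---------------------------------------------------------------------------
# BED I/O

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    Track/browser/comment lines are skipped.  Coordinates are taken as
    0-based half-open.  Malformed lines raise :class:`BedParseError` naming
    the offending 1-based line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate in {fields[1:3]}"
                ) from exc
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            try:
                intervals.append(GenomicInterval(chrom, start, end, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(name or path.stem, intervals, source=str(path))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED3 (plus score in column 5 when present)."""
    path = Path(path)
    with path.open("w") as fh:
        for iv in peaks.intervals:
            if iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.name}\t{iv.score}\n")


# ---------------------------------------------------------------------------
# Set operations


def merge_intervals(s: PeakSet) -> PeakSet:
    """Union of a peak set: minimal non-overlapping intervals, same bases.

    Touching intervals are *not* merged -- half-open adjacency is not overlap.
    Idempotent and base-conserving.
    """
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in s.intervals:  # already sorted
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            continue
        if cur is not None:
            merged.append(cur)
        cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return PeakSet(s.name, merged, s.source)


def _max_single_overlap(
    start: int,
    end: int,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
) -> int:
    """Largest shared-base count between [start,end) and any one b interval.

    ``b_starts`` is sorted; intervals may overlap each other.
    """
    if b_starts.size == 0:
        return 0
    hi = int(np.searchsorted(b_starts, end, side="left"))
    if hi == 0:
        return 0
    # Intervals with start < end are candidates; they may still end before
    # `start`. b is sorted by start only, so scan the candidate prefix but
    # stop early using a running max of ends would require precomputation;
    # candidate windows are small in practice, scan back a bounded slice.
    ov = np.minimum(b_ends[:hi], end) - np.maximum(b_starts[:hi], start)
    return int(ov.max()) if ov.size else 0


def intersect_sets(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Subset of ``a``'s intervals with >= ``min_overlap`` shared bases with
    at least one interval of ``b``; ``a``'s coordinates are retained."""
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if min_overlap == 1:
        # merged b is equivalent and fast
        b_idx = merge_intervals(b).by_chrom()
        kept = []
        for iv in a.intervals:
            arrs = b_idx.get(iv.chrom)
            if arrs is None:
                continue
            bs, be = arrs
            j = int(np.searchsorted(bs, iv.end, side="left")) - 1
            if j >= 0 and be[j] > iv.start:
                kept.append(iv)
        return PeakSet(a.name, kept, a.source)
    b_idx = b.by_chrom()
    kept = []
    for iv in a.intervals:
        arrs = b_idx.get(iv.chrom)
        if arrs is None:
            continue
        if _max_single_overlap(iv.start, iv.end, *arrs) >= min_overlap:
            kept.append(iv)
    return PeakSet(a.name, kept, a.source)


def consensus_peaks(
    caller1: PeakSet, caller2: PeakSet, symmetric: bool = False
) -> PeakSet:
    """High-confidence peaks: caller1 peaks supported (>=1 bp) by caller2.

    By default the first caller's coordinates survive.  With
    ``symmetric=True`` the union of both callers' supported intervals is
    merged instead.
    """
    if len(caller1) == 0 or len(caller2) == 0:
        logger.warning(
            "consensus_peaks: empty input (%r has %d peaks, %r has %d); "
            "returning empty consensus",
            caller1.name,
            len(caller1),
            caller2.name,
            len(caller2),
        )
        return PeakSet("high_confidence", [])
    first = intersect_sets(caller1, caller2, 1)
    if not symmetric:
        return PeakSet("high_confidence", first.intervals, caller1.source)
    second = intersect_sets(caller2, caller1, 1)
    both = PeakSet("high_confidence", first.intervals + second.intervals)
    return merge_intervals(both)


def pairwise_overlap_matrix(
    sets: Sequence[PeakSet], min_overlap: int = 1
) -> OverlapMatrix:
    """All-pairs overlap percentages: entry (i, j) is
    ``100 * |intersect(set_i, set_j)| / |set_i|`` over unique intervals."""
    if len(sets) < 2:
        raise ValueError("need at least two peak sets")
    for s in sets:
        if len(s) == 0:
            raise ValueError(f"peak set {s.name!r} is empty")
    uniq = [s.unique() for s in sets]
    n = len(uniq)
    values = np.zeros((n, n))
    for i, a in enumerate(uniq):
        for j, b in enumerate(uniq):
            if i == j:
                values[i, j] = 100.0
            else:
                values[i, j] = 100.0 * len(intersect_sets(a, b, min_overlap)) / len(a)
    return OverlapMatrix([s.name for s in sets], values)


# ---------------------------------------------------------------------------
# Clustering


def _corr_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant rows get distance 1."""
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            "constant row(s) in matrix: correlation undefined, using distance 1",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(v)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def _deterministic_order(Z: np.ndarray, n: int) -> list[int]:
    """Leaf order with children sorted by (subtree size, smallest leaf)."""

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        lo, ro = walk(left), walk(right)
        key_l = (len(lo), min(lo))
        key_r = (len(ro), min(ro))
        return lo + ro if key_l <= key_r else ro + lo

    return walk(2 * n - 2)


def cluster_matrix(m: OverlapMatrix) -> ClusterResult:
    """Average-linkage hierarchical clustering of the matrix rows with
    distance 1 - Pearson correlation and a deterministic leaf order."""
    n = len(m.set_names)
    if n < 2:
        raise ValueError("need a matrix with >= 2 rows to cluster")
    Z = linkage(_corr_distance(m.values), method="average")
    order = _deterministic_order(Z, n)
    ordered_names = [m.set_names[i] for i in order]
    ordered = m.values[np.ix_(order, order)]
    return ClusterResult(Z, order, ordered_names, ordered)
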