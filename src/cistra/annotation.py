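"""Peak-to-gene annotation: windowed assignment, closest feature, profiles.

Distances are measured from the peak midpoint (floor of the centre) to the
gene's transcription start site.  On the + strand the TSS is the half-open
span start, on the - strand the half-open span end.  An ``anchor="span"``
variant measures distance to the nearest gene-body edge instead (0 for a
midpoint inside the span).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from cistra.intervals import GenomicInterval, PeakSet

__all__ = [
    "GeneModel",
    "PeakGeneAssignment",
    "DistanceProfile",
    "load_gene_annotation",
    "write_gene_annotation",
    "assign_peaks_to_genes",
    "closest_gene",
    "distance_distribution",
    "DEFAULT_DISTANCE_BINS",
    "DEFAULT_WINDOWS",
]

#: Named window ladder (bp) used across the pipeline.
DEFAULT_WINDOWS = (5_000, 10_000, 25_000, 50_000)

#: Distance-profile bin edges (bp); bins are [0,5k), [5k,50k), [50k,500k), [500k,inf).
DEFAULT_DISTANCE_BINS = (5_000, 50_000, 500_000)


@dataclass(frozen=True)
class GeneModel:
    """Gene anchor for distance logic: id, strand-aware TSS and span."""

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.span_start >= self.span_end:
            raise ValueError(
                f"gene {self.gene_id}: span_start must be < span_end "
                f"({self.span_start} >= {self.span_end})"
            )

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: GenomicInterval
    gene_id: str
    distance: int
    window: int

    def __post_init__(self) -> None:
        if self.distance > self.window:
            raise ValueError("assignment distance exceeds its window")


@dataclass
class DistanceProfile:
    bin_labels: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be >= 0")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]


def load_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Load the gene-annotation TSV (columns gene_id, chrom, strand, start,
    end; half-open span).  Duplicate ids and malformed rows are errors."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing column(s): {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate gene_id(s): {list(dup[:5])}")
    bad_strand = df.index[~df["strand"].isin(["+", "-"])]
    if bad_strand.size:
        lines = [int(i) + 2 for i in bad_strand[:5]]  # +2: header + 1-based
        raise ValueError(f"malformed strand at line(s) {lines}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                span_start=int(row.start),
                span_end=int(row.end),
            )
        )
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.span_start for g in genes],
            "end": [g.span_end for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


Anchor = Literal["tss", "span"]


class _GeneIndex:
    """Per-chromosome sorted TSS (or span-edge) index."""

    def __init__(self, genes: Sequence[GeneModel], anchor: Anchor = "tss"):
        self.anchor = anchor
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        tmp: dict[str, list[GeneModel]] = {}
        for g in genes:
            tmp.setdefault(g.chrom, []).append(g)
        for chrom, gl in tmp.items():
            gl.sort(key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = (
                np.asarray([g.tss for g in gl], dtype=np.int64),
                gl,
            )

    def distance(self, gene: GeneModel, point: int) -> int:
        if self.anchor == "tss":
            return abs(point - gene.tss)
        if gene.span_start <= point < gene.span_end:
            return 0
        return min(abs(point - gene.span_start), abs(point - (gene.span_end - 1)))


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    window: int,
    anchor: Anchor = "tss",
) -> list[PeakGeneAssignment]:
    """Assign each peak to *every* gene whose anchor lies strictly within
    ``window`` bp of the peak midpoint (same chromosome)."""
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    index = _GeneIndex(genes, anchor)
    out: list[PeakGeneAssignment] = []
    for iv in peaks.intervals:
        entry = index.by_chrom.get(iv.chrom)
        if entry is None:
            continue
        tss_arr, gene_list = entry
        mid = iv.midpoint
        if anchor == "tss":
            lo = int(np.searchsorted(tss_arr, mid - window, side="right"))
            hi = int(np.searchsorted(tss_arr, mid + window, side="left"))
            candidates = gene_list[lo:hi]
        else:
            candidates = gene_list
        for g in candidates:
            d = index.distance(g, mid)
            if d < window:
                out.append(PeakGeneAssignment(iv, g.gene_id, d, window))
    return out


def closest_gene(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    anchor: Anchor = "tss",
) -> tuple[str, int]:
    """Gene minimising |peak midpoint - anchor|; ties broken by smallest id."""
    index = _GeneIndex(genes, anchor)
    entry = index.by_chrom.get(peak.chrom)
    if entry is None:
        raise LookupError(f"no gene on chromosome {peak.chrom!r}")
    tss_arr, gene_list = entry
    mid = peak.midpoint
    if anchor == "tss":
        j = int(np.searchsorted(tss_arr, mid))
        cand_idx = {max(j - 1, 0), min(j, len(gene_list) - 1)}
        best_d = min(abs(mid - int(tss_arr[i])) for i in cand_idx)
        ties = [
            g
            for i in range(len(gene_list))
            if abs(mid - int(tss_arr[i])) == best_d
            for g in [gene_list[i]]
        ]
    else:
        dists = [index.distance(g, mid) for g in gene_list]
        best_d = min(dists)
        ties = [g for g, d in zip(gene_list, dists) if d == best_d]
    return min(t.gene_id for t in ties), best_d


def distance_distribution(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    bin_edges: Sequence[int] = DEFAULT_DISTANCE_BINS,
    anchor: Anchor = "tss",
) -> DistanceProfile:
    """Fraction of peaks per closest-anchor distance bin.

    Default bins: ``[0,5kb) [5,50kb) [50,500kb) [500kb,inf)``.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    index = _GeneIndex(genes, anchor)
    dist_list: list[int] = []
    for iv in peaks.intervals:
        entry = index.by_chrom.get(iv.chrom)
        if entry is None:
            raise ValueError(f"no gene on chromosome {iv.chrom!r}")
        tss_arr, gene_list = entry
        mid = iv.midpoint
        if anchor == "tss":
            j = int(np.searchsorted(tss_arr, mid))
            cand = {max(j - 1, 0), min(j, len(gene_list) - 1)}
            dist_list.append(min(abs(mid - int(tss_arr[i])) for i in cand))
        else:
            dist_list.append(min(index.distance(g, mid) for g in gene_list))
    dists = np.asarray(dist_list, dtype=np.int64)
    full = [0] + edges + [np.inf]
    counts = np.histogram(dists, bins=full)[0]
    labels = []
    for lo, hi in zip(full[:-1], full[1:]):
        hi_s = "inf" if hi == np.inf else f"{int(hi)}"
        labels.append(f"[{int(lo)},{hi_s})")
    return DistanceProfile(labels, counts / counts.sum())
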