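"""Overlap/enrichment statistics for peak sets and gene sets.

Four tests are provided: a hypergeometric upper tail for count overlaps, a
Benjamini–Hochberg step-up FDR, a length-preserving genomic permutation
("proximity") test, and a region-fraction binomial test.  Permutation
p-values use the add-one estimator ``(1 + exceed) / (1 + n_perm)`` and so
are never zero; ties with the observed statistic count as exceedances
(conservative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from cistra.intervals import PeakSet, merge_intervals

__all__ = [
    "GenomeSpec",
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_fdr",
    "permutation_proximity_test",
    "region_binomial_test",
    "geneset_hypergeometric",
    "default_universe_size",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths (bp) defining the permutation/binomial support."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))


@dataclass
class EnrichmentResult:
    """Outcome of one enrichment test plus its null-model metadata."""

    method: str
    observed: int
    expected: float
    statistic: float
    p_value: float
    n_perm: int | None = None
    seed: int | None = None
    universe_descriptor: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.observed < 0:
            raise ValueError("observed count must be >= 0")
        if self.n_perm is not None and self.p_value < 1.0 / (self.n_perm + 1) - 1e-12:
            raise ValueError("permutation p-value below attainable minimum")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str)


def default_universe_size(sets: Sequence[PeakSet]) -> int:
    """Default universe for peak-level hypergeometric tests: the number of
    merged intervals in the union of all peak sets under comparison."""
    pooled = PeakSet("_union", [iv for s in sets for iv in s.intervals])
    return len(merge_intervals(pooled))


def hypergeometric_tail(
    overlap_k: int, size_a: int, size_b: int, universe_n: int
) -> EnrichmentResult:
    """Upper-tail hypergeometric test: P(X >= overlap_k) drawing ``size_b``
    items from a universe of ``universe_n`` containing ``size_a`` successes."""
    if not 0 <= overlap_k <= min(size_a, size_b):
        raise ValueError(
            f"need 0 <= overlap_k <= min(size_a, size_b); got overlap_k="
            f"{overlap_k}, size_a={size_a}, size_b={size_b}"
        )
    if size_a > universe_n or size_b > universe_n:
        raise ValueError(
            f"need size_a <= universe_n and size_b <= universe_n; got "
            f"size_a={size_a}, size_b={size_b}, universe_n={universe_n}"
        )
    p = float(stats.hypergeom.sf(overlap_k - 1, universe_n, size_a, size_b))
    expected = size_a * size_b / universe_n
    return EnrichmentResult(
        method="hypergeometric",
        observed=overlap_k,
        expected=expected,
        statistic=float(overlap_k),
        p_value=min(p, 1.0),
        universe_descriptor=f"universe_n={universe_n}",
    )


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)]
        raise ValueError(f"p-values outside [0, 1]: {bad[:5]}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _count_overlapping(
    starts: np.ndarray,
    ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
) -> np.ndarray:
    """Per-interval bool: does [start,end) share >=1 bp with merged b?"""
    if b_starts.size == 0:
        return np.zeros(starts.shape, dtype=bool)
    j = np.searchsorted(b_starts, ends, side="left") - 1
    ok = j >= 0
    hit = np.zeros(starts.shape, dtype=bool)
    hit[ok] = b_ends[j[ok]] > starts[ok]
    return hit


def count_overlap_statistic(a: PeakSet, b: PeakSet) -> int:
    """Number of ``a`` intervals overlapping (>=1 bp) the merged ``b``."""
    b_idx = merge_intervals(b).by_chrom()
    total = 0
    for chrom, (s, e) in a.by_chrom().items():
        arrs = b_idx.get(chrom)
        if arrs is None:
            continue
        total += int(_count_overlapping(s, e, *arrs).sum())
    return total


def permutation_proximity_test(
    a: PeakSet,
    b: PeakSet,
    genome: GenomeSpec,
    n_perm: int = 1000,
    seed: int = 0,
    avoid_self_overlap: bool = False,
) -> EnrichmentResult:
    """Permutation test of whether ``a`` overlaps ``b`` more than expected.

    The statistic is the count of ``a`` intervals overlapping ``b``.  Under
    the null, each ``a`` interval is placed uniformly at random on its own
    chromosome with its length preserved, independently of the others
    (``n_perm`` resamplings).  With ``avoid_self_overlap=True`` placements
    overlapping an already-placed interval of the same resampling are
    rejection-sampled.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    lengths = genome.chrom_lengths
    for s in (a, b):
        for iv in s.intervals:
            if iv.chrom not in lengths:
                raise ValueError(
                    f"chromosome {iv.chrom!r} in peak set {s.name!r} absent "
                    "from genome"
                )
            if iv.end > lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {lengths[iv.chrom]}"
                )
    observed = count_overlap_statistic(a, b)
    b_idx = merge_intervals(b).by_chrom()
    rng = np.random.default_rng(seed)

    a_by_chrom = a.by_chrom()
    exceed = np.zeros(n_perm, dtype=np.int64)
    for chrom, (s_arr, e_arr) in a_by_chrom.items():
        ivl_len = e_arr - s_arr
        max_start = lengths[chrom] - ivl_len  # inclusive upper bound
        arrs = b_idx.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        if not avoid_self_overlap:
            # (n_perm, n_intervals) starts in one draw
            starts = (
                rng.random((n_perm, ivl_len.size)) * (max_start + 1)
            ).astype(np.int64)
            ends = starts + ivl_len
            bs, be = arrs
            if bs.size:
                j = np.searchsorted(bs, ends, side="left") - 1
                ok = j >= 0
                hits = np.zeros(starts.shape, dtype=bool)
                hits[ok] = be[j[ok]] > starts[ok]
                exceed += hits.sum(axis=1)
        else:
            for k in range(n_perm):
                placed_s: list[int] = []
                placed_e: list[int] = []
                count = 0
                for L, ms in zip(ivl_len, max_start):
                    for _ in range(1000):
                        st = int(rng.integers(0, ms + 1))
                        en = st + int(L)
                        if not any(
                            st < pe and en > ps
                            for ps, pe in zip(placed_s, placed_e)
                        ):
                            break
                    placed_s.append(st)
                    placed_e.append(en)
                    bs, be = arrs
                    if bs.size:
                        jj = int(np.searchsorted(bs, en, side="left")) - 1
                        if jj >= 0 and be[jj] > st:
                            count += 1
                exceed[k] += count
    # `exceed` accumulated per-chromosome hit counts per resampling
    n_ge = int(np.count_nonzero(exceed >= observed))
    p = (1 + n_ge) / (1 + n_perm)
    expected = float(exceed.mean()) if n_perm else 0.0
    return EnrichmentResult(
        method="permutation",
        observed=observed,
        expected=expected,
        statistic=float(observed),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        universe_descriptor=f"genome_bp={genome.total_bp}",
    )


def region_binomial_test(
    peaks: PeakSet, domains: PeakSet, genome: GenomeSpec
) -> EnrichmentResult:
    """Region-fraction binomial test: with ``f`` the genome fraction covered
    by the (merged) domains, tests whether more peak midpoints fall inside
    the domains than Binomial(n_peaks, f) predicts."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    merged = merge_intervals(domains)
    for iv in merged.intervals:
        if iv.chrom not in genome.chrom_lengths:
            raise ValueError(f"chromosome {iv.chrom!r} absent from genome")
    covered = sum(len(iv) for iv in merged.intervals)
    f = covered / genome.total_bp
    dom_idx = merged.by_chrom()
    k = 0
    for iv in peaks.intervals:
        arrs = dom_idx.get(iv.chrom)
        if arrs is None:
            continue
        mid = iv.midpoint
        bs, be = arrs
        j = int(np.searchsorted(bs, mid, side="right")) - 1
        if j >= 0 and be[j] > mid:
            k += 1
    n = len(peaks)
    if f == 0.0 and k > 0:
        raise ValueError(
            "impossible state: zero domain coverage but peaks fall inside domains"
        )
    p = float(stats.binom.sf(k - 1, n, f)) if f > 0 else (1.0 if k == 0 else 0.0)
    return EnrichmentResult(
        method="binomial",
        observed=k,
        expected=n * f,
        statistic=float(k),
        p_value=min(p, 1.0),
        universe_descriptor=f"domain_fraction={f:.6g}; genome_bp={genome.total_bp}",
    )


def geneset_hypergeometric(
    query: Iterable[str], signature: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Gene-set enrichment of ``query`` for ``signature`` within ``universe``.

    The effective signature is ``signature & universe``; ``query`` must be a
    subset of the universe.
    """
    q, sig, uni = set(query), set(signature), set(universe)
    extra = q - uni
    if extra:
        shown = sorted(extra)[:10]
        raise ValueError(
            f"{len(extra)} query gene(s) absent from universe, e.g. {shown}"
        )
    eff_sig = sig & uni
    k = len(q & eff_sig)
    res = hypergeometric_tail(k, len(eff_sig), len(q), len(uni))
    res.method = "geneset_hypergeometric"
    res.universe_descriptor = (
        f"universe={len(uni)} genes; signature={len(eff_sig)} in universe"
    )
    return res
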