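"""Seeded synthetic-data generators with planted, recoverable structure.

Every generator is deterministic given its spec and seed.  A single master
seed is expanded into independent per-generator child streams with
``numpy.random.SeedSequence(master).spawn(...)`` in a fixed order
(genome, peaks, overlap, expression, survival), so regenerating one input
class never perturbs the others.

Planted parameters (promoter bias, pairwise overlap fraction, concordant
differential-expression effects, hazard ratio and cutpoint) are the
quantities the corresponding pipeline stages are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from cistra.annotation import GeneModel
from cistra.enrichment import GenomeSpec
from cistra.expression import ExpressionMatrix
from cistra.intervals import GenomicInterval, PeakSet, merge_intervals
from cistra.survival import SurvivalRecord

__all__ = [
    "SyntheticSpec",
    "child_seeds",
    "gen_genome",
    "gen_peakset",
    "gen_overlapping_peakset",
    "gen_expression",
    "gen_survival",
]

_STREAMS = ("genome", "peaks", "overlap", "expression", "survival")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort; all structure is planted."""

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 8_000_000}
    )
    n_genes: int = 300
    gene_length: int = 10_000
    n_peaks: int = 1000
    peak_length_dist: tuple[int, int] = (200, 400)
    promoter_bias: float = 0.8
    promoter_halfwidth: int = 5_000
    overlap_fraction: float = 0.5
    de_effect: float = 2.0
    de_frac: float = 0.05
    noise_sd: float = 0.5
    hr: float = 3.0
    censor_frac: float = 0.2

    def __post_init__(self) -> None:
        for name in ("promoter_bias", "overlap_fraction", "de_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.hr <= 0:
            raise ValueError("hr must be > 0")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")
        for name in ("n_genes", "n_peaks", "gene_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.peak_length_dist
        if not 1 <= lo <= hi:
            raise ValueError("peak_length_dist must satisfy 1 <= min <= max")

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec(dict(self.chrom_lengths))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        return d


def child_seeds(master: int) -> dict[str, np.random.SeedSequence]:
    """Fixed-order child seed sequences derived from the master seed."""
    seqs = np.random.SeedSequence(master).spawn(len(_STREAMS))
    return dict(zip(_STREAMS, seqs))


def _rng_for(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(child_seeds(spec.seed)[stream])


# ---------------------------------------------------------------------------
# Genome and genes


def gen_genome(spec: SyntheticSpec) -> tuple[GenomeSpec, list[GeneModel]]:
    """Disjoint gene spans placed uniformly on the chromosomes.

    Uses the gaps construction: n disjoint length-L intervals on a
    chromosome of length C correspond to n uniform points on [0, C - nL].
    Strands are Bernoulli(1/2).
    """
    rng = _rng_for(spec, "genome")
    genome = spec.genome
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(spec.n_genes * lengths / lengths.sum()).astype(int)
    while alloc.sum() < spec.n_genes:
        alloc[int(np.argmax(lengths - alloc * spec.gene_length))] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_c in zip(chroms, alloc):
        C = genome.chrom_lengths[chrom]
        L = spec.gene_length
        slack = C - n_c * L
        if slack < 0:
            raise ValueError(
                f"genome too small: cannot place {n_c} genes of {L} bp on "
                f"{chrom} ({C} bp)"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=n_c))
        starts = offsets + np.arange(n_c) * L
        strands = rng.random(n_c) < 0.5
        for s, plus in zip(starts, strands):
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chrom=chrom,
                    strand="+" if plus else "-",
                    span_start=int(s),
                    span_end=int(s) + L,
                )
            )
            gid += 1
    return genome, genes


# ---------------------------------------------------------------------------
# Peaks


def _random_peak(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    mid: int,
    length: int,
) -> GenomicInterval:
    start = max(0, min(mid - length // 2, chrom_len - length))
    return GenomicInterval(chrom, start, start + length)


def gen_peakset(
    genome: GenomeSpec,
    genes: Sequence[GeneModel],
    spec: SyntheticSpec,
    name: str = "synthetic_peaks",
    rng: np.random.Generator | None = None,
) -> PeakSet:
    """Peaks placed near promoters with probability ``promoter_bias``
    (midpoint within ``promoter_halfwidth`` of a random TSS), otherwise
    uniformly on the genome; lengths uniform in ``peak_length_dist``."""
    rng = rng if rng is not None else _rng_for(spec, "peaks")
    chroms = list(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    lo, hi = spec.peak_length_dist
    intervals = []
    for _ in range(spec.n_peaks):
        length = int(rng.integers(lo, hi + 1))
        if rng.random() < spec.promoter_bias and len(genes) > 0:
            g = genes[int(rng.integers(0, len(genes)))]
            offset = int(rng.integers(-spec.promoter_halfwidth + 1,
                                      spec.promoter_halfwidth))
            chrom = g.chrom
            mid = min(max(g.tss + offset, 0), genome.chrom_lengths[chrom] - 1)
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            mid = int(rng.integers(0, genome.chrom_lengths[chrom]))
        intervals.append(
            _random_peak(rng, chrom, genome.chrom_lengths[chrom], mid, length)
        )
    return PeakSet(name, intervals, source=f"synthetic(seed={spec.seed})")


def gen_overlapping_peakset(
    base: PeakSet,
    f: float,
    genome: GenomeSpec,
    seed: int,
    n: int | None = None,
    peak_length_dist: tuple[int, int] = (200, 400),
    name: str = "synthetic_overlap",
    max_tries: int = 10_000,
) -> PeakSet:
    """New peak set with a planted fraction ``f`` of peaks overlapping
    ``base`` (>=1 bp, midpoint placed inside a random base interval) and the
    remainder placed uniformly while avoiding ``base`` entirely."""
    if not 0 <= f <= 1:
        raise ValueError(f"overlap fraction must be in [0,1], got {f}")
    rng = np.random.default_rng(seed)
    n = n if n is not None else len(base)
    n_overlap = int(round(f * n))
    if n_overlap > 0 and len(base) == 0:
        raise ValueError("cannot plant overlap against an empty base set")
    merged = merge_intervals(base).by_chrom()
    chroms = list(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    lo, hi = peak_length_dist
    base_ivs = list(base.intervals)
    intervals = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        if i < n_overlap:
            b = base_ivs[int(rng.integers(0, len(base_ivs)))]
            # a midpoint inside [start, end) guarantees >= 1 shared bp;
            # 1 bp base intervals degenerate to their single position
            mid = int(rng.integers(b.start, b.end))
            iv = _random_peak(
                rng, b.chrom, genome.chrom_lengths[b.chrom], mid, length
            )
            # clamping at chromosome edges could in principle break the
            # guarantee; re-centre if it did
            if not (iv.start < b.end and iv.end > b.start):
                iv = GenomicInterval(b.chrom, b.start, b.start + length)
            intervals.append(iv)
        else:
            for attempt in range(max_tries):
                chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                mid = int(rng.integers(0, genome.chrom_lengths[chrom]))
                iv = _random_peak(
                    rng, chrom, genome.chrom_lengths[chrom], mid, length
                )
                arrs = merged.get(chrom)
                if arrs is None:
                    break
                bs, be = arrs
                j = int(np.searchsorted(bs, iv.end, side="left")) - 1
                if j < 0 or be[j] <= iv.start:
                    break
            else:
                raise ValueError(
                    "could not place a non-overlapping peak: genome too "
                    "crowded for the requested overlap fraction"
                )
            intervals.append(iv)
    return PeakSet(name, intervals, source=f"synthetic_overlap(f={f},seed={seed})")


# ---------------------------------------------------------------------------
# Expression


def gen_expression(
    genes: Sequence[GeneModel],
    spec: SyntheticSpec,
    design: Mapping[str, int] | None = None,
    planted_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Log2 expression with planted concordant OE-up / KD-down effects.

    Baseline per gene ~ Normal(8, 1); planted genes shift by +de_effect in
    OE samples and -de_effect in KD samples; i.i.d. Normal(0, noise_sd)
    noise on every value.  Returns the matrix and the planted gene ids.
    """
    design = dict(design or {"OE": 3, "KD": 3, "control": 3})
    for arm, reps in design.items():
        if reps < 2:
            raise ValueError(f"arm {arm!r} has {reps} replicate(s); need >= 2")
    rng = rng if rng is not None else _rng_for(spec, "expression")
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    if planted_ids is None:
        n_planted = int(round(spec.de_frac * n_genes))
        if n_planted < 1:
            raise ValueError("de_frac * n_genes < 1: no gene to plant")
        planted_ids = [
            gene_ids[i]
            for i in sorted(rng.choice(n_genes, size=n_planted, replace=False))
        ]
    planted = set(planted_ids)
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    cols = []
    for arm in ("control", "OE", "KD"):
        if arm not in design:
            continue
        for r in range(design[arm]):
            sid = f"{arm}_{r + 1}"
            sample_ids.append(sid)
            groups[sid] = arm
            shift = np.zeros(n_genes)
            if arm == "OE":
                shift[[i for i, g in enumerate(gene_ids) if g in planted]] = (
                    spec.de_effect
                )
            elif arm == "KD":
                shift[[i for i, g in enumerate(gene_ids) if g in planted]] = (
                    -spec.de_effect
                )
            cols.append(baseline + shift + rng.normal(0, spec.noise_sd, n_genes))
    values = np.column_stack(cols)
    return (
        ExpressionMatrix(gene_ids, sample_ids, values, groups),
        sorted(planted),
    )


# ---------------------------------------------------------------------------
# Survival


def gen_survival(
    n: int,
    spec: SyntheticSpec,
    score_link: str = "step",
    step_at: float = 0.6,
    baseline_hazard: float = 0.02,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, float], list[SurvivalRecord]]:
    """Exponential survival with a planted score-hazard link.

    ``score_link``: "none" (hazard independent of score), "step" (hazard
    multiplied by ``hr`` when score > step_at) or "linear" (hazard
    multiplied by ``exp(log(hr) * score)``).  Scores are Uniform(0,1).
    Censoring is by an independent exponential time whose rate is chosen so
    roughly ``censor_frac`` of subjects are censored.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if score_link not in ("none", "step", "linear"):
        raise ValueError(f"unknown score_link {score_link!r}")
    rng = rng if rng is not None else _rng_for(spec, "survival")
    scores_arr = rng.random(n)
    if score_link == "step":
        hazard = np.where(scores_arr > step_at, baseline_hazard * spec.hr,
                          baseline_hazard)
    elif score_link == "linear":
        hazard = baseline_hazard * np.exp(np.log(spec.hr) * scores_arr)
    else:
        hazard = np.full(n, baseline_hazard)
    event_times = rng.exponential(1.0 / hazard)
    if spec.censor_frac > 0:
        c_rate = hazard.mean() * spec.censor_frac / (1.0 - spec.censor_frac)
        censor_times = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    times = np.minimum(event_times, censor_times)
    events = event_times <= censor_times
    times = np.maximum(times, 1e-6)  # record invariant: time > 0
    scores = {}
    records = []
    for i in range(n):
        sid = f"s{i:04d}"
        scores[sid] = float(scores_arr[i])
        records.append(
            SurvivalRecord(
                subject_id=sid,
                time=float(times[i]),
                event=bool(events[i]),
                covariates={"score": float(scores_arr[i])},
            )
        )
    return scores, records
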