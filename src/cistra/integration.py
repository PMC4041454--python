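"""Join binding annotations with regulated gene sets.

Provides per-gene bound/regulated records, the fraction of a core set bound
within a window, a gene-panel regulation check ("regulated" = nearest peak
closer than the window AND concordant OE-up/KD-down differential
expression) and a multi-peak-set concordance report bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cistra.annotation import (
    DEFAULT_WINDOWS,
    GeneModel,
    PeakGeneAssignment,
    closest_gene,
    distance_distribution,
)
from cistra.enrichment import (
    GenomeSpec,
    default_universe_size,
    hypergeometric_tail,
    permutation_proximity_test,
)
from cistra.expression import DEResult, GeneSet, core_regulated_set
from cistra.intervals import PeakSet, intersect_sets, pairwise_overlap_matrix

__all__ = [
    "IntegratedGeneRecord",
    "PanelCheckResult",
    "integrate_binding_expression",
    "panel_regulation_check",
    "cistrome_concordance_report",
]


@dataclass
class IntegratedGeneRecord:
    gene_id: str
    bound_within: dict[int, bool]
    in_core_set: bool
    nearest_distance: float  # bp to nearest peak midpoint (inf if none)

    def __post_init__(self) -> None:
        windows = sorted(self.bound_within)
        for w1, w2 in zip(windows, windows[1:]):
            if self.bound_within[w1] and not self.bound_within[w2]:
                raise ValueError(
                    f"bound_within must be monotone in window "
                    f"({w1} true but {w2} false for {self.gene_id})"
                )


@dataclass
class PanelCheckResult:
    panel_name: str
    per_gene: dict[str, dict[str, bool]]
    n_regulated: int
    n_panel: int
    missing_from_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_regulated > self.n_panel:
            raise ValueError("n_regulated cannot exceed n_panel")


def _nearest_distances(
    assignments: Sequence[PeakGeneAssignment],
) -> dict[str, int]:
    nearest: dict[str, int] = {}
    for a in assignments:
        cur = nearest.get(a.gene_id)
        if cur is None or a.distance < cur:
            nearest[a.gene_id] = a.distance
    return nearest


def integrate_binding_expression(
    assignments: Sequence[PeakGeneAssignment],
    core: GeneSet,
    window: int,
    window_ladder: Sequence[int] = DEFAULT_WINDOWS,
) -> tuple[list[IntegratedGeneRecord], float]:
    """Per-gene binding records for a core set and the fraction of core
    genes with a peak strictly closer than ``window``.

    ``assignments`` must have been produced with a window at least as large
    as ``window`` (and as max(window_ladder)), otherwise distant genes are
    invisible here.
    """
    if len(core) == 0:
        raise ValueError("empty core gene set")
    if assignments:
        produced = max(a.window for a in assignments)
        if produced < window:
            raise ValueError(
                f"assignments were made at window {produced} < query window {window}"
            )
    nearest = _nearest_distances(assignments)
    records = []
    n_bound = 0
    for gene in sorted(core.gene_ids):
        d = nearest.get(gene, float("inf"))
        bound = {int(w): bool(d < w) for w in window_ladder}
        if d < window:
            n_bound += 1
        records.append(
            IntegratedGeneRecord(
                gene_id=gene,
                bound_within=bound,
                in_core_set=True,
                nearest_distance=float(d),
            )
        )
    return records, n_bound / len(core)


def panel_regulation_check(
    panel: GeneSet,
    assignments: Sequence[PeakGeneAssignment],
    de_oe: Sequence[DEResult],
    de_kd: Sequence[DEResult],
    window: int = 25_000,
    threshold: float = 0.1,
    concordant_only: bool = True,
) -> PanelCheckResult:
    """Check which panel genes are directly regulated: bound (nearest peak
    midpoint strictly closer than ``window`` bp) AND differentially
    expressed.

    With ``concordant_only`` (default) "differentially expressed" means the
    concordant OE-up/KD-down rule at the adjusted threshold; otherwise a
    significant change in either direction in either contrast suffices.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    universe = {r.gene_id for r in de_oe} & {r.gene_id for r in de_kd}
    missing = sorted(g for g in panel.gene_ids if g not in universe)
    nearest = _nearest_distances(assignments)
    core = core_regulated_set(de_oe, de_kd, threshold).gene_ids
    loose = {
        r.gene_id
        for r in list(de_oe) + list(de_kd)
        if r.adj_p < threshold and r.log_fc != 0
    }
    de_ok = core if concordant_only else loose
    per_gene: dict[str, dict[str, bool]] = {}
    n_regulated = 0
    for gene in sorted(panel.gene_ids):
        bound = nearest.get(gene, float("inf")) < window
        concordant = gene in de_ok
        regulated = bound and concordant
        per_gene[gene] = {
            "bound_lt_window": bool(bound),
            "de_concordant": bool(concordant),
            "regulated": bool(regulated),
        }
        if regulated:
            n_regulated += 1
    return PanelCheckResult(
        panel_name=panel.name,
        per_gene=per_gene,
        n_regulated=n_regulated,
        n_panel=len(panel),
        missing_from_universe=missing,
    )


def cistrome_concordance_report(
    peak_sets: Sequence[PeakSet],
    genes: Sequence[GeneModel],
    genome: GenomeSpec,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    n_perm: int = 199,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Pairwise concordance of peak sets: overlap counts/percentages,
    hypergeometric and permutation p-values, per-set distance profiles and
    shared-closest-gene counts per window.  Optionally serialised to
    ``out_dir`` as TSVs plus a JSON manifest."""
    if len(peak_sets) < 2:
        raise ValueError("need >= 2 peak sets")
    matrix = pairwise_overlap_matrix(peak_sets)
    universe_n = default_universe_size(peak_sets)
    rows = []
    for i, a in enumerate(peak_sets):
        for j, b in enumerate(peak_sets):
            if i >= j:
                continue
            k = len(intersect_sets(a.unique(), b.unique()))
            hyper = hypergeometric_tail(
                min(k, min(a.n_unique(), b.n_unique())),
                a.n_unique(),
                b.n_unique(),
                max(universe_n, a.n_unique() + b.n_unique()),
            )
            perm = permutation_proximity_test(
                a, b, genome, n_perm=n_perm, seed=seed + 1000 * i + j
            )
            rows.append(
                {
                    "set_a": a.name,
                    "set_b": b.name,
                    "n_a": a.n_unique(),
                    "n_b": b.n_unique(),
                    "n_overlap": k,
                    "pct_of_a": matrix.values[i, j],
                    "pct_of_b": matrix.values[j, i],
                    "hypergeom_p": hyper.p_value,
                    "perm_p": perm.p_value,
                    "perm_expected": perm.expected,
                }
            )
    pairwise = pd.DataFrame(rows)

    profiles = {}
    for s in peak_sets:
        prof = distance_distribution(s, genes)
        profiles[s.name] = dict(zip(prof.bin_labels, prof.fractions.tolist()))

    closest: dict[str, set[str]] = {
        s.name: {closest_gene(iv, genes)[0] for iv in s.intervals}
        for s in peak_sets
    }
    gene_rows = []
    for i, a in enumerate(peak_sets):
        for j, b in enumerate(peak_sets):
            if i >= j:
                continue
            shared = closest[a.name] & closest[b.name]
            gene_rows.append(
                {
                    "set_a": a.name,
                    "set_b": b.name,
                    "n_genes_a": len(closest[a.name]),
                    "n_genes_b": len(closest[b.name]),
                    "n_shared_closest": len(shared),
                }
            )
    gene_overlap = pd.DataFrame(gene_rows)

    report = {
        "pairwise": pairwise,
        "overlap_matrix": matrix,
        "distance_profiles": profiles,
        "gene_overlap": gene_overlap,
        "parameters": {
            "windows": [int(w) for w in windows],
            "n_perm": n_perm,
            "seed": seed,
            "universe_n": universe_n,
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pairwise.to_csv(out / "pairwise_stats.tsv", sep="\t", index=False)
        gene_overlap.to_csv(out / "gene_overlap.tsv", sep="\t", index=False)
        matrix.to_frame().to_csv(out / "overlap_matrix.tsv", sep="\t")
        with (out / "manifest.json").open("w") as fh:
            json.dump(
                {
                    "parameters": report["parameters"],
                    "distance_profiles": profiles,
                    "orientation": matrix.orientation,
                },
                fh,
                indent=2,
            )
    return report
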